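"""Coordinate-frame and composition I/O.

The in-memory model is deliberately small: a :class:`Frame` is one snapshot
of bead positions (nm) in an orthorhombic periodic box, with per-bead species
labels of the form ``"RESNAME:BEADNAME"``; a :class:`Trajectory` is an
ordered sequence of frames sharing one species ordering plus the system's
:class:`Composition` (lipid metadata: headgroup class, tail codes, per-tail
double-bond counts, leaflet, copy number).

GRO files are parsed directly (the fixed-width dialect, possibly with several
concatenated frames); PDB files are read through MDAnalysis and converted
from Å to nm.  Coordinates are wrapped into ``[0, box)`` on read because all
lateral-grid analyses downstream assume in-box coordinates.  Only
orthorhombic boxes are supported.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Frame",
    "Trajectory",
    "CompositionEntry",
    "Composition",
    "ParseError",
    "read_frames",
    "read_composition",
    "write_frames",
    "write_composition",
]

HEADGROUP_CLASSES = frozenset(
    {"PC", "PE", "SM", "PS", "PIP", "GM", "CER", "DAG", "LPC", "PA", "PI", "CHOL", "NP"}
)
LEAFLET_VALUES = frozenset({"inner", "outer", "both", "n/a"})

#: residue names never required to appear in a composition table
NON_LIPID_RESIDUES = frozenset({"W", "WF", "ION", "NA", "CL", "NA+", "CL-", "NP"})


class ParseError(ValueError):
    """Malformed coordinate or composition file; carries the line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass
class Frame:
    """One snapshot: positions (N, 3) in nm, labels, residue ids, box (3,) nm."""

    positions: np.ndarray
    species: np.ndarray  # dtype=str, "RESNAME:BEADNAME"
    resids: np.ndarray  # dtype=int
    box: np.ndarray  # (3,) nm, orthorhombic
    time: float | None = None  # ps

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.species = np.asarray(self.species, dtype=str)
        self.resids = np.asarray(self.resids, dtype=int)
        self.box = np.asarray(self.box, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (N, 3)")
        if len(self.species) != len(self.positions):
            raise ValueError("positions and species must have equal length")
        if len(self.resids) != len(self.positions):
            raise ValueError("positions and resids must have equal length")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError("box must be three positive lengths (orthorhombic)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("all coordinates must be finite")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def resnames(self) -> np.ndarray:
        return np.array([s.split(":", 1)[0] for s in self.species])

    @property
    def beadnames(self) -> np.ndarray:
        return np.array([s.split(":", 1)[1] for s in self.species])

    def wrapped(self) -> "Frame":
        """Return a copy with coordinates wrapped into [0, box)."""
        pos = np.mod(self.positions, self.box)
        # mod can return box itself for tiny negative inputs; fold those back
        pos = np.where(pos >= self.box, pos - self.box, pos)
        return replace(self, positions=pos)

    def select(self, labels: Iterable[str]) -> np.ndarray:
        """Boolean mask of beads whose species label is in ``labels``."""
        labels = set(labels)
        if not labels:
            raise ValueError("empty species selector")
        mask = np.isin(self.species, sorted(labels))
        return mask


@dataclass
class Trajectory:
    frames: list[Frame]
    composition: "Composition | None" = None

    def __post_init__(self) -> None:
        if self.frames:
            ref = self.frames[0]
            for i, fr in enumerate(self.frames):
                if len(fr) != len(ref):
                    raise ValueError(f"frame {i} bead count differs from frame 0")
                if not np.array_equal(fr.species, ref.species):
                    raise ValueError(f"frame {i} species ordering differs from frame 0")
            times = [fr.time for fr in self.frames if fr.time is not None]
            if times != sorted(times):
                raise ValueError("frame times must be non-decreasing")

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[Frame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]


@dataclass(frozen=True)
class CompositionEntry:
    residue: str
    headgroup: str
    tail1: str | None
    tail2: str | None
    db1: int
    db2: int
    leaflet: str
    count: int

    def __post_init__(self) -> None:
        if self.headgroup not in HEADGROUP_CLASSES:
            raise ValueError(f"{self.residue}: unknown headgroup class {self.headgroup!r}")
        if self.leaflet not in LEAFLET_VALUES:
            raise ValueError(f"{self.residue}: leaflet must be one of {sorted(LEAFLET_VALUES)}")
        if self.count < 0:
            raise ValueError(f"{self.residue}: negative count")
        for db in (self.db1, self.db2):
            if not 0 <= db <= 6:
                raise ValueError(f"{self.residue}: double-bond count {db} outside 0..6")

    @property
    def tails(self) -> list[tuple[str, int]]:
        """(tail code, double bonds) for each acyl chain present."""
        out = []
        if self.tail1:
            out.append((self.tail1, self.db1))
        if self.tail2:
            out.append((self.tail2, self.db2))
        return out


@dataclass
class Composition:
    """Lipid species metadata keyed by residue name."""

    entries: dict[str, CompositionEntry] = field(default_factory=dict)

    def __getitem__(self, residue: str) -> CompositionEntry:
        return self.entries[residue]

    def __contains__(self, residue: str) -> bool:
        return residue in self.entries

    def __iter__(self) -> Iterator[CompositionEntry]:
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def residues_with_tail(self, tail_code: str) -> list[tuple[str, int]]:
        """Residues carrying ``tail_code``; (residue, chain index 1 or 2)."""
        hits = []
        for e in self:
            if e.tail1 == tail_code:
                hits.append((e.residue, 1))
            if e.tail2 == tail_code:
                hits.append((e.residue, 2))
        return hits

    def tail_codes(self) -> list[str]:
        codes: set[str] = set()
        for e in self:
            codes.update(t for t, _ in e.tails)
        return sorted(codes)

    def validate_frame(self, frame: Frame) -> None:
        """Every lipid residue name in the frame must have an entry."""
        seen = set(frame.resnames)
        missing = seen - set(self.entries) - NON_LIPID_RESIDUES
        if missing:
            raise ValueError(f"residues without composition entry: {sorted(missing)}")


# ---------------------------------------------------------------------------
# GRO

_GRO_BOX_FMT = "{:10.5f}{:10.5f}{:10.5f}\n"


def _parse_gro_stream(lines: list[str], path: str) -> list[Frame]:
    frames: list[Frame] = []
    i = 0
    nlines = len(lines)
    while i < nlines:
        if not lines[i].strip():
            i += 1
            continue
        title = lines[i]
        time = None
        if "t=" in title:
            try:
                time = float(title.split("t=")[1].split()[0])
            except (IndexError, ValueError):
                time = None
        try:
            natoms = int(lines[i + 1].strip())
        except (IndexError, ValueError):
            raise ParseError(f"{path}: expected atom count", line=i + 2)
        first_atom = i + 2
        box_line_no = first_atom + natoms
        if box_line_no >= nlines:
            raise ParseError(f"{path}: truncated frame (missing box line)", line=nlines)
        pos = np.empty((natoms, 3))
        species = np.empty(natoms, dtype=object)
        resids = np.empty(natoms, dtype=int)
        for j in range(natoms):
            ln = lines[first_atom + j]
            try:
                resids[j] = int(ln[0:5])
                resname = ln[5:10].strip()
                beadname = ln[10:15].strip()
                pos[j, 0] = float(ln[20:28])
                pos[j, 1] = float(ln[28:36])
                pos[j, 2] = float(ln[36:44])
            except (ValueError, IndexError):
                raise ParseError(f"{path}: malformed atom record", line=first_atom + j + 1)
            species[j] = f"{resname}:{beadname}"
        box_fields = lines[box_line_no].split()
        if len(box_fields) < 3:
            raise ParseError(f"{path}: malformed box line", line=box_line_no + 1)
        if len(box_fields) > 3 and any(float(v) != 0.0 for v in box_fields[3:]):
            raise ParseError(
                f"{path}: triclinic box not supported (orthorhombic only)",
                line=box_line_no + 1,
            )
        try:
            box = np.array([float(v) for v in box_fields[:3]])
        except ValueError:
            raise ParseError(f"{path}: malformed box line", line=box_line_no + 1)
        if not np.all(box > 0):
            raise ParseError(f"{path}: box lengths must be positive", line=box_line_no + 1)
        frames.append(
            Frame(pos, species.astype(str), resids, box, time=time).wrapped()
        )
        i = box_line_no + 1
    if not frames:
        raise ParseError(f"{path}: no frames found", line=1)
    return frames


def _read_pdb(path: str | Path) -> list[Frame]:
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        frames: list[Frame] = []
        species = np.array(
            [f"{r}:{n}" for r, n in zip(u.atoms.resnames, u.atoms.names)]
        )
        resids = u.atoms.resids.astype(int)
        for ts in u.trajectory:
            if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
                raise ParseError(f"{path}: missing or zero CRYST1 box (box is required)")
            if not np.allclose(ts.dimensions[3:], 90.0):
                raise ParseError(f"{path}: triclinic box not supported (orthorhombic only)")
            frames.append(
                Frame(
                    ts.positions / 10.0,  # Å -> nm
                    species,
                    resids,
                    np.asarray(ts.dimensions[:3], dtype=float) / 10.0,
                    time=float(ts.time) if ts.time is not None else None,
                ).wrapped()
            )
    return frames


def read_frames(
    path: str | Path, format: str | None = None, composition: Composition | None = None
) -> Trajectory:
    """Read a GRO or PDB coordinate file into a :class:`Trajectory`.

    GRO positions are taken in nm as printed; PDB positions are converted
    from Å to nm (CRYST1 box likewise).  Multi-frame GRO (concatenated
    blocks) and multi-model PDB are supported.
    """
    path = Path(path)
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format not in ("gro", "pdb"):
        raise ValueError(f"unsupported format {format!r} (gro or pdb)")
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "gro":
        frames = _parse_gro_stream(path.read_text().splitlines(), str(path))
    else:
        frames = _read_pdb(path)
    traj = Trajectory(frames, composition=composition)
    if composition is not None:
        composition.validate_frame(frames[0])
    return traj


def write_frames(traj: Trajectory, path: str | Path, format: str = "gro") -> None:
    """Write a trajectory as (multi-frame) GRO; 3-decimal nm precision."""
    if format != "gro":
        raise ValueError("only GRO output is supported")
    if len(traj) == 0:
        raise ValueError("refusing to write an empty trajectory")
    buf = io.StringIO()
    for k, fr in enumerate(traj):
        t = fr.time if fr.time is not None else 0.0
        buf.write(f"memshadow frame {k} t= {t:.3f}\n")
        buf.write(f"{len(fr):5d}\n")
        for j in range(len(fr)):
            resname, bead = fr.species[j].split(":", 1)
            resid = int(fr.resids[j]) % 100000
            x, y, z = fr.positions[j]
            buf.write(
                f"{resid:5d}{resname:<5.5s}{bead:>5.5s}{(j + 1) % 100000:5d}"
                f"{x:8.3f}{y:8.3f}{z:8.3f}\n"
            )
        buf.write(_GRO_BOX_FMT.format(*fr.box))
    Path(path).write_text(buf.getvalue())


# ---------------------------------------------------------------------------
# Composition tables

_COMP_COLUMNS = ["residue", "headgroup", "tail1", "tail2", "db1", "db2", "leaflet", "count"]


def read_composition(path: str | Path) -> Composition:
    """Read a composition CSV (residue, headgroup, tail1, tail2, db1, db2, leaflet, count)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _COMP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing composition columns {missing}")
    entries: dict[str, CompositionEntry] = {}
    for i, row in df.iterrows():
        name = row["residue"].strip()
        if name in entries:
            raise ParseError(f"{path}: duplicate residue name {name!r}", line=int(i) + 2)
        try:
            entry = CompositionEntry(
                residue=name,
                headgroup=row["headgroup"].strip(),
                tail1=row["tail1"].strip() or None,
                tail2=row["tail2"].strip() or None,
                db1=int(row["db1"] or 0),
                db2=int(row["db2"] or 0),
                leaflet=row["leaflet"].strip(),
                count=int(row["count"]),
            )
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}", line=int(i) + 2)
        entries[name] = entry
    return Composition(entries)


def write_composition(comp: Composition, path: str | Path) -> None:
    rows = [
        {
            "residue": e.residue,
            "headgroup": e.headgroup,
            "tail1": e.tail1 or "",
            "tail2": e.tail2 or "",
            "db1": e.db1,
            "db2": e.db2,
            "leaflet": e.leaflet,
            "count": e.count,
        }
        for e in comp
    ]
    pd.DataFrame(rows, columns=_COMP_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Selectors

def tail_bead_labels(comp: Composition, tail_code: str) -> set[str]:
    """Species labels of the tail beads carrying ``tail_code``.

    Bead naming convention: acyl-chain beads are named ``T<i>A`` (chain 1)
    and ``T<i>B`` (chain 2).  Headgroup/linker beads (PO4, NC3, GL1, ROH,
    ...) are excluded, so tail selectors isolate the chains, never the
    interface region.
    """
    labels: set[str] = set()
    for residue, chain in comp.residues_with_tail(tail_code):
        suffix = "A" if chain == 1 else "B"
        for i in range(1, 7):  # CG chains are short (3-6 beads)
            labels.add(f"{residue}:T{i}{suffix}")
    if not labels:
        raise ValueError(f"no residue in the composition carries tail code {tail_code!r}")
    return labels


def residue_bead_labels(frame: Frame, resname: str) -> set[str]:
    """All species labels present in the frame for one residue name."""
    labels = {s for s in frame.species if s.split(":", 1)[0] == resname}
    if not labels:
        raise ValueError(f"residue {resname!r} matches no beads in the frame")
    return labels


def bead_name_labels(frame: Frame, bead_names: Sequence[str]) -> set[str]:
    """Species labels whose bead name is in ``bead_names`` (e.g. ['PO4'])."""
    wanted = set(bead_names)
    labels = {s for s in frame.species if s.split(":", 1)[1] in wanted}
    if not labels:
        raise ValueError(f"bead names {sorted(wanted)} match no beads in the frame")
    return labels
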