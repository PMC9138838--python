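"""Synthetic asymmetric-bilayer configurations with planted ground truth.

Every analysis stage in this package is validated against configurations
whose structure is known by construction.  The generator emulates a
coarse-grained plasma-membrane patch: a ~40 x 40 nm lateral box, two
leaflets with different lipid species (the inner leaflet carrying more
polyunsaturated tails), ~30 mol% sterol, membrane undulations as a sum of
cosine height modes, and embedded nanoparticle beads whose lateral
distribution can be biased toward the patches of one chosen tail type.

Key planted features, all recorded in :class:`GroundTruth`:

* per-tail lateral "patch" domains from thresholded Gaussian random fields
  (correlation length ~5 nm) — the structure the shadow-matrix MSE
  statistic must detect;
* nanoparticle lateral positions drawn from the mixture
  (1 - s) * uniform + s * target-patch density, so s = 0 is uniform and
  s = 1 fully patch-confined;
* a fraction of nanoparticles grouped into contact-distance clusters;
* phosphate planes at local-midplane +/- offset, with an optional local
  thickness bump, so leaflet assignment, thickness maps and undulation
  spectra have exact references.

The module also provides the umbrella-sampling data generator: Metropolis
samples from exp(-[U(z) + bias]/kT) for an arbitrary tabulated or callable
potential, used to exercise the WHAM estimator against analytic profiles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .trajectory_io import Composition, CompositionEntry, Frame, Trajectory
from .wham_pmf import KB, UmbrellaWindow

__all__ = [
    "MembraneSpec",
    "GroundTruth",
    "build_membrane",
    "sample_umbrella_windows",
    "default_composition",
]

#: lateral footprints used by the overcrowding check (nm^2 per molecule)
PHOSPHOLIPID_AREA = 0.6
STEROL_AREA = 0.3

#: double-bond count per acyl chain by tail code
TAIL_DOUBLE_BONDS = {"DA": 4, "DU": 5, "PU": 5, "PI": 2, "PO": 1, "DP": 0, "PN": 1}


def default_composition() -> Composition:
    """Synthetic reduced plasma-membrane composition (14 species).

    A stand-in for a full multicomponent plasma-membrane table: ~6200
    lipids, 30 mol% sterol, the inner leaflet enriched in 4-5 double-bond
    tails (DA/DU/PU) and the outer leaflet in saturated/monounsaturated
    PC/SM/GM species.  Counts are chosen to pack a 40 x 40 nm leaflet at
    ~0.6 nm^2 per phospholipid.
    """
    rows = [
        # residue, headgroup, tail1, tail2, db1, db2, leaflet, count
        ("DAPE", "PE", "DA", "DA", 4, 4, "inner", 400),
        ("DAPS", "PS", "DA", "DA", 4, 4, "inner", 240),
        ("DAPC", "PC", "DA", "DA", 4, 4, "inner", 220),
        ("DUPE", "PE", "DU", "DU", 5, 5, "inner", 310),
        ("PUPC", "PC", "PU", "PU", 5, 5, "inner", 240),
        ("PUPS", "PS", "PU", "PU", 5, 5, "inner", 170),
        ("PIPI", "PI", "PI", "PI", 2, 2, "inner", 280),
        ("POPE", "PE", "PO", "PO", 1, 1, "inner", 310),
        ("POPC", "PC", "PO", "PO", 1, 1, "outer", 620),
        ("DPPC", "PC", "DP", "DP", 0, 0, "outer", 260),
        ("DPSM", "SM", "DP", "DP", 0, 0, "outer", 490),
        ("PNSM", "SM", "PN", "PN", 1, 1, "outer", 310),
        ("DPGM", "GM", "DP", "DP", 0, 0, "outer", 240),
        ("DPCE", "CER", "DP", "DP", 0, 0, "outer", 130),
        ("PIPC", "PC", "PI", "PI", 2, 2, "outer", 120),
        ("CHOL", "CHOL", None, None, 0, 0, "both", 1860),
    ]
    return Composition(
        {
            r[0]: CompositionEntry(
                residue=r[0], headgroup=r[1], tail1=r[2], tail2=r[3],
                db1=r[4], db2=r[5], leaflet=r[6], count=r[7],
            )
            for r in rows
        }
    )


def equal_abundance_composition(
    tail_codes: Sequence[str] = ("DA", "DU", "PI", "DP"),
    count: int = 150,
    sterol_count: int = 0,
) -> Composition:
    """Composition with one PC species per tail code, all at equal copy number.

    Used for statistical calibration: with equal abundances (and hence equal
    expected shadow-matrix occupancies) differences in mean MSE against a
    reference species isolate lateral co-localization from abundance.
    """
    entries: dict[str, CompositionEntry] = {}
    for code in tail_codes:
        if code not in TAIL_DOUBLE_BONDS:
            raise ValueError(f"unknown tail code {code!r}")
        name = f"{code}PC"
        db = TAIL_DOUBLE_BONDS[code]
        entries[name] = CompositionEntry(name, "PC", code, code, db, db, "both", count)
    if sterol_count:
        entries["CHOL"] = CompositionEntry("CHOL", "CHOL", None, None, 0, 0, "both", sterol_count)
    return Composition(entries)


@dataclass
class MembraneSpec:
    """Parameters of one synthetic membrane configuration."""

    box: tuple[float, float, float] = (40.0, 40.0, 13.0)
    composition: Composition = field(default_factory=default_composition)
    leaflet_z_offset: float = 2.0  # nm: phosphate planes at midplane +/- offset
    np_count: int = 314  # nanoparticle beads (the study's lowest loading)
    np_colocal_target: str | None = "DA"  # tail code, or None
    np_colocal_strength: float = 0.9  # 0 = uniform, 1 = patch-confined
    np_z_offset: float = -1.0  # nm from local midplane (negative = inner side)
    undulation_amplitude: float = 0.3  # nm per cosine mode
    undulation_modes: int = 3
    cluster_fraction: float = 0.5  # fraction of NPs placed in contact clusters
    cluster_size: int = 8
    patch_correlation_length: float = 5.0  # nm, Gaussian-random-field scale
    patchiness: float = 0.9  # probability weight contrast: domain vs background
    thickness_bump_height: float = 0.0  # nm added to local thickness
    thickness_bump_sigma: float = 3.0  # nm
    thickness_bump_center: tuple[float, float] | None = None
    n_frames: int = 1
    frame_dt: float = 1000.0  # ps
    lateral_jitter: float = 0.35  # fraction of lattice spacing
    bead_xy_jitter: float = 0.25  # nm: lateral splay of individual beads
    np_z_noise: float = 0.2  # nm
    np_expand_beads: bool = False  # 16-bead shell instead of a single bead
    min_area_per_lipid: float = 0.45  # nm^2, overcrowding guard
    seed: int = 0

    def __post_init__(self) -> None:
        self.box = tuple(float(b) for b in self.box)
        if any(b <= 0 for b in self.box):
            raise ValueError("box lengths must be positive")
        if not 0 <= self.np_colocal_strength <= 1:
            raise ValueError("np_colocal_strength must lie in [0, 1]")
        if not 0 <= self.cluster_fraction <= 1:
            raise ValueError("cluster_fraction must lie in [0, 1]")
        if self.np_count < 0:
            raise ValueError("np_count must be >= 0")
        if self.leaflet_z_offset >= self.box[2] / 2:
            raise ValueError("leaflet_z_offset must be below half the box height")
        if self.np_colocal_target is not None:
            if self.np_colocal_target not in TAIL_DOUBLE_BONDS:
                raise ValueError(f"unknown tail code {self.np_colocal_target!r}")
            codes = self.composition.tail_codes()
            if self.np_colocal_target not in codes:
                raise ValueError(
                    f"tail code {self.np_colocal_target!r} absent from the composition"
                )

    def leaflet_counts(self, leaflet: str) -> dict[str, int]:
        """Copy numbers per residue for one leaflet ('both' split evenly)."""
        out: dict[str, int] = {}
        for e in self.composition:
            if e.count == 0:
                continue
            if e.leaflet == leaflet:
                out[e.residue] = e.count
            elif e.leaflet == "both":
                half = e.count // 2
                out[e.residue] = half + (e.count % 2 if leaflet == "outer" else 0)
        return out


@dataclass
class GroundTruth:
    """Everything the generator planted, for parameter-recovery tests."""

    bead_leaflet: np.ndarray  # per bead: "inner" | "outer" | "np"
    lipid_leaflet: dict[int, str]  # resid -> leaflet
    colocal_target: str | None
    colocal_strength: float
    np_cluster_labels: np.ndarray  # per NP bead; -1 = unclustered
    np_cluster_centers: np.ndarray  # (n_clusters, 3)
    undulation_modes: list[tuple[int, int, float, float]]  # (kx, ky, amp, phase)
    thickness_center: float  # 2 * leaflet_z_offset
    bump: tuple[float, float, float, float] | None  # (cx, cy, height, sigma)
    patch_mask: np.ndarray | None  # target-tail patch mask on patch_grid
    patch_cell: float

    def midplane_height(self, x: np.ndarray, y: np.ndarray, box: Sequence[float]) -> np.ndarray:
        h = np.zeros_like(np.asarray(x, dtype=float))
        for kx, ky, amp, phase in self.undulation_modes:
            h = h + amp * np.cos(2 * np.pi * (kx * x / box[0] + ky * y / box[1]) + phase)
        return h

    def thickness(self, x: np.ndarray, y: np.ndarray, box: Sequence[float]) -> np.ndarray:
        t = np.full_like(np.asarray(x, dtype=float), self.thickness_center)
        if self.bump is not None:
            cx, cy, height, sigma = self.bump
            dx = np.abs(np.asarray(x) - cx)
            dx = np.minimum(dx, box[0] - dx)
            dy = np.abs(np.asarray(y) - cy)
            dy = np.minimum(dy, box[1] - dy)
            t = t + height * np.exp(-(dx**2 + dy**2) / (2 * sigma**2))
        return t

    def to_json(self, path: str | Path) -> None:
        payload = {
            "colocal_target": self.colocal_target,
            "colocal_strength": self.colocal_strength,
            "lipid_leaflet": {str(k): v for k, v in self.lipid_leaflet.items()},
            "np_cluster_labels": self.np_cluster_labels.tolist(),
            "undulation_modes": [list(m) for m in self.undulation_modes],
            "thickness_center": self.thickness_center,
            "bump": list(self.bump) if self.bump else None,
        }
        Path(path).write_text(json.dumps(payload))


# ---------------------------------------------------------------------------
# lateral patch fields

def _patch_fields(
    spec: MembraneSpec, rng: np.random.Generator
) -> tuple[dict[str, np.ndarray], float]:
    """Lateral tail-type domains: a mosaic of Gaussian-random-field patches.

    One smoothed GRF per tail code (correlation length
    ``patch_correlation_length``); each 1 nm cell belongs to the code whose
    shifted field is largest there, with per-code shifts calibrated so each
    domain's area share tracks the code's abundance.  Domains are therefore
    disjoint and can actually be filled by their species, which is what the
    shadow-matrix statistic must detect.  The sterol field is the
    complement of the co-localization target's domain (sterol planted
    anti-correlated with the unsaturated patches).
    """
    cell = 1.0
    gx = max(4, int(round(spec.box[0] / cell)))
    gy = max(4, int(round(spec.box[1] / cell)))
    sigma = spec.patch_correlation_length / cell
    codes = sorted(spec.composition.tail_codes())
    fields = np.stack(
        [
            ndimage.gaussian_filter(rng.standard_normal((gx, gy)), sigma=sigma, mode="wrap")
            for _ in codes
        ]
    )
    fields /= fields.std(axis=(1, 2), keepdims=True)

    # area share target: tail-bead abundance per code
    weights = np.zeros(len(codes))
    for e in spec.composition:
        for code, _ in e.tails:
            weights[codes.index(code)] += e.count
    shares = weights / weights.sum()

    shifts = np.zeros(len(codes))
    for _ in range(60):  # calibrate domain areas to the abundance shares
        lab = np.argmax(fields + shifts[:, None, None], axis=0)
        got = np.bincount(lab.ravel(), minlength=len(codes)) / lab.size
        shifts -= 0.5 * (got - shares) / np.maximum(shares, 1e-3)
    lab = np.argmax(fields + shifts[:, None, None], axis=0)

    masks: dict[str, np.ndarray] = {
        code: (lab == i).astype(float) for i, code in enumerate(codes)
    }
    if spec.np_colocal_target is not None and "CHOL" in spec.composition:
        masks["CHOL"] = 1.0 - masks[spec.np_colocal_target]
    return masks, cell


def _site_weights(
    entry: CompositionEntry,
    masks: dict[str, np.ndarray],
    xy: np.ndarray,
    cell: float,
    patchiness: float,
) -> np.ndarray:
    key = entry.tail1 if entry.tail1 else entry.residue
    mask = masks.get(key)
    if mask is None:
        return np.ones(len(xy))
    ix = np.minimum((xy[:, 0] / cell).astype(int), mask.shape[0] - 1)
    iy = np.minimum((xy[:, 1] / cell).astype(int), mask.shape[1] - 1)
    return (1.0 - patchiness) + patchiness * mask[ix, iy]


def _assign_species(
    counts: dict[str, int],
    comp: Composition,
    xy: np.ndarray,
    masks: dict[str, np.ndarray],
    cell: float,
    patchiness: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Assign residue names to lattice sites, patch-weighted, exact counts.

    Sequential weighted sampling without replacement via the Gumbel trick.
    The sterol is assigned first: its planted field is the complement of
    the target domain, and if the tail species (each confined to its own
    domain) were placed first, the leftover sites for the sterol would be
    concentrated inside the target domain, silently inverting the planted
    anti-correlation.  Tail species follow in shuffled order; their
    domains are disjoint, so order among them is immaterial.
    """
    n = len(xy)
    names = sorted(counts)
    rng.shuffle(names)
    names.sort(key=lambda s: comp[s].headgroup != "CHOL")  # stable: sterols first
    owner = np.full(n, "", dtype=object)
    free = np.ones(n, dtype=bool)
    for name in names:
        c = counts[name]
        idx_free = np.flatnonzero(free)
        if c > len(idx_free):
            raise ValueError("species counts exceed available lattice sites")
        w = _site_weights(comp[name], masks, xy[idx_free], cell, patchiness)
        scores = np.log(np.maximum(w, 1e-12)) + rng.gumbel(size=len(idx_free))
        take = idx_free[np.argsort(scores)[::-1][:c]]
        owner[take] = name
        free[take] = False
    return owner


def _leaflet_lattice(
    spec: MembraneSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """n jittered lattice sites over the lateral box."""
    m = int(np.ceil(np.sqrt(n)))
    sx, sy = spec.box[0] / m, spec.box[1] / m
    ix, iy = np.meshgrid(np.arange(m), np.arange(m), indexing="ij")
    sites = np.stack([(ix.ravel() + 0.5) * sx, (iy.ravel() + 0.5) * sy], axis=1)
    pick = rng.choice(len(sites), size=n, replace=False)
    xy = sites[pick]
    xy = xy + rng.uniform(-spec.lateral_jitter, spec.lateral_jitter, size=xy.shape) * [sx, sy]
    return np.mod(xy, spec.box[:2])


def _sample_patch_xy(
    n: int, mask: np.ndarray, cell: float, box: Sequence[float], rng: np.random.Generator
) -> np.ndarray:
    """Uniform lateral positions over the patch cells of ``mask``."""
    cells = np.argwhere(mask > 0)
    if len(cells) == 0:
        raise ValueError("patch mask is empty; cannot confine nanoparticles")
    pick = cells[rng.integers(0, len(cells), size=n)]
    xy = (pick + rng.uniform(0, 1, size=(n, 2))) * cell
    return np.mod(xy, np.asarray(box[:2]))


#: unit sphere directions for the optional 16-bead nanoparticle shell
def _fullerene_shell(radius: float = 0.35) -> np.ndarray:
    i = np.arange(16)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i  # Fibonacci sphere
    zu = 1.0 - 2.0 * (i + 0.5) / 16
    r = np.sqrt(1.0 - zu**2)
    return radius * np.stack([r * np.cos(phi), r * np.sin(phi), zu], axis=1)


def build_membrane(spec: MembraneSpec) -> tuple[Trajectory, GroundTruth]:
    """Generate a synthetic membrane trajectory and its ground truth.

    Deterministic under ``spec.seed``.  Raises on overcrowded leaflets
    (less than ``min_area_per_lipid`` nm^2 per phospholipid equivalent) and
    on unknown tail codes.
    """
    rng = np.random.default_rng(spec.seed)
    area = spec.box[0] * spec.box[1]
    for leaflet in ("inner", "outer"):
        counts = spec.leaflet_counts(leaflet)
        eff = sum(
            c * (STEROL_AREA if spec.composition[r].headgroup == "CHOL" else PHOSPHOLIPID_AREA)
            for r, c in counts.items()
        )
        eff *= spec.min_area_per_lipid / 0.45
        if eff > area:
            raise ValueError(
                f"{leaflet} leaflet overcrowded: needs {eff:.0f} nm^2 "
                f"of {area:.0f} nm^2 available"
            )
    for e in spec.composition:
        for code, _ in e.tails:
            if code not in TAIL_DOUBLE_BONDS:
                raise ValueError(f"unknown tail code {code!r} on {e.residue}")

    masks, cell = _patch_fields(spec, rng)

    # undulation modes: lowest integer wavevectors, random phases
    wavevectors = [(1, 0), (0, 1), (1, 1), (2, 0), (0, 2), (2, 1), (1, 2), (2, 2)]
    modes = [
        (kx, ky, spec.undulation_amplitude, float(rng.uniform(0, 2 * np.pi)))
        for kx, ky in wavevectors[: spec.undulation_modes]
    ]
    if spec.undulation_amplitude == 0:
        modes = []

    # --- static identity layer (shared by all frames) -----------------------
    leaflet_sites: dict[str, np.ndarray] = {}
    leaflet_owner: dict[str, np.ndarray] = {}
    for leaflet in ("outer", "inner"):
        counts = spec.leaflet_counts(leaflet)
        n = sum(counts.values())
        xy = _leaflet_lattice(spec, n, rng)
        owner = _assign_species(counts, spec.composition, xy, masks, cell, spec.patchiness, rng)
        leaflet_sites[leaflet] = xy
        leaflet_owner[leaflet] = owner

    # nanoparticle lateral law (frame-independent draw of cluster structure)
    n_np = spec.np_count
    n_clustered = int(round(spec.cluster_fraction * n_np))
    sizes = []
    remaining = n_clustered
    while remaining > 0:
        s = min(max(2, spec.cluster_size), remaining)
        sizes.append(s)
        remaining -= s
    n_clusters = len(sizes)

    def _np_xy(n: int) -> np.ndarray:
        if n == 0:
            return np.empty((0, 2))
        target = spec.np_colocal_target
        if target is None or spec.np_colocal_strength == 0:
            return rng.uniform(0, 1, size=(n, 2)) * spec.box[:2]
        from_patch = rng.uniform(0, 1, size=n) < spec.np_colocal_strength
        xy = rng.uniform(0, 1, size=(n, 2)) * spec.box[:2]
        k = int(from_patch.sum())
        if k:
            xy[from_patch] = _sample_patch_xy(k, masks[target], cell, spec.box, rng)
        return xy

    cluster_centers_xy = _np_xy(n_clusters)
    free_xy0 = _np_xy(n_np - n_clustered)
    np_cluster_labels = np.full(n_np, -1, dtype=int)
    pos0 = 0
    for ci, s in enumerate(sizes):
        np_cluster_labels[pos0 : pos0 + s] = ci
        pos0 += s

    bump = None
    if spec.thickness_bump_height != 0:
        if spec.thickness_bump_center is not None:
            cx, cy = spec.thickness_bump_center
        elif n_clusters:
            cx, cy = cluster_centers_xy[0]
        else:
            cx, cy = spec.box[0] / 2, spec.box[1] / 2
        bump = (float(cx), float(cy), spec.thickness_bump_height, spec.thickness_bump_sigma)

    truth = GroundTruth(
        bead_leaflet=np.empty(0, dtype=object),  # filled below
        lipid_leaflet={},
        colocal_target=spec.np_colocal_target,
        colocal_strength=spec.np_colocal_strength,
        np_cluster_labels=np_cluster_labels,
        np_cluster_centers=np.empty((n_clusters, 3)),
        undulation_modes=modes,
        thickness_center=2 * spec.leaflet_z_offset,
        bump=bump,
        patch_mask=masks.get(spec.np_colocal_target) if spec.np_colocal_target else None,
        patch_cell=cell,
    )

    z_mid = spec.box[2] / 2.0

    def _build_frame(fi: int, frng: np.random.Generator) -> Frame:
        positions: list[np.ndarray] = []
        species: list[str] = []
        resids: list[int] = []
        bead_leaflet: list[str] = []
        resid = 0
        for leaflet, sign in (("outer", +1.0), ("inner", -1.0)):
            xy = leaflet_sites[leaflet]
            owner = leaflet_owner[leaflet]
            # small per-frame lateral breathing keeps frames distinct
            jit = frng.normal(0, 0.05, size=xy.shape) if spec.n_frames > 1 else 0.0
            xyf = np.mod(xy + jit, spec.box[:2])
            h = truth.midplane_height(xyf[:, 0], xyf[:, 1], spec.box)
            half_t = truth.thickness(xyf[:, 0], xyf[:, 1], spec.box) / 2.0
            for j in range(len(xyf)):
                resid += 1
                name = owner[j]
                entry = spec.composition[name]
                x, y = xyf[j]
                zp = z_mid + h[j] + sign * half_t[j]
                truth.lipid_leaflet[resid] = leaflet
                if entry.headgroup == "CHOL":
                    beads = [("ROH", zp - sign * 0.2 * half_t[j]), ("R1", zp - sign * 0.6 * half_t[j])]
                else:
                    beads = [("PO4", zp)]
                    for chain, suffix in ((entry.tail1, "A"), (entry.tail2, "B")):
                        if not chain:
                            continue
                        for ti in (1, 2):
                            beads.append(
                                (f"T{ti}{suffix}", zp - sign * half_t[j] * (0.45 * ti))
                            )
                splay = (
                    frng.normal(0, spec.bead_xy_jitter, size=(len(beads), 2))
                    if spec.bead_xy_jitter > 0
                    else np.zeros((len(beads), 2))
                )
                for bi, (bead, z) in enumerate(beads):
                    positions.append(np.array([x + splay[bi, 0], y + splay[bi, 1], z]))
                    species.append(f"{name}:{bead}")
                    resids.append(resid)
                    bead_leaflet.append(leaflet)

        # nanoparticles: clusters keep their centers; free NPs resample
        np_xyz: list[np.ndarray] = []
        for ci, s in enumerate(sizes):
            cx, cy = cluster_centers_xy[ci]
            hz = truth.midplane_height(np.array([cx]), np.array([cy]), spec.box)[0]
            center = np.array([cx, cy, z_mid + hz + spec.np_z_offset])
            truth.np_cluster_centers[ci] = center
            offs = frng.normal(0, 0.3, size=(s, 3))
            offs -= offs.mean(axis=0)  # keep the planted center exact
            np_xyz.extend(center + offs)
        free_xy = free_xy0 if spec.n_frames == 1 else _np_xy(n_np - n_clustered)
        for x, y in free_xy:
            hz = truth.midplane_height(np.array([x]), np.array([y]), spec.box)[0]
            z = z_mid + hz + spec.np_z_offset + frng.normal(0, spec.np_z_noise)
            np_xyz.append(np.array([x, y, z]))
        shell = _fullerene_shell() if spec.np_expand_beads else None
        for k, p in enumerate(np_xyz):
            resid += 1
            if shell is None:
                positions.append(p)
                species.append("NP:C60")
                resids.append(resid)
                bead_leaflet.append("np")
            else:
                for b, off in enumerate(shell):
                    positions.append(p + off)
                    species.append(f"NP:C{b:02d}")
                    resids.append(resid)
                    bead_leaflet.append("np")

        if fi == 0:
            truth.bead_leaflet = np.array(bead_leaflet, dtype=object)
        return Frame(
            np.array(positions),
            np.array(species),
            np.array(resids),
            np.array(spec.box),
            time=fi * spec.frame_dt,
        ).wrapped()

    frames = []
    for fi in range(spec.n_frames):
        frng = np.random.default_rng((spec.seed, 1000 + fi))
        frames.append(_build_frame(fi, frng))
    traj = Trajectory(frames, composition=spec.composition)
    return traj, truth


# ---------------------------------------------------------------------------
# umbrella-sampling data

def sample_umbrella_windows(
    true_potential: Callable[[np.ndarray], np.ndarray] | tuple[np.ndarray, np.ndarray],
    centers: Sequence[float],
    force_const: float,
    n_samples: int,
    temperature: float = 298.0,
    seed: int = 0,
    proposal_scale: float | None = None,
) -> list[UmbrellaWindow]:
    """Draw biased samples from exp(-[U(z) + 1/2 k (z-c)^2]/kT) per window.

    ``true_potential`` is a callable U(z) in kJ/mol or a tabulated
    ``(z, U)`` pair (linearly interpolated).  Sampling is Metropolis with a
    Gaussian proposal, 10x thinning and 10% burn-in, vectorized across
    windows; deterministic under ``seed``.
    """
    centers = np.asarray(centers, dtype=float)
    if len(centers) == 0:
        raise ValueError("need at least one window center")
    if np.any(np.diff(centers) <= 0):
        raise ValueError("centers must be strictly increasing")
    if force_const <= 0:
        raise ValueError("force_const must be positive")
    if n_samples < 100:
        raise ValueError("n_samples must be at least 100")
    kT = KB * temperature

    if callable(true_potential):
        U = true_potential
    else:
        z_tab, u_tab = (np.asarray(a, dtype=float) for a in true_potential)
        if not np.all(np.isfinite(u_tab)):
            raise ValueError("tabulated potential contains non-finite values")
        U = lambda z: np.interp(z, z_tab, u_tab)

    sigma_bias = np.sqrt(kT / force_const)
    # normalizability check: total potential must rise toward the support edges
    span = centers.max() - centers.min() + 8 * sigma_bias
    zz = np.linspace(centers.min() - span, centers.max() + span, 512)
    probe = U(zz) + 0.5 * force_const * (zz - centers.mean()) ** 2
    if not np.all(np.isfinite(probe)):
        raise ValueError("total potential non-finite on the sampling support")

    step = proposal_scale if proposal_scale is not None else 2.0 * sigma_bias
    rng = np.random.default_rng(seed)
    nwin = len(centers)
    thin, burn_frac = 10, 0.10
    n_prod = n_samples * thin
    n_burn = int(burn_frac * n_prod)

    z = centers.copy()
    e = U(z) + 0.5 * force_const * (z - centers) ** 2
    kept = np.empty((n_samples, nwin))
    ki = 0
    for it in range(n_burn + n_prod):
        prop = z + rng.normal(0, step, size=nwin)
        e_prop = U(prop) + 0.5 * force_const * (prop - centers) ** 2
        accept = rng.uniform(size=nwin) < np.exp(np.minimum(0.0, -(e_prop - e) / kT))
        z = np.where(accept, prop, z)
        e = np.where(accept, e_prop, e)
        it_prod = it - n_burn
        if it_prod >= 0 and (it_prod + 1) % thin == 0:
            kept[ki] = z
            ki += 1
    return [
        UmbrellaWindow(center=float(c), force_const=float(force_const), samples=kept[:, i])
        for i, c in enumerate(centers)
    ]
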