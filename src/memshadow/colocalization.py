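"""Shadow-matrix construction and the MSE co-localization statistic.

The lateral plane of the membrane is gridded (default 0.5 nm cells).  For a
chosen species, one frame yields a binary "shadow" occupancy matrix: a cell
is 1 if at least one selected bead's (x, y) falls inside it, else 0.  Two
species' lateral distributions are compared by the mean square error between
their shadow matrices, which for binary matrices is exactly the fraction of
mismatched cells: 0 means identical lateral localization, values near 1 mean
the two species tile disjoint regions.

Because the nanoparticles sit near the bilayer center, the default scope
pools beads from both leaflets into one matrix.  Ranking every lipid-tail
species by its mean MSE against the nanoparticle reference (averaged over
frames) produces the co-localization table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .trajectory_io import Composition, Frame, Trajectory, residue_bead_labels, tail_bead_labels

__all__ = [
    "GridSpec2D",
    "ShadowMatrix",
    "shadow_matrix",
    "mse",
    "colocalization_table",
    "default_targets",
]


@dataclass(frozen=True)
class GridSpec2D:
    """Fixed lateral grid: nx x ny cells over a box_x x box_y plane (nm)."""

    spacing: float
    nx: int
    ny: int
    box_x: float
    box_y: float

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("grid spacing must be positive")
        if self.nx != math.ceil(self.box_x / self.spacing) or self.ny != math.ceil(
            self.box_y / self.spacing
        ):
            raise ValueError("nx, ny must equal ceil(box / spacing)")

    @classmethod
    def from_box(cls, box_x: float, box_y: float, spacing: float = 0.5) -> "GridSpec2D":
        return cls(
            spacing=spacing,
            nx=math.ceil(box_x / spacing),
            ny=math.ceil(box_y / spacing),
            box_x=float(box_x),
            box_y=float(box_y),
        )

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nx, self.ny)

    def cell_indices(self, xy: np.ndarray, box_xy: np.ndarray | None = None) -> np.ndarray:
        """Map (x, y) coordinates to integer cell indices.

        If the frame's instantaneous box differs (barostat fluctuations),
        its coordinates are binned in fractional units so every frame maps
        onto the same nx x ny cell topology.
        """
        if box_xy is None:
            box_xy = np.array([self.box_x, self.box_y])
        frac = np.mod(xy / box_xy, 1.0)
        ix = np.minimum((frac[:, 0] * self.nx).astype(int), self.nx - 1)
        iy = np.minimum((frac[:, 1] * self.ny).astype(int), self.ny - 1)
        return np.stack([ix, iy], axis=1)


@dataclass
class ShadowMatrix:
    grid: GridSpec2D
    values: np.ndarray  # (nx, ny) of {0, 1}
    species: str = ""
    frame_index: int = -1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.shape != self.grid.shape:
            raise ValueError("shadow-matrix dimensions must match the grid")
        uniq = np.unique(self.values)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("shadow matrix must be binary")

    @property
    def occupancy(self) -> float:
        """Fraction of occupied cells."""
        return float(self.values.mean())


def shadow_matrix(
    frame: Frame,
    species_selector: set[str] | Sequence[str],
    grid: GridSpec2D,
    leaflet_scope: str = "both",
    leaflet_labels: np.ndarray | None = None,
    species_name: str = "",
    frame_index: int = -1,
) -> ShadowMatrix:
    """Binary lateral occupancy of the selected beads on ``grid``.

    ``leaflet_scope`` of ``"both"`` pools beads from both leaflets; to
    restrict to one leaflet pass per-bead ``leaflet_labels`` ("inner"/"outer")
    alongside scope "inner" or "outer".
    """
    mask = frame.select(species_selector)
    if not mask.any():
        raise ValueError(f"selector {sorted(set(species_selector))[:5]}... matches no beads")
    if leaflet_scope not in ("both", "inner", "outer"):
        raise ValueError("leaflet_scope must be both|inner|outer")
    if leaflet_scope != "both":
        if leaflet_labels is None:
            raise ValueError("per-bead leaflet labels required for a single-leaflet scope")
        mask &= np.asarray(leaflet_labels) == leaflet_scope
        if not mask.any():
            raise ValueError(f"selector matches no beads in the {leaflet_scope} leaflet")
    xy = np.mod(frame.positions[mask, :2], frame.box[:2])
    idx = grid.cell_indices(xy, frame.box[:2])
    values = np.zeros(grid.shape, dtype=np.int8)
    values[idx[:, 0], idx[:, 1]] = 1
    return ShadowMatrix(grid, values, species=species_name, frame_index=frame_index)


def mse(a: ShadowMatrix, b: ShadowMatrix) -> float:
    """Mean square error between two shadow matrices on the same grid.

    For binary matrices this is the fraction of mismatched cells; 0 means
    the two species occupy exactly the same cells, 1 means they are
    complementary everywhere.
    """
    if a.grid != b.grid:
        raise ValueError("shadow matrices live on different grids")
    diff = a.values.astype(np.float64) - b.values.astype(np.float64)
    return float(np.mean(diff * diff))


def default_targets(comp: Composition, frame: Frame, sterol_residue: str = "CHOL") -> dict[str, set[str]]:
    """Tail-code selectors for every tail in the composition, plus the sterol.

    Tail selectors use acyl-chain beads only; the sterol target uses all of
    its beads.  Labels absent from the frame are dropped per target.
    """
    present = set(frame.species)
    targets: dict[str, set[str]] = {}
    for code in comp.tail_codes():
        labels = tail_bead_labels(comp, code) & present
        if labels:
            targets[code] = labels
    if sterol_residue in comp:
        try:
            targets[sterol_residue] = residue_bead_labels(frame, sterol_residue)
        except ValueError:
            pass
    return targets


def colocalization_table(
    traj: Trajectory,
    reference: set[str] | Sequence[str],
    targets: Mapping[str, set[str]],
    grid_spacing: float = 0.5,
    frame_range: slice | None = None,
    leaflet_scope: str = "both",
    mode: str = "per-frame",
    top_k: int = 5,
) -> pd.DataFrame:
    """Ranked co-localization table of mean MSE against a reference species.

    Per frame, reference and target shadow matrices are built on the grid
    fixed by frame 0's box and compared by MSE; each target is reported as
    mean +/- standard error over frames, sorted ascending (smallest MSE =
    strongest co-localization first).  ``mode="averaged"`` instead compares
    time-averaged occupancies thresholded back to binary (seen-at-least-once).

    Columns: species, mean_mse, se_mse, rank, top5_smallest, top5_largest,
    tied (ties broken by species label, lexicographic).
    """
    frames = traj.frames[frame_range] if frame_range is not None else traj.frames
    if not frames:
        raise ValueError("empty frame range")
    if not targets:
        raise ValueError("no targets given")
    if mode not in ("per-frame", "averaged"):
        raise ValueError("mode must be per-frame|averaged")
    grid = GridSpec2D.from_box(frames[0].box[0], frames[0].box[1], grid_spacing)

    names = list(targets)
    if mode == "per-frame":
        per_frame = np.empty((len(frames), len(names)))
        for fi, fr in enumerate(frames):
            ref_m = shadow_matrix(fr, reference, grid, leaflet_scope, frame_index=fi)
            for ti, name in enumerate(names):
                tgt_m = shadow_matrix(fr, targets[name], grid, leaflet_scope,
                                      species_name=name, frame_index=fi)
                per_frame[fi, ti] = mse(ref_m, tgt_m)
        means = per_frame.mean(axis=0)
        ses = (
            per_frame.std(axis=0, ddof=1) / math.sqrt(len(frames))
            if len(frames) > 1
            else np.zeros(len(names))
        )
    else:
        ref_any = np.zeros(grid.shape, dtype=np.int8)
        tgt_any = {n: np.zeros(grid.shape, dtype=np.int8) for n in names}
        for fi, fr in enumerate(frames):
            ref_any |= shadow_matrix(fr, reference, grid, leaflet_scope).values
            for n in names:
                tgt_any[n] |= shadow_matrix(fr, targets[n], grid, leaflet_scope).values
        ref_m = ShadowMatrix(grid, ref_any)
        means = np.array([mse(ref_m, ShadowMatrix(grid, tgt_any[n])) for n in names])
        ses = np.zeros(len(names))

    df = pd.DataFrame({"species": names, "mean_mse": means, "se_mse": ses})
    df = df.sort_values(["mean_mse", "species"], kind="mergesort").reset_index(drop=True)
    df["rank"] = np.arange(1, len(df) + 1)
    df["tied"] = df["mean_mse"].duplicated(keep=False)
    k = min(top_k, len(df))
    df["top5_smallest"] = df["rank"] <= k
    df["top5_largest"] = df["rank"] > len(df) - k
    return df


def expected_random_mse(p: float, q: float) -> float:
    """Expected MSE of two independent random binary matrices.

    With i.i.d. cell occupancy probabilities p and q, a cell mismatches with
    probability p(1-q) + q(1-p).
    """
    return p * (1.0 - q) + q * (1.0 - p)
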