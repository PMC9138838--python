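"""Leaflet assignment, density profiles, lateral maps and undulation metrics.

All analyses share one geometric idea: the bilayer midplane is a slowly
varying height field h(x, y).  Phosphate (PO4) beads are first split into
inner/outer populations against the global phosphate mean, then a local
midplane is estimated per lateral cell as the average of the two leaflets'
mean phosphate heights (leaflet-aware, so a flat bilayer yields the exact
midplane regardless of how many lipids of each leaflet fall in a cell).
Lipids are assigned to the leaflet on their side of the local midplane;
local thickness is the outer-minus-inner phosphate plane separation per
cell; undulations are the RMS and cosine-mode spectrum of h.

z-density profiles are re-centered per frame to the instantaneous bilayer
center so the bilayer center sits at z = 0, matching the convention of
plotting phosphate and nanoparticle densities against the membrane normal.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .colocalization import GridSpec2D
from .trajectory_io import (
    NON_LIPID_RESIDUES,
    Composition,
    Frame,
    Trajectory,
    bead_name_labels,
)

__all__ = [
    "DensityProfile",
    "EnrichmentMap",
    "ThicknessMap",
    "UnsaturationHistogram",
    "assign_leaflets",
    "density_profile",
    "enrichment_map",
    "thickness_map",
    "undulation_metric",
    "unsaturation_histogram",
]

PHOSPHATE_BEADS = ("PO4",)


# ---------------------------------------------------------------------------
# midplane machinery

def _phosphate_mask(frame: Frame, phosphate_selector: set[str] | None) -> np.ndarray:
    if phosphate_selector is None:
        phosphate_selector = bead_name_labels(frame, PHOSPHATE_BEADS)
    mask = frame.select(phosphate_selector)
    if mask.sum() < 2:
        raise ValueError("need at least 2 phosphate beads")
    return mask


def _midplane_field(
    frame: Frame,
    phos_mask: np.ndarray,
    cell: float = 2.0,
    smooth: int = 3,
) -> tuple[GridSpec2D, np.ndarray, np.ndarray]:
    """Local midplane and half-separation per lateral cell.

    Returns (grid, midplane, half_thickness); cells with no phosphate of one
    leaflet within the smoothing footprint fall back to that leaflet's
    global mean (with a warning).
    """
    pos = frame.positions[phos_mask]
    z = pos[:, 2]
    z0 = z.mean()
    outer = z >= z0
    grid = GridSpec2D.from_box(frame.box[0], frame.box[1], cell)
    idx = grid.cell_indices(pos[:, :2], frame.box[:2])
    flat = idx[:, 0] * grid.ny + idx[:, 1]
    ncell = grid.nx * grid.ny

    means = {}
    warned = False
    for name, sel in (("outer", outer), ("inner", ~outer)):
        ssum = (
            np.bincount(flat[sel], weights=z[sel], minlength=ncell)
            .reshape(grid.shape)
            .astype(float)
        )
        cnt = np.bincount(flat[sel], minlength=ncell).reshape(grid.shape).astype(float)
        fallback = z[sel].mean() if sel.any() else z.mean()
        ssum = ndimage.uniform_filter(ssum, size=smooth, mode="wrap")
        cnt = ndimage.uniform_filter(cnt, size=smooth, mode="wrap")
        covered = cnt > 0
        mean = np.where(
            covered,
            np.divide(ssum, cnt, where=covered, out=np.zeros_like(ssum)),
            fallback,
        )
        if not covered.all() and not warned:
            warnings.warn(
                "lateral cells without phosphates in the smoothing radius; "
                "falling back to the global midplane there",
                RuntimeWarning,
            )
            warned = True
        means[name] = mean
    midplane = 0.5 * (means["outer"] + means["inner"])
    half = 0.5 * (means["outer"] - means["inner"])
    return grid, midplane, half


def _lookup(grid: GridSpec2D, field: np.ndarray, xy: np.ndarray, box_xy: np.ndarray) -> np.ndarray:
    idx = grid.cell_indices(xy, box_xy)
    return field[idx[:, 0], idx[:, 1]]


def assign_leaflets(
    frame: Frame,
    phosphate_selector: set[str] | None = None,
    cell: float = 2.0,
    smooth: int = 3,
) -> pd.Series:
    """Per-lipid leaflet labels ("inner"/"outer"), indexed by residue id.

    Each lipid is placed by its phosphate bead (or its mean bead position
    for sterols and other phosphate-free species) and labeled by the side
    of the local midplane it sits on.  Water/ion/nanoparticle residues are
    excluded.
    """
    phos_mask = _phosphate_mask(frame, phosphate_selector)
    grid, midplane, _ = _midplane_field(frame, phos_mask, cell, smooth)

    resnames = frame.resnames
    lipid_mask = ~np.isin(resnames, sorted(NON_LIPID_RESIDUES))
    if not lipid_mask.any():
        raise ValueError("no lipid beads in the frame")
    df = pd.DataFrame(
        {
            "resid": frame.resids[lipid_mask],
            "x": frame.positions[lipid_mask, 0],
            "y": frame.positions[lipid_mask, 1],
            "z": frame.positions[lipid_mask, 2],
            "phos": phos_mask[lipid_mask],
        }
    )
    # representative position: the phosphate bead when present, else all beads
    def _rep(g: pd.DataFrame) -> pd.Series:
        sub = g[g["phos"]] if g["phos"].any() else g
        return pd.Series({"x": sub["x"].mean(), "y": sub["y"].mean(), "z": sub["z"].mean()})

    rep = df.groupby("resid").apply(_rep, include_groups=False)
    mid = _lookup(grid, midplane, rep[["x", "y"]].to_numpy(), frame.box[:2])
    labels = np.where(rep["z"].to_numpy() >= mid, "outer", "inner")
    return pd.Series(labels, index=rep.index, name="leaflet")


# ---------------------------------------------------------------------------
# z-density profiles

@dataclass
class DensityProfile:
    bin_edges: np.ndarray  # nm, bilayer-center frame
    counts: dict[str, np.ndarray]  # mean bead count per bin per frame
    n_frames: int
    lateral_area: float  # nm^2

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def number_density(self, name: str) -> np.ndarray:
        """beads per nm^3."""
        return self.counts[name] / (self.bin_width * self.lateral_area)

    def to_frame(self) -> pd.DataFrame:
        out = {"z_nm": self.bin_centers}
        for name, c in self.counts.items():
            out[f"count_{name}"] = c
            out[f"density_{name}"] = self.number_density(name)
        return pd.DataFrame(out)


def density_profile(
    traj: Trajectory,
    selectors: Mapping[str, set[str]],
    bin_width: float = 0.1,
    center_mode: str = "phosphate",
    phosphate_selector: set[str] | None = None,
) -> DensityProfile:
    """Per-species bead-count profiles along z, re-centered per frame.

    ``center_mode``: "phosphate" centers each frame on the mean phosphate z
    (the instantaneous bilayer center); "box" uses box_z / 2; "none" leaves
    coordinates as read.  The profile integral conserves the selected bead
    count exactly: sum(counts) equals the mean per-frame selection size.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not selectors:
        raise ValueError("no selectors given")
    if center_mode not in ("phosphate", "box", "none"):
        raise ValueError("center_mode must be phosphate|box|none")

    per_frame_z: dict[str, list[np.ndarray]] = {n: [] for n in selectors}
    for fr in traj:
        if center_mode == "phosphate":
            phos = _phosphate_mask(fr, phosphate_selector)
            center = fr.positions[phos, 2].mean()
        elif center_mode == "box":
            center = fr.box[2] / 2.0
        else:
            center = 0.0
        for name, sel in selectors.items():
            mask = fr.select(sel)
            if not mask.any():
                raise ValueError(f"selector {name!r} matches no beads")
            per_frame_z[name].append(fr.positions[mask, 2] - center)

    zmin = min(z.min() for zs in per_frame_z.values() for z in zs)
    zmax = max(z.max() for zs in per_frame_z.values() for z in zs)
    lo = math.floor(zmin / bin_width) * bin_width
    nbin = max(1, math.ceil((zmax - lo) / bin_width + 1e-9))
    edges = lo + bin_width * np.arange(nbin + 1)

    counts = {}
    for name, zs in per_frame_z.items():
        h = np.zeros(nbin)
        for z in zs:
            h += np.histogram(z, bins=edges)[0]
        counts[name] = h / len(traj)
    return DensityProfile(edges, counts, len(traj), float(traj[0].box[0] * traj[0].box[1]))


# ---------------------------------------------------------------------------
# lateral maps

@dataclass
class EnrichmentMap:
    grid: GridSpec2D
    values: np.ndarray  # local density / lateral mean; mean exactly 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values)


def enrichment_map(
    traj: Trajectory,
    species_selector: set[str] | Sequence[str],
    grid_spacing: float = 0.5,
    leaflet_scope: str = "both",
    leaflet_labels: np.ndarray | None = None,
) -> EnrichmentMap:
    """Time-averaged lateral bead counts per cell, normalized by the mean.

    Values above 1 mark lateral enrichment, below 1 depletion; the map mean
    is exactly 1 by construction.
    """
    grid = GridSpec2D.from_box(traj[0].box[0], traj[0].box[1], grid_spacing)
    acc = np.zeros(grid.shape)
    for fr in traj:
        mask = fr.select(species_selector)
        if leaflet_scope != "both":
            if leaflet_labels is None:
                raise ValueError("leaflet labels required for single-leaflet scope")
            mask &= np.asarray(leaflet_labels) == leaflet_scope
        if not mask.any():
            raise ValueError("selector matches no beads")
        idx = grid.cell_indices(fr.positions[mask, :2], fr.box[:2])
        np.add.at(acc, (idx[:, 0], idx[:, 1]), 1.0)
    total = acc.sum()
    if total == 0:
        raise ValueError("zero total density")
    return EnrichmentMap(grid, acc / acc.mean())


@dataclass
class ThicknessMap:
    grid: GridSpec2D
    values: np.ndarray  # nm; nan on uncovered cells
    coverage: np.ndarray  # bool

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.values))


def thickness_map(
    traj: Trajectory,
    phosphate_selector: set[str] | None = None,
    grid_spacing: float = 1.0,
) -> ThicknessMap:
    """Local bilayer thickness: outer minus inner mean phosphate z per cell,
    time-averaged.  Cells never visited by both leaflets are masked."""
    grid = GridSpec2D.from_box(traj[0].box[0], traj[0].box[1], grid_spacing)
    ncell = grid.nx * grid.ny
    sums = {"outer": np.zeros(ncell), "inner": np.zeros(ncell)}
    cnts = {"outer": np.zeros(ncell), "inner": np.zeros(ncell)}
    for fr in traj:
        phos = _phosphate_mask(fr, phosphate_selector)
        pos = fr.positions[phos]
        z = pos[:, 2]
        mgrid, midplane, _ = _midplane_field(fr, phos)
        side = z >= _lookup(mgrid, midplane, pos[:, :2], fr.box[:2])
        idx = grid.cell_indices(pos[:, :2], fr.box[:2])
        flat = idx[:, 0] * grid.ny + idx[:, 1]
        for name, sel in (("outer", side), ("inner", ~side)):
            sums[name] += np.bincount(flat[sel], weights=z[sel], minlength=ncell)
            cnts[name] += np.bincount(flat[sel], minlength=ncell)
    covered = (cnts["outer"] > 0) & (cnts["inner"] > 0)
    if not covered.any():
        raise ValueError("no lateral cell contains phosphates of both leaflets")
    with np.errstate(invalid="ignore", divide="ignore"):
        thick = sums["outer"] / cnts["outer"] - sums["inner"] / cnts["inner"]
    values = np.where(covered, thick, np.nan).reshape(grid.shape)
    return ThicknessMap(grid, values, covered.reshape(grid.shape))


# ---------------------------------------------------------------------------
# undulations

def undulation_metric(
    traj: Trajectory,
    phosphate_selector: set[str] | None = None,
    cell: float = 2.0,
) -> tuple[float, pd.DataFrame]:
    """RMS midplane height and cosine-mode amplitude spectrum.

    The midplane height field h(x, y) is estimated per frame (leaflet-aware
    cell means); RMS is of h minus its lateral mean, averaged over frames.
    The spectrum reports, per integer wavevector (kx, ky) up to 4, the
    cosine amplitude 2|H(k)| / Ncells, frame-averaged.
    """
    rms_acc = 0.0
    amp_acc: np.ndarray | None = None
    for fr in traj:
        phos = _phosphate_mask(fr, phosphate_selector)
        grid, midplane, _ = _midplane_field(fr, phos, cell=cell, smooth=1)
        h = midplane - midplane.mean()
        rms_acc += float(np.sqrt(np.mean(h**2)))
        F = np.fft.fft2(h) / h.size
        if amp_acc is None:
            amp_acc = np.zeros_like(F, dtype=float)
        amp_acc += 2.0 * np.abs(F)
    rms = rms_acc / len(traj)
    amp = amp_acc / len(traj)
    kmax = min(4, amp.shape[0] - 1, amp.shape[1] - 1)
    rows = [
        {"kx": kx, "ky": ky, "amplitude_nm": float(amp[kx, ky])}
        for kx in range(kmax + 1)
        for ky in range(kmax + 1)
        if (kx, ky) != (0, 0)
    ]
    return rms, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# tail unsaturation

@dataclass
class UnsaturationHistogram:
    fractions: pd.DataFrame  # index: leaflet, columns: 0..6 double bonds

    def mean_unsaturation(self, leaflet: str) -> float:
        f = self.fractions.loc[leaflet]
        return float((f * f.index.to_numpy()).sum())


def unsaturation_histogram(composition: Composition) -> UnsaturationHistogram:
    """Mole fraction of lipid tails per double-bond class, by leaflet.

    Each acyl chain of each lipid contributes its copy number to its
    double-bond class (0-6); species assigned to 'both' leaflets split their
    count evenly.  Sterols carry no acyl chains and do not contribute.
    """
    counts = {"inner": np.zeros(7), "outer": np.zeros(7)}
    for e in composition:
        if not e.tails or e.count == 0:
            continue
        shares = (
            [("inner", e.count / 2), ("outer", e.count / 2)]
            if e.leaflet == "both"
            else [(e.leaflet, float(e.count))]
        )
        for leaflet, n in shares:
            if leaflet not in counts:
                continue
            for _, db in e.tails:
                counts[leaflet][db] += n
    for leaflet, c in counts.items():
        if c.sum() == 0:
            raise ValueError(f"leaflet {leaflet!r} has no lipid tails")
    frac = pd.DataFrame(
        {db: [counts["inner"][db] / counts["inner"].sum(),
              counts["outer"][db] / counts["outer"].sum()]
         for db in range(7)},
        index=["inner", "outer"],
    )
    return UnsaturationHistogram(frac)
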