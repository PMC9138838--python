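"""Weighted histogram analysis (WHAM) for 1D umbrella-sampling data.

Each umbrella window restrains the reaction coordinate z (distance along the
membrane normal, nm) with a harmonic bias U_i(z) = 1/2 k_i (z - c_i)^2 and
contributes a histogram n_i(z).  The unbiased probability follows the
self-consistent equations

    P(z)  =  sum_i n_i(z)  /  sum_i N_i exp[(f_i - U_i(z)) / kT]
    f_i   =  -kT ln sum_z P(z) exp(-U_i(z) / kT)

iterated to a fixed point; the potential of mean force is G(z) = -kT ln P(z),
shifted so its mean over a declared reference region (by default the
outermost 0.5 nm of coverage on the high-z side, i.e. bulk water) is zero.
Statistical errors come from an ordinary within-window bootstrap: each
window's samples are resampled with replacement, WHAM is re-solved per
replicate, and the per-bin standard deviation across replicates is reported.

All energies are kJ/mol, force constants kJ mol^-1 nm^-2, temperatures K.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

__all__ = [
    "KB",
    "UmbrellaWindow",
    "PMFProfile",
    "wham_solve",
    "bootstrap_pmf",
    "pmf_minimum",
    "read_windows",
    "write_pmf",
]

KB = 0.008314462618  # kJ mol^-1 K^-1


@dataclass
class UmbrellaWindow:
    center: float  # nm
    force_const: float  # kJ mol^-1 nm^-2; 0 = unbiased window
    samples: np.ndarray  # z values, nm

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.force_const < 0:
            raise ValueError("force constant must be >= 0")
        if self.samples.size == 0:
            raise ValueError("window has no samples")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    def bias(self, z: np.ndarray) -> np.ndarray:
        return 0.5 * self.force_const * (np.asarray(z) - self.center) ** 2


@dataclass
class PMFProfile:
    z: np.ndarray  # bin centers, nm
    free_energy: np.ndarray  # kJ/mol, nan on uncovered bins
    se: np.ndarray | None  # bootstrap SE, kJ/mol
    temperature: float  # K
    reference: tuple[float, float]  # z range where <G> = 0
    f_window: np.ndarray | None = None  # converged per-window free energies
    residual: float = np.nan
    n_iter: int = 0

    @property
    def covered(self) -> np.ndarray:
        return np.isfinite(self.free_energy)


def _bin_edges(windows: Sequence[UmbrellaWindow], bin_width: float) -> np.ndarray:
    lo = min(w.samples.min() for w in windows)
    hi = max(w.samples.max() for w in windows)
    lo = np.floor(lo / bin_width) * bin_width
    nbin = max(1, int(np.ceil((hi - lo) / bin_width + 1e-9)))
    return lo + bin_width * np.arange(nbin + 1)


def _check_overlap(windows: Sequence[UmbrellaWindow], hists: np.ndarray) -> None:
    order = np.argsort([w.center for w in windows])
    for a, b in zip(order[:-1], order[1:]):
        if not np.any((hists[a] > 0) & (hists[b] > 0)):
            warnings.warn(
                f"umbrella windows at z={windows[a].center:.3f} and "
                f"z={windows[b].center:.3f} nm share no histogram bins; "
                "the profile may be disconnected",
                RuntimeWarning,
            )


def wham_solve(
    windows: Sequence[UmbrellaWindow],
    bin_width: float = 0.05,
    temperature: float = 298.0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    reference: tuple[float, float] | None = None,
    edges: np.ndarray | None = None,
    f_init: np.ndarray | None = None,
    _check: bool = True,
) -> PMFProfile:
    """Self-consistent WHAM solution over all windows.

    ``reference`` is the z range whose mean free energy is pinned to zero;
    ``None`` selects the outermost 0.5 nm of covered bins on the high-z end.
    ``edges``/``f_init`` let callers (the bootstrap) fix the binning and warm
    start the iteration.  Raises if the fixed point is not reached within
    ``max_iter`` (the residual is reported).
    """
    if not windows:
        raise ValueError("need at least one umbrella window")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    kT = KB * temperature
    if edges is None:
        edges = _bin_edges(windows, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    nwin, nbin = len(windows), len(centers)

    hists = np.stack([np.histogram(w.samples, bins=edges)[0] for w in windows])
    if _check:
        _check_overlap(windows, hists)
    n_tot = hists.sum(axis=0).astype(float)
    covered = n_tot > 0
    N = hists.sum(axis=1).astype(float)  # samples per window

    # bias energies over bins, in units of kT
    U = np.stack([w.bias(centers) for w in windows]) / kT
    logN = np.log(N)
    log_ntot = np.where(covered, np.log(n_tot, where=covered, out=np.zeros(nbin)), -np.inf)

    f = np.zeros(nwin) if f_init is None else np.array(f_init, dtype=float)  # in kT
    residual = np.inf
    for it in range(1, max_iter + 1):
        # log denominator per bin: logsumexp_i [ log N_i + f_i - U_i(z) ]
        log_denom = logsumexp(logN[:, None] + f[:, None] - U, axis=0)
        logP = np.where(covered, log_ntot - log_denom, -np.inf)
        f_new = -logsumexp(logP[None, :] - U, axis=1)
        f_new -= f_new[0]
        residual = float(np.max(np.abs(f_new - f) / (1.0 + np.abs(f))))
        f = f_new
        if residual < tol:
            break
    else:
        raise RuntimeError(
            f"WHAM did not converge in {max_iter} iterations (residual {residual:.3e})"
        )

    log_denom = logsumexp(logN[:, None] + f[:, None] - U, axis=0)
    with np.errstate(divide="ignore"):
        G = np.where(covered, -kT * (log_ntot - log_denom), np.nan)

    if reference is None:
        z_cov = centers[covered]
        reference = (float(z_cov.max() - 0.5), float(z_cov.max()))
    ref_mask = covered & (centers >= reference[0]) & (centers <= reference[1])
    if not ref_mask.any():
        raise ValueError(f"reference region {reference} contains no covered bins")
    G = G - np.nanmean(G[ref_mask])

    return PMFProfile(
        z=centers,
        free_energy=G,
        se=None,
        temperature=temperature,
        reference=reference,
        f_window=f * kT,
        residual=residual,
        n_iter=it,
    )


def bootstrap_pmf(
    windows: Sequence[UmbrellaWindow],
    n_boot: int = 200,
    seed: int = 0,
    bin_width: float = 0.05,
    temperature: float = 298.0,
    tol: float = 1e-7,
    max_iter: int = 100_000,
    reference: tuple[float, float] | None = None,
    block_length: int = 1,
) -> PMFProfile:
    """WHAM profile with within-window bootstrap standard errors.

    Each replicate resamples every window's z values with replacement
    (``block_length`` > 1 resamples contiguous blocks instead, for
    autocorrelated samples), re-solves WHAM on the shared binning, and SE is
    the per-bin standard deviation across replicates.  Deterministic under a
    fixed seed.
    """
    if n_boot < 20:
        raise ValueError("n_boot must be at least 20")
    rng = np.random.default_rng(seed)
    edges = _bin_edges(windows, bin_width)
    base = wham_solve(
        windows, bin_width, temperature, tol, max_iter, reference, edges=edges
    )
    f_warm = base.f_window / (KB * temperature)

    reps = np.full((n_boot, len(base.z)), np.nan)
    for b in range(n_boot):
        rep_windows = []
        for w in windows:
            n = w.n_samples
            if block_length <= 1:
                pick = rng.integers(0, n, size=n)
            else:
                n_blocks = int(np.ceil(n / block_length))
                starts = rng.integers(0, n, size=n_blocks)
                pick = (starts[:, None] + np.arange(block_length)[None, :]).ravel() % n
                pick = pick[:n]
            rep_windows.append(UmbrellaWindow(w.center, w.force_const, w.samples[pick]))
        prof = wham_solve(
            rep_windows,
            bin_width,
            temperature,
            tol,
            max_iter,
            reference=base.reference,
            edges=edges,
            f_init=f_warm,
            _check=False,
        )
        reps[b] = prof.free_energy

    n_ok = np.isfinite(reps).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        se = np.nanstd(reps, axis=0, ddof=1)
    se[n_ok < 2] = np.nan
    se[~base.covered] = np.nan
    return PMFProfile(
        z=base.z,
        free_energy=base.free_energy,
        se=se,
        temperature=temperature,
        reference=base.reference,
        f_window=base.f_window,
        residual=base.residual,
        n_iter=base.n_iter,
    )


def pmf_minimum(profile: PMFProfile, refine: bool = False) -> dict:
    """Global minimum of the profile: depth (kJ/mol, relative to the zero
    reference) and position (nm).

    ``refine=True`` fits a parabola through the minimum bin and its covered
    neighbors for sub-bin position resolution.  A minimum on the edge of the
    covered range is flagged ``boundary_minimum``.
    """
    cov = profile.covered
    if not cov.any():
        raise ValueError("profile has no covered bins")
    idx_cov = np.flatnonzero(cov)
    i = idx_cov[np.argmin(profile.free_energy[idx_cov])]
    depth = float(profile.free_energy[i])
    position = float(profile.z[i])
    boundary = i == idx_cov[0] or i == idx_cov[-1]
    if refine and not boundary and cov[i - 1] and cov[i + 1]:
        z3 = profile.z[i - 1 : i + 2]
        g3 = profile.free_energy[i - 1 : i + 2]
        a, b, c = np.polyfit(z3, g3, 2)
        if a > 0:
            position = float(-b / (2 * a))
            depth = float(c - b**2 / (4 * a))
    return {"depth": depth, "position": position, "boundary_minimum": bool(boundary)}


# ---------------------------------------------------------------------------
# window file I/O (one delimited file per window, or a manifest of paths)

def read_windows(manifest: str) -> list[UmbrellaWindow]:
    """Read windows from a manifest: one window-file path per line.

    Each window file: header line ``center,force_const`` then values, then
    one sample (z in nm) per line.
    """
    from pathlib import Path

    man = Path(manifest)
    windows = []
    for rel in man.read_text().split():
        p = man.parent / rel
        lines = p.read_text().split()
        if lines[0].replace(",", " ").split()[0] == "center":
            header = lines[1]
        else:
            header = lines[0]
        c, k = (float(v) for v in header.replace(",", " ").split()[:2])
        samples = np.array([float(v) for v in lines[2:]])
        windows.append(UmbrellaWindow(c, k, samples))
    return windows


def write_pmf(profile: PMFProfile, path: str) -> None:
    import pandas as pd

    df = pd.DataFrame(
        {
            "z_nm": profile.z,
            "G_kJ_mol": profile.free_energy,
            "se_kJ_mol": profile.se if profile.se is not None else np.nan,
        }
    )
    with open(path, "w") as fh:
        fh.write(
            f"# temperature_K={profile.temperature} "
            f"reference_nm={profile.reference[0]:.3f}:{profile.reference[1]:.3f}\n"
        )
        df.to_csv(fh, index=False)
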