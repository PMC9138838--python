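"""Reproducible validation studies over the synthetic membrane conditions.

Each function runs one self-contained study — generate configurations with
planted structure, run the corresponding analysis, measure how well the
planted structure is recovered — and returns plain numbers.  The analysis
drivers, the test suite and the acceptance script all call these, so every
reported figure comes from the same computation.

Study problem sizes (chosen once; see the methods note):

* co-localization recovery: full-scale 40 x 40 nm membranes, four
  equal-abundance tail species (1300 lipids each), 629 nanoparticles
  (the study's 10% loading), planted strength 0.9, 20 seeds;
* co-localization null: 20 x 20 nm membranes, 280 lipids per species,
  100 nanoparticles, strength 0, 200 seeds;
* WHAM recovery: U(z) = 1/2 * 50 * z^2 kJ/mol/nm^2, 46 windows spaced
  0.1 nm symmetric about z = 0, k = 1000 kJ/mol/nm^2, 10^4 samples per
  window at 298 K.
"""

from __future__ import annotations

import itertools
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clustering import find_clusters
from .colocalization import (
    GridSpec2D,
    ShadowMatrix,
    colocalization_table,
    default_targets,
    expected_random_mse,
    mse,
    shadow_matrix,
)
from .density_structure import (
    assign_leaflets,
    density_profile,
    enrichment_map,
    thickness_map,
    undulation_metric,
    unsaturation_histogram,
)
from .synthetic_membrane import (
    MembraneSpec,
    build_membrane,
    default_composition,
    equal_abundance_composition,
    sample_umbrella_windows,
)
from .trajectory_io import (
    Frame,
    bead_name_labels,
    residue_bead_labels,
    tail_bead_labels,
)
from .wham_pmf import KB, UmbrellaWindow, bootstrap_pmf, pmf_minimum, wham_solve

NULL_TAILS = ("DA", "DP", "DU", "PI")


def _subseed(seed: int, k: int) -> int:
    """Independent child seed < 2^31."""
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# MSE statistic

def mse_enumeration_error(max_cells: int = 9) -> float:
    """Exhaustive check of the MSE statistic against a cell-count oracle.

    Enumerates every pair of binary matrices on shapes up to 3 x 3 and
    compares ``mse`` with the mismatched-cell fraction counted cell by
    cell.  Returns the largest absolute discrepancy (0 when exact).
    """
    worst = 0.0
    for nx, ny in [(1, 1), (1, 2), (2, 2), (2, 3), (3, 3)]:
        grid = GridSpec2D(spacing=1.0, nx=nx, ny=ny, box_x=nx, box_y=ny)
        n = nx * ny
        flat = np.array(list(itertools.product((0, 1), repeat=n)), dtype=np.int8)
        shadows = [ShadowMatrix(grid, row.reshape(nx, ny)) for row in flat]
        # oracle: mismatched-cell fraction counted directly on the bit vectors
        oracle = (flat[:, None, :] != flat[None, :, :]).mean(axis=2)
        for i, sa in enumerate(shadows):
            got = np.array([mse(sa, sb) for sb in shadows])
            worst = max(worst, float(np.max(np.abs(got - oracle[i]))))
    return worst


def mse_random_null(
    p: float = 0.3, q: float = 0.2, shape: tuple[int, int] = (16, 16),
    n_draws: int = 10_000, seed: int = 0,
) -> dict[str, float]:
    """Empirical mean MSE of independent random binary matrices vs the
    closed form p(1-q) + q(1-p); returns the deviation in units of SE."""
    rng = np.random.default_rng(seed)
    a = rng.uniform(size=(n_draws, *shape)) < p
    b = rng.uniform(size=(n_draws, *shape)) < q
    vals = (a ^ b).mean(axis=(1, 2))
    expected = expected_random_mse(p, q)
    se = vals.std(ddof=1) / np.sqrt(n_draws)
    return {
        "empirical": float(vals.mean()),
        "expected": float(expected),
        "z": float((vals.mean() - expected) / se),
        "n": n_draws,
    }


# ---------------------------------------------------------------------------
# co-localization parameter recovery

def recovery_spec(seed: int, strength: float = 0.9) -> MembraneSpec:
    return MembraneSpec(
        box=(40.0, 40.0, 13.0),
        composition=equal_abundance_composition(NULL_TAILS, count=1300),
        np_count=629,
        np_colocal_strength=strength,
        seed=seed,
    )


def null_spec(seed: int) -> MembraneSpec:
    return MembraneSpec(
        box=(20.0, 20.0, 10.0),
        composition=equal_abundance_composition(NULL_TAILS, count=280),
        np_count=100,
        np_colocal_strength=0.0,
        seed=seed,
    )


def _first_ranked(spec: MembraneSpec) -> str:
    traj, _ = build_membrane(spec)
    frame0 = traj[0]
    table = colocalization_table(
        traj,
        residue_bead_labels(frame0, "NP"),
        default_targets(spec.composition, frame0),
    )
    return str(table.iloc[0]["species"])


def colocal_recovery(n_seeds: int = 20, seed: int = 0) -> dict[str, float]:
    """Fraction of seeds in which the planted target tail ranks first."""
    wins = sum(
        _first_ranked(recovery_spec(_subseed(seed, k), strength=0.9)) == "DA"
        for k in range(n_seeds)
    )
    return {"first_rank_fraction": wins / n_seeds, "n": n_seeds}


def colocal_null(n_seeds: int = 200, seed: int = 0) -> dict[str, float]:
    """Chi-square uniformity of the first rank under zero planted signal."""
    firsts = [_first_ranked(null_spec(_subseed(seed, 10_000 + k))) for k in range(n_seeds)]
    obs = [firsts.count(t) for t in NULL_TAILS]
    res = stats.chisquare(obs)
    return {"chi2_p": float(res.pvalue), "counts": obs, "n": n_seeds}


# ---------------------------------------------------------------------------
# WHAM analytic recovery

HARMONIC_A = 50.0  # kJ mol^-1 nm^-2
UMBRELLA_K = 1000.0  # kJ mol^-1 nm^-2
WINDOW_SPACING = 0.1  # nm
N_WINDOWS = 46


def harmonic_windows(seed: int, n_samples: int = 10_000) -> list[UmbrellaWindow]:
    span = (N_WINDOWS - 1) * WINDOW_SPACING
    centers = np.round(np.linspace(-span / 2, span / 2, N_WINDOWS), 6)
    return sample_umbrella_windows(
        lambda z: 0.5 * HARMONIC_A * z**2,
        centers,
        UMBRELLA_K,
        n_samples,
        seed=seed,
    )


def wham_recovery(
    seed: int = 0, n_samples: int = 10_000, n_boot: int = 40, z_check: float = 2.0
) -> dict[str, float]:
    """Recover the harmonic free-energy profile from umbrella samples.

    Returns the maximum |G_est - U| over |z| <= z_check (after aligning the
    arbitrary additive constant on that range), the fraction of those bins
    whose 2*SE bootstrap band covers the analytic curve, and the
    single-window Boltzmann-inversion deviation.
    """
    windows = harmonic_windows(seed, n_samples)
    prof = bootstrap_pmf(windows, n_boot=n_boot, seed=_subseed(seed, 77), bin_width=0.05)
    sel = prof.covered & (np.abs(prof.z) <= z_check)
    ref = 0.5 * HARMONIC_A * prof.z[sel] ** 2
    est = prof.free_energy[sel]
    offset = float(np.mean(est - ref))
    max_err = float(np.max(np.abs(est - offset - ref)))
    cover = float(np.mean(np.abs(est - offset - ref) <= 2 * prof.se[sel]))

    # single-window limit: WHAM == Boltzmann inversion of the bias-corrected histogram
    w = windows[N_WINDOWS // 2]
    single = wham_solve([w], bin_width=0.05)
    edges = np.concatenate([single.z - 0.025, [single.z[-1] + 0.025]])
    hist = np.histogram(w.samples, bins=edges)[0]
    kT = KB * 298.0
    mask = hist > 0
    with np.errstate(divide="ignore"):
        g_direct = -kT * np.log(hist[mask]) - w.bias(single.z[mask])
    g_wham = single.free_energy[single.covered]
    boltz_dev = float(
        np.max(np.abs((g_wham - g_wham.mean()) - (g_direct - g_direct.mean())))
    )
    return {
        "max_abs_error": max_err,
        "coverage_2se": cover,
        "boltzmann_dev": boltz_dev,
        "n": n_samples,
    }


# ---------------------------------------------------------------------------
# geometry recovery

def geometry_recovery(seed: int = 0) -> dict[str, float]:
    """Planted-geometry checks on full-scale membranes.

    Flat bilayer: thickness map must equal the planted separation exactly
    and leaflet labels must match the generator's.  Undulating bilayer
    (one 1 nm cosine mode): leaflet recovery and mode-amplitude error.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        flat = MembraneSpec(undulation_amplitude=0.0, seed=_subseed(seed, 1))
        traj, truth = build_membrane(flat)
        tmap = thickness_map(traj)
        thick_dev = float(np.nanmax(np.abs(tmap.values - truth.thickness_center)))
        labels = assign_leaflets(traj[0])
        flat_acc = float(
            np.mean([labels[r] == truth.lipid_leaflet[r] for r in labels.index])
        )

        wavy = MembraneSpec(
            undulation_amplitude=1.0, undulation_modes=1, seed=_subseed(seed, 2)
        )
        traj, truth = build_membrane(wavy)
        labels = assign_leaflets(traj[0])
        wavy_acc = float(
            np.mean([labels[r] == truth.lipid_leaflet[r] for r in labels.index])
        )
        rms, spectrum = undulation_metric(traj)
        kx, ky, amp, _ = truth.undulation_modes[0]
        got = float(
            spectrum.loc[(spectrum.kx == kx) & (spectrum.ky == ky), "amplitude_nm"].iloc[0]
        )
        amp_err = abs(got - amp) / amp
    return {
        "flat_thickness_max_dev": thick_dev,
        "flat_leaflet_accuracy": flat_acc,
        "undulating_leaflet_accuracy": wavy_acc,
        "amplitude_rel_error": float(amp_err),
        "rms_nm": float(rms),
    }


# ---------------------------------------------------------------------------
# clustering oracle

def _minimum_image_clusters_oracle(
    positions: np.ndarray, box: np.ndarray, cutoff: float
) -> np.ndarray:
    """Independent O(n^2) reference: all-pairs minimum-image distances and
    union-find, no spatial data structures."""
    n = len(positions)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = np.abs(positions[i] - positions[j])
            d = np.minimum(d, box - d)
            if float(np.sqrt((d**2).sum())) <= cutoff:
                parent[find(i)] = find(j)
    roots = [find(i) for i in range(n)]
    order: dict[int, int] = {}
    labels = np.empty(n, dtype=int)
    for i, r in enumerate(roots):
        if r not in order:
            order[r] = len(order)
        labels[i] = order[r]
    return labels


def cluster_oracle_agreement(n_instances: int = 1000, seed: int = 0) -> dict[str, float]:
    """Random <=50-particle instances (including PBC-straddling clusters):
    fraction whose partition matches the brute-force oracle, and whether
    cutoff monotonicity (more clusters at smaller cutoff) ever fails."""
    rng = np.random.default_rng(seed)
    agree = 0
    monotone_ok = True
    for _ in range(n_instances):
        n = int(rng.integers(2, 51))
        box = np.array([4.0, 4.0, 4.0])
        pos = rng.uniform(0, 1, size=(n, 3)) * box
        # seed some tight groups, some deliberately across the boundary
        k = int(rng.integers(0, n // 4 + 1))
        for c in range(k):
            center = rng.uniform(-0.3, 1.0, size=3) * box  # may straddle edges
            m = int(rng.integers(2, 5))
            idx = rng.integers(0, n, size=m)
            pos[idx] = np.mod(center + rng.normal(0, 0.2, size=(m, 3)), box)
        cutoff = float(rng.uniform(0.3, 0.8))
        frame = Frame(
            pos, np.array(["NP:C60"] * n), np.arange(n) + 1, box
        )
        res = find_clusters(frame, {"NP:C60"}, cutoff)
        oracle = _minimum_image_clusters_oracle(pos, box, cutoff)
        if np.array_equal(res.labels, oracle):
            agree += 1
        res_small = find_clusters(frame, {"NP:C60"}, cutoff * 0.5)
        if res_small.n_clusters < res.n_clusters:
            monotone_ok = False
    return {
        "agreement_fraction": agree / n_instances,
        "cutoff_monotonicity": float(monotone_ok),
        "n": n_instances,
    }


# ---------------------------------------------------------------------------
# conservation invariants

def conservation_checks(seed: int = 0) -> dict[str, float]:
    """Exact bookkeeping invariants on one full-scale membrane."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        spec = MembraneSpec(seed=_subseed(seed, 3), n_frames=2)
        traj, _ = build_membrane(spec)
        frame0 = traj[0]
        po4 = bead_name_labels(frame0, ("PO4",))
        prof = density_profile(traj, {"PO4": po4})
        integral_dev = abs(prof.counts["PO4"].sum() - float(frame0.select(po4).sum()))
        emap = enrichment_map(traj, residue_bead_labels(frame0, "NP"), grid_spacing=1.0)
        mean_dev = abs(float(emap.values.mean()) - 1.0)
        hist = unsaturation_histogram(spec.composition)
        sum_dev = float(np.abs(hist.fractions.sum(axis=1) - 1.0).max())
    return {
        "density_integral_dev": float(integral_dev),
        "enrichment_mean_dev": float(mean_dev),
        "unsat_sum_dev": sum_dev,
    }


# ---------------------------------------------------------------------------
# end-to-end determinism

def determinism_check(workdir: str, seed: int = 0) -> dict[str, float]:
    """Run the full pipeline twice with one config; compare output hashes."""
    from .pipeline import RunConfig, run_pipeline

    manifests = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        for tag in ("a", "b"):
            cfg = RunConfig(
                output_dir=f"{workdir}/determinism_{tag}",
                seed=_subseed(seed, 4),
                membrane={"n_frames": 2},
            )
            manifests.append(run_pipeline(cfg))
    h1, h2 = (m["outputs"] for m in manifests)
    identical = set(h1) == set(h2) and all(h1[k] == h2[k] for k in h1)
    return {"identical": float(identical), "n_outputs": len(h1)}
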