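"""Generator contracts: determinism, planted structure, umbrella sampling."""

import numpy as np
import pytest
from scipy import stats

from memshadow.colocalization import GridSpec2D, colocalization_table, default_targets
from memshadow.synthetic_membrane import (
    MembraneSpec,
    build_membrane,
    default_composition,
    equal_abundance_composition,
    sample_umbrella_windows,
)
from memshadow.trajectory_io import bead_name_labels, residue_bead_labels
from memshadow.wham_pmf import KB


class TestBuildMembrane:
    def test_deterministic_under_seed(self):
        spec = lambda: MembraneSpec(
            box=(16, 16, 10), composition=equal_abundance_composition(count=120),
            np_count=30, seed=11, n_frames=2,
        )
        t1, _ = build_membrane(spec())
        t2, _ = build_membrane(spec())
        for f1, f2 in zip(t1, t2):
            assert np.array_equal(f1.positions, f2.positions)
            assert np.array_equal(f1.species, f2.species)

    def test_flat_bilayer_phosphates_exactly_on_planes(self, flat_membrane):
        spec, traj, _ = flat_membrane
        fr = traj[0]
        z = fr.positions[fr.select(bead_name_labels(fr, ("PO4",))), 2]
        mid = spec.box[2] / 2
        planes = np.unique(np.round(z, 9))
        assert np.allclose(
            planes, [mid - spec.leaflet_z_offset, mid + spec.leaflet_z_offset]
        )

    def test_overcrowding_rejected(self):
        with pytest.raises(ValueError, match="overcrowded"):
            build_membrane(
                MembraneSpec(box=(8, 8, 10), composition=default_composition())
            )

    def test_unknown_tail_code_rejected(self):
        with pytest.raises(ValueError, match="tail code"):
            MembraneSpec(np_colocal_target="QQ")

    def test_uniform_np_positions_at_zero_strength(self):
        """Chi-square uniformity on a coarse 8x8 grid is not rejected."""
        spec = MembraneSpec(
            box=(32, 32, 10), composition=equal_abundance_composition(count=700),
            np_count=640, np_colocal_strength=0.0, cluster_fraction=0.0, seed=5,
        )
        traj, _ = build_membrane(spec)
        fr = traj[0]
        xy = fr.positions[fr.select(residue_bead_labels(fr, "NP")), :2]
        g = GridSpec2D.from_box(32, 32, 4.0)
        idx = g.cell_indices(xy, fr.box[:2])
        counts = np.bincount(idx[:, 0] * 8 + idx[:, 1], minlength=64)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_ground_truth_matches_frame(self, small_membrane):
        spec, traj, truth = small_membrane
        assert len(truth.bead_leaflet) == len(traj[0])
        assert truth.colocal_strength == spec.np_colocal_strength
        assert (truth.np_cluster_labels >= -1).all()

    def test_planted_colocalization_monotone_in_strength(self):
        """Mean MSE against the target tail decreases with planted strength."""
        mean_mse = []
        for strength in (0.0, 0.5, 0.9):
            vals = []
            for seed in range(20):
                spec = MembraneSpec(
                    box=(20, 20, 10),
                    composition=equal_abundance_composition(count=280),
                    np_count=100, np_colocal_strength=strength, seed=100 + seed,
                )
                traj, _ = build_membrane(spec)
                table = colocalization_table(
                    traj,
                    residue_bead_labels(traj[0], "NP"),
                    default_targets(spec.composition, traj[0]),
                )
                vals.append(
                    float(table.loc[table.species == "DA", "mean_mse"].iloc[0])
                )
            mean_mse.append(np.mean(vals))
        assert mean_mse[0] > mean_mse[1] > mean_mse[2]


class TestUmbrellaSampler:
    def test_unbiased_harmonic_recovers_gaussian_width(self):
        kT = KB * 298.0
        sigma = 0.1
        wins = sample_umbrella_windows(
            lambda z: np.zeros_like(z), [0.0], kT / sigma**2, 10_000, seed=3
        )
        assert wins[0].samples.std() == pytest.approx(sigma, rel=0.05)

    def test_window_count_for_tenth_nm_steps(self):
        centers = np.arange(0.0, 4.51, 0.1)
        wins = sample_umbrella_windows(
            lambda z: np.zeros_like(z), centers, 1000.0, 200, seed=4
        )
        assert len(wins) == 46

    def test_harmonic_plus_bias_matches_gaussian_product(self):
        """U + bias are both harmonic: the sampled density is the analytic
        Gaussian with mean k*c/(a+k) and variance kT/(a+k)."""
        a, k, c = 50.0, 1000.0, 1.0
        kT = KB * 298.0
        wins = sample_umbrella_windows(
            lambda z: 0.5 * a * z**2, [c], k, 10_000, seed=5
        )
        mu, sd = k * c / (a + k), np.sqrt(kT / (a + k))
        p = stats.kstest(wins[0].samples, "norm", args=(mu, sd)).pvalue
        assert p > 0.01

    def test_determinism(self):
        f = lambda: sample_umbrella_windows(
            lambda z: np.zeros_like(z), [0.0, 0.5], 500.0, 500, seed=9
        )
        w1, w2 = f(), f()
        assert np.array_equal(w1[0].samples, w2[0].samples)
        assert np.array_equal(w1[1].samples, w2[1].samples)

    @pytest.mark.parametrize(
        "kwargs, match",
        [
            (dict(centers=[1.0, 0.5], force_const=100.0, n_samples=500), "increasing"),
            (dict(centers=[0.0], force_const=-1.0, n_samples=500), "positive"),
            (dict(centers=[0.0], force_const=100.0, n_samples=10), "at least 100"),
        ],
    )
    def test_invalid_inputs_rejected(self, kwargs, match):
        with pytest.raises(ValueError, match=match):
            sample_umbrella_windows(lambda z: np.zeros_like(z), seed=0, **kwargs)

    def test_tabulated_potential_accepted(self):
        z = np.linspace(-3, 3, 200)
        wins = sample_umbrella_windows((z, 0.5 * 50 * z**2), [0.0], 1000.0, 500, seed=6)
        assert wins[0].n_samples == 500

    def test_nonfinite_tabulated_potential_rejected(self):
        z = np.linspace(-3, 3, 200)
        u = 0.5 * z**2
        u[10] = np.inf
        with pytest.raises(ValueError, match="finite"):
            sample_umbrella_windows((z, u), [0.0], 1000.0, 500, seed=6)
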