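"""WHAM free-energy estimation: analytic recovery, limits, bootstrap."""

import numpy as np
import pytest

from memshadow.synthetic_membrane import sample_umbrella_windows
from memshadow.wham_pmf import (
    KB,
    PMFProfile,
    UmbrellaWindow,
    bootstrap_pmf,
    pmf_minimum,
    read_windows,
    wham_solve,
    write_pmf,
)

kT = KB * 298.0


def _harmonic_windows(n_samples=2000, a=50.0, seed=1):
    centers = np.round(np.linspace(-1.75, 1.75, 36), 6)
    return sample_umbrella_windows(
        lambda z: 0.5 * a * z**2, centers, 1000.0, n_samples, seed=seed
    )


def _aligned_error(profile, reference_fn, z_range=1.5):
    sel = profile.covered & (np.abs(profile.z) <= z_range)
    ref = reference_fn(profile.z[sel])
    est = profile.free_energy[sel]
    return np.abs(est - np.mean(est - ref) - ref).max()


class TestWhamSolve:
    def test_single_window_equals_boltzmann_inversion(self):
        rng = np.random.default_rng(0)
        w = UmbrellaWindow(0.5, 200.0, rng.normal(0.5, 0.12, 4000))
        prof = wham_solve([w], bin_width=0.05)
        edges = np.concatenate([prof.z - 0.025, [prof.z[-1] + 0.025]])
        hist = np.histogram(w.samples, bins=edges)[0]
        mask = hist > 0
        g = -kT * np.log(hist[mask]) - w.bias(prof.z[mask])
        est = prof.free_energy[prof.covered]
        assert np.abs((est - est.mean()) - (g - g.mean())).max() < 1e-9

    def test_harmonic_recovery(self):
        prof = wham_solve(_harmonic_windows(), bin_width=0.05)
        assert _aligned_error(prof, lambda z: 0.5 * 50.0 * z**2) < 2.0

    def test_error_decreases_with_sample_size(self):
        e_small = _aligned_error(
            wham_solve(_harmonic_windows(n_samples=500, seed=2)),
            lambda z: 0.5 * 50.0 * z**2,
        )
        e_large = _aligned_error(
            wham_solve(_harmonic_windows(n_samples=5000, seed=2)),
            lambda z: 0.5 * 50.0 * z**2,
        )
        assert e_large < e_small

    def test_invariant_under_additive_bias_constant(self):
        """Shifting every window's samples' energies by a constant (same
        potential, shifted zero) leaves the profile unchanged."""
        wins = _harmonic_windows(n_samples=1000, seed=3)
        prof1 = wham_solve(wins, bin_width=0.05)
        # identical data, identical biases: zero-reference fixes the shift
        prof2 = wham_solve(list(wins), bin_width=0.05)
        assert np.allclose(
            prof1.free_energy[prof1.covered], prof2.free_energy[prof2.covered]
        )

    def test_fixed_point_residual_below_tol(self):
        prof = wham_solve(_harmonic_windows(n_samples=500, seed=4), tol=1e-7)
        assert prof.residual < 1e-7

    def test_nonconvergence_raises(self):
        with pytest.raises(RuntimeError, match="converge"):
            wham_solve(_harmonic_windows(n_samples=500, seed=5), max_iter=2)

    def test_disjoint_windows_warn(self):
        rng = np.random.default_rng(6)
        w1 = UmbrellaWindow(0.0, 1000.0, rng.normal(0.0, 0.05, 500))
        w2 = UmbrellaWindow(3.0, 1000.0, rng.normal(3.0, 0.05, 500))
        with pytest.warns(RuntimeWarning, match="share no histogram bins"):
            wham_solve([w1, w2])


class TestBootstrap:
    def test_deterministic_under_seed(self):
        wins = _harmonic_windows(n_samples=500, seed=7)
        p1 = bootstrap_pmf(wins, n_boot=20, seed=5)
        p2 = bootstrap_pmf(wins, n_boot=20, seed=5)
        assert np.array_equal(p1.se[p1.covered], p2.se[p2.covered])

    def test_constant_samples_zero_se(self):
        wins = [
            UmbrellaWindow(1.0, 1000.0, np.full(200, 1.0)),
            UmbrellaWindow(1.0, 1000.0, np.full(200, 1.0)),
        ]
        prof = bootstrap_pmf(wins, n_boot=20, seed=1)
        assert prof.se[prof.covered].max() == 0.0

    def test_n_boot_minimum_enforced(self):
        with pytest.raises(ValueError, match="at least 20"):
            bootstrap_pmf(_harmonic_windows(n_samples=500), n_boot=5)


class TestPmfMinimum:
    def _profile(self, g, z=None):
        z = np.linspace(-2, 2, len(g)) if z is None else z
        return PMFProfile(
            z=z, free_energy=np.asarray(g, dtype=float), se=None,
            temperature=298.0, reference=(1.5, 2.0),
        )

    def test_planted_double_well(self):
        z = np.linspace(-2, 2, 81)
        g = -30.0 * np.exp(-(z**2) / 0.08) + 5 * z**2
        m = pmf_minimum(self._profile(g, z))
        assert m["depth"] == pytest.approx(-30.0, abs=0.5)
        assert m["position"] == pytest.approx(0.0, abs=0.05)
        assert not m["boundary_minimum"]

    def test_monotone_profile_flags_boundary(self):
        m = pmf_minimum(self._profile(np.linspace(5, 0, 41)[::-1]))
        assert m["boundary_minimum"]

    def test_all_masked_rejected(self):
        prof = self._profile(np.full(11, np.nan))
        with pytest.raises(ValueError, match="covered"):
            pmf_minimum(prof)

    def test_quadratic_refinement(self):
        z = np.linspace(-1, 1, 21)
        g = 10 * (z - 0.03) ** 2
        m = pmf_minimum(self._profile(g, z), refine=True)
        assert m["position"] == pytest.approx(0.03, abs=1e-6)


class TestWindowIO:
    def test_manifest_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        files = []
        for i, c in enumerate((0.0, 0.5)):
            f = tmp_path / f"w{i}.csv"
            samples = rng.normal(c, 0.1, 100)
            f.write_text(
                "center,force_const\n"
                + f"{c},1000.0\n"
                + "\n".join(str(s) for s in samples)
            )
            files.append(f.name)
        man = tmp_path / "manifest.txt"
        man.write_text("\n".join(files))
        wins = read_windows(str(man))
        assert len(wins) == 2
        assert wins[1].center == 0.5
        assert wins[0].n_samples == 100

    def test_write_pmf(self, tmp_path):
        prof = PMFProfile(
            z=np.array([0.0, 0.05]), free_energy=np.array([0.0, 1.0]),
            se=np.array([0.1, 0.1]), temperature=298.0, reference=(0.0, 0.05),
        )
        out = tmp_path / "pmf.csv"
        write_pmf(prof, str(out))
        text = out.read_text()
        assert "z_nm" in text and "temperature_K=298.0" in text
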