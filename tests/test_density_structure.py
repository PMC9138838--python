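"""Leaflet assignment, profiles, maps, undulations, tail unsaturation."""

import numpy as np
import pandas as pd
import pytest

from memshadow.density_structure import (
    assign_leaflets,
    density_profile,
    enrichment_map,
    thickness_map,
    undulation_metric,
    unsaturation_histogram,
)
from memshadow.synthetic_membrane import (
    MembraneSpec,
    build_membrane,
    default_composition,
    equal_abundance_composition,
)
from memshadow.trajectory_io import (
    Composition,
    CompositionEntry,
    Frame,
    Trajectory,
    bead_name_labels,
    residue_bead_labels,
    tail_bead_labels,
)


class TestAssignLeaflets:
    def test_flat_bilayer_perfect_recovery(self, flat_membrane):
        _, traj, truth = flat_membrane
        labels = assign_leaflets(traj[0])
        assert all(labels[r] == truth.lipid_leaflet[r] for r in labels.index)

    def test_undulating_recovery_above_995(self):
        spec = MembraneSpec(undulation_amplitude=1.0, undulation_modes=1, seed=2)
        traj, truth = build_membrane(spec)
        labels = assign_leaflets(traj[0])
        acc = np.mean([labels[r] == truth.lipid_leaflet[r] for r in labels.index])
        assert acc >= 0.995

    def test_single_layer_all_outer(self):
        """Degenerate input: one phosphate plane with lipids above it."""
        n = 40
        rng = np.random.default_rng(0)
        xy = rng.uniform(0, 10, size=(n, 2))
        pos = np.column_stack([xy, np.full(n, 2.0)])
        above = np.column_stack([xy, np.full(n, 3.0)])
        fr = Frame(
            np.vstack([pos, above]),
            np.array(["POPC:PO4"] * n + ["POPC:T1A"] * n),
            np.concatenate([np.arange(n) + 1, np.arange(n) + 1]),
            np.array([10.0, 10.0, 10.0]),
        )
        labels = assign_leaflets(fr)
        assert (labels == "outer").all()

    def test_too_few_phosphates_rejected(self):
        fr = Frame(
            np.array([[1.0, 1, 1]]), np.array(["POPC:PO4"]), np.array([1]),
            np.array([4.0, 4, 4]),
        )
        with pytest.raises(ValueError, match="phosphate"):
            assign_leaflets(fr)


class TestDensityProfile:
    def test_uniform_beads_conserved_and_flat(self):
        rng = np.random.default_rng(1)
        n = 5000
        pos = rng.uniform(0, 1, size=(n, 3)) * [10, 10, 10]
        fr = Frame(pos, np.array(["NP:C60"] * n), np.arange(n) + 1, np.array([10.0, 10, 10]))
        prof = density_profile(
            Trajectory([fr]), {"NP": {"NP:C60"}}, bin_width=0.5, center_mode="none"
        )
        assert prof.counts["NP"].sum() == n
        inner = prof.counts["NP"][1:-1]  # edge bins may be partial
        assert inner.std() / inner.mean() < 0.2

    def test_flat_bilayer_phosphate_peaks_at_planted_offset(self, flat_membrane):
        spec, traj, _ = flat_membrane
        prof = density_profile(
            traj, {"PO4": bead_name_labels(traj[0], ("PO4",))}, bin_width=0.1
        )
        c = prof.bin_centers
        counts = prof.counts["PO4"]
        top2 = sorted(c[np.argsort(counts)[-2:]])
        half_bin = prof.bin_width / 2 + 1e-12
        assert top2[0] == pytest.approx(-spec.leaflet_z_offset, abs=half_bin)
        assert top2[1] == pytest.approx(+spec.leaflet_z_offset, abs=half_bin)

    def test_nanoparticles_peak_on_inner_side(self):
        spec = MembraneSpec(undulation_amplitude=0.0, seed=9)
        traj, _ = build_membrane(spec)
        prof = density_profile(
            traj, {"NP": residue_bead_labels(traj[0], "NP")}, bin_width=0.1
        )
        peak = prof.bin_centers[np.argmax(prof.counts["NP"])]
        assert -1.3 < peak < -0.7  # planted 1 nm below the bilayer center

    def test_empty_selector_rejected(self, flat_membrane):
        _, traj, _ = flat_membrane
        with pytest.raises(ValueError):
            density_profile(traj, {})


class TestEnrichmentMap:
    def test_all_beads_in_one_cell_of_four(self):
        pos = np.array([[0.2, 0.2, 0.5]] * 5)
        fr = Frame(pos, np.array(["NP:C60"] * 5), np.arange(5) + 1, np.array([1.0, 1, 1]))
        emap = enrichment_map(Trajectory([fr]), {"NP:C60"}, grid_spacing=0.5)
        assert emap.values[0, 0] == 4.0
        assert emap.values.sum() == 4.0

    def test_uniform_beads_near_one(self):
        rng = np.random.default_rng(2)
        n = 40_000
        pos = rng.uniform(0, 1, size=(n, 3)) * [20, 20, 10]
        fr = Frame(pos, np.array(["NP:C60"] * n), np.arange(n) + 1, np.array([20.0, 20, 10]))
        emap = enrichment_map(Trajectory([fr]), {"NP:C60"}, grid_spacing=2.0)
        per_cell = n / emap.values.size
        sigma = np.sqrt(per_cell) / per_cell
        assert np.abs(emap.values - 1.0).max() <= 3.5 * sigma

    def test_mean_exactly_one(self, small_membrane):
        _, traj, _ = small_membrane
        emap = enrichment_map(traj, residue_bead_labels(traj[0], "NP"), grid_spacing=1.0)
        assert emap.values.mean() == pytest.approx(1.0, abs=1e-9)

    def test_planted_correlations(self):
        """Nanoparticle maps correlate with the target-tail domains and
        anti-correlate with the sterol (planted complementary)."""
        spec = MembraneSpec(seed=7, n_frames=8)
        traj, _ = build_membrane(spec)
        fr = traj[0]
        e_np = enrichment_map(traj, residue_bead_labels(fr, "NP"), grid_spacing=4.0)
        e_da = enrichment_map(traj, tail_bead_labels(spec.composition, "DA"), grid_spacing=4.0)
        e_ch = enrichment_map(traj, residue_bead_labels(fr, "CHOL"), grid_spacing=4.0)
        r_da = np.corrcoef(e_np.values.ravel(), e_da.values.ravel())[0, 1]
        r_ch = np.corrcoef(e_np.values.ravel(), e_ch.values.ravel())[0, 1]
        assert r_da > 0.5
        assert r_ch < 0.0


class TestThicknessMap:
    def test_flat_bilayer_exact(self, flat_membrane):
        spec, traj, truth = flat_membrane
        tmap = thickness_map(traj)
        assert np.nanmax(np.abs(tmap.values - truth.thickness_center)) == 0.0

    def test_pooling_limit_single_cell(self, flat_membrane):
        spec, traj, truth = flat_membrane
        tmap = thickness_map(traj, grid_spacing=50.0)
        assert tmap.values.shape == (1, 1)
        assert tmap.values[0, 0] == pytest.approx(truth.thickness_center)

    def test_planted_bump_recovered(self):
        spec = MembraneSpec(
            undulation_amplitude=0.0, thickness_bump_height=0.5,
            thickness_bump_center=(20.0, 20.0), seed=6,
        )
        traj, truth = build_membrane(spec)
        tmap = thickness_map(traj)
        ij = np.unravel_index(np.nanargmax(tmap.values), tmap.values.shape)
        cx, cy, _, _ = truth.bump
        assert abs(ij[0] + 0.5 - cx) <= 1.5 and abs(ij[1] + 0.5 - cy) <= 1.5
        assert np.nanmax(tmap.values) == pytest.approx(
            truth.thickness_center + 0.5, abs=0.1
        )


class TestUndulation:
    def test_flat_rms_zero(self, flat_membrane):
        _, traj, _ = flat_membrane
        rms, _ = undulation_metric(traj)
        assert rms < 1e-6

    def test_single_mode_amplitude_within_5_percent(self):
        spec = MembraneSpec(undulation_amplitude=1.0, undulation_modes=1, seed=5)
        traj, truth = build_membrane(spec)
        _, spectrum = undulation_metric(traj)
        kx, ky, amp, _ = truth.undulation_modes[0]
        got = spectrum.loc[(spectrum.kx == kx) & (spectrum.ky == ky), "amplitude_nm"].iloc[0]
        assert got == pytest.approx(amp, rel=0.05)

    def test_two_modes_both_recovered(self):
        spec = MembraneSpec(undulation_amplitude=0.8, undulation_modes=2, seed=8)
        traj, truth = build_membrane(spec)
        _, spectrum = undulation_metric(traj)
        planted = {(kx, ky) for kx, ky, _, _ in truth.undulation_modes}
        top2 = set(
            map(tuple, spectrum.nlargest(2, "amplitude_nm")[["kx", "ky"]].to_numpy())
        )
        assert top2 == planted


class TestMapInvariances:
    def test_lateral_translation_permutes_cells(self, small_membrane):
        """Rigid lateral shift by a multiple of the cell size: the multiset
        of map values is unchanged."""
        _, traj, _ = small_membrane
        fr = traj[0]
        sel = residue_bead_labels(fr, "NP")
        base = enrichment_map(Trajectory([fr]), sel, grid_spacing=1.0)
        shifted_pos = fr.positions.copy()
        shifted_pos[:, 0] = np.mod(shifted_pos[:, 0] + 3.0, fr.box[0])
        fr2 = Frame(shifted_pos, fr.species, fr.resids, fr.box)
        shifted = enrichment_map(Trajectory([fr2]), sel, grid_spacing=1.0)
        assert np.allclose(
            np.sort(base.values.ravel()), np.sort(shifted.values.ravel())
        )


class TestUnsaturation:
    def test_two_species_split(self):
        comp = Composition(
            {
                "DAPE": CompositionEntry("DAPE", "PE", "DA", "DA", 4, 4, "inner", 100),
                "DPPC": CompositionEntry("DPPC", "PC", "DP", "DP", 0, 0, "outer", 50),
            }
        )
        hist = unsaturation_histogram(comp)
        assert hist.fractions.loc["inner", 4] == 1.0
        assert hist.fractions.loc["outer", 0] == 1.0

    def test_fractions_sum_to_one(self):
        hist = unsaturation_histogram(default_composition())
        assert np.allclose(hist.fractions.sum(axis=1), 1.0, atol=1e-9)

    def test_inner_leaflet_more_unsaturated_by_construction(self):
        hist = unsaturation_histogram(default_composition())
        assert hist.mean_unsaturation("inner") > hist.mean_unsaturation("outer")

    def test_empty_leaflet_rejected(self):
        comp = Composition(
            {"DAPE": CompositionEntry("DAPE", "PE", "DA", "DA", 4, 4, "inner", 100)}
        )
        with pytest.raises(ValueError, match="outer"):
            unsaturation_histogram(comp)
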