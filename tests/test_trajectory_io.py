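"""Coordinate and composition I/O: round trips, units, error reporting."""

import numpy as np
import pytest

from memshadow.trajectory_io import (
    Composition,
    CompositionEntry,
    Frame,
    ParseError,
    Trajectory,
    read_composition,
    read_frames,
    tail_bead_labels,
    write_composition,
    write_frames,
)


def _random_frame(n=100, box=(5.0, 5.0, 5.0), seed=0):
    rng = np.random.default_rng(seed)
    pos = rng.uniform(0, 1, size=(n, 3)) * box
    species = np.array(["POPC:PO4"] * n)
    return Frame(pos, species, np.arange(n) + 1, np.array(box))


class TestGro:
    def test_round_trip_precision(self, tmp_path):
        traj = Trajectory([_random_frame()])
        p = tmp_path / "t.gro"
        write_frames(traj, p)
        back = read_frames(p)
        assert np.max(np.abs(back[0].positions - traj[0].positions)) <= 0.0005
        assert np.array_equal(back[0].species, traj[0].species)

    def test_multi_frame_round_trip(self, tmp_path):
        frames = [_random_frame(seed=s) for s in (0, 1)]
        p = tmp_path / "t.gro"
        write_frames(Trajectory(frames), p)
        back = read_frames(p)
        assert len(back) == 2
        assert np.array_equal(back[0].species, back[1].species)

    def test_box_written_at_five_decimals(self, tmp_path):
        fr = _random_frame(n=3, box=(40.0, 40.0, 13.0))
        p = tmp_path / "t.gro"
        write_frames(Trajectory([fr]), p)
        box_line = p.read_text().splitlines()[5]
        assert [float(v) for v in box_line.split()] == [40.0, 40.0, 13.0]
        assert "40.00000" in box_line and "13.00000" in box_line

    def test_hand_written_gro(self, tmp_path):
        p = tmp_path / "t.gro"
        p.write_text(
            "three beads\n"
            "    3\n"
            "    1POPC  PO4    1   0.500   1.500   2.000\n"
            "    1POPC  T1A    2   0.600   1.400   1.500\n"
            "    2NP    C60    3   3.900   3.900   2.000\n"
            "   4.00000   4.00000   4.00000\n"
        )
        traj = read_frames(p)
        fr = traj[0]
        assert len(fr) == 3
        assert np.allclose(fr.box, 4.0)
        assert fr.species[2] == "NP:C60"
        assert np.allclose(fr.positions[0], [0.5, 1.5, 2.0])

    def test_malformed_atom_names_line(self, tmp_path):
        p = tmp_path / "bad.gro"
        p.write_text("t\n    1\n    1POPC  PO4    1   x.500   1.500\n   4.0 4.0 4.0\n")
        with pytest.raises(ParseError, match="line 3"):
            read_frames(p)

    def test_triclinic_rejected(self, tmp_path):
        p = tmp_path / "tri.gro"
        p.write_text(
            "t\n    1\n    1POPC  PO4    1   0.500   1.500   2.000\n"
            "   4.0   4.0   4.0   0.0   0.0   2.0   0.0   0.0   0.0\n"
        )
        with pytest.raises(ParseError, match="triclinic"):
            read_frames(p)

    def test_coordinates_wrapped_on_read(self, tmp_path):
        p = tmp_path / "t.gro"
        p.write_text(
            "t\n    1\n    1POPC  PO4    1  -0.100   4.100   2.000\n   4.0 4.0 4.0\n"
        )
        fr = read_frames(p)[0]
        assert np.allclose(fr.positions[0], [3.9, 0.1, 2.0])

    def test_empty_trajectory_refused(self, tmp_path):
        with pytest.raises(ValueError, match="empty"):
            write_frames(Trajectory([]), tmp_path / "x.gro")


class TestPdb:
    def test_cryst1_angstrom_to_nm(self, tmp_path):
        p = tmp_path / "t.pdb"
        p.write_text(
            "CRYST1   40.000   40.000  130.000  90.00  90.00  90.00 P 1           1\n"
            "ATOM      1  C60 NP      1      10.000  20.000  65.000  1.00  0.00           C\n"
            "END\n"
        )
        fr = read_frames(p)[0]
        assert np.allclose(fr.box, [4.0, 4.0, 13.0])
        assert np.allclose(fr.positions[0], [1.0, 2.0, 6.5])

    def test_missing_box_rejected(self, tmp_path):
        p = tmp_path / "nobox.pdb"
        p.write_text(
            "ATOM      1  C60 NP      1      10.000  20.000  65.000  1.00  0.00           C\n"
            "END\n"
        )
        with pytest.raises(ParseError, match="box"):
            read_frames(p)


class TestComposition:
    HEADER = "residue,headgroup,tail1,tail2,db1,db2,leaflet,count\n"

    def test_parse_rows(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(self.HEADER + "DAPE,PE,DA,DA,4,4,inner,100\nCHOL,CHOL,,,0,0,both,1980\n")
        comp = read_composition(p)
        assert comp["DAPE"].tails == [("DA", 4), ("DA", 4)]
        assert comp["CHOL"].tails == []
        assert comp["CHOL"].count == 1980

    def test_duplicate_residue_rejected(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text(self.HEADER + "DAPE,PE,DA,DA,4,4,inner,100\nDAPE,PE,DA,DA,4,4,inner,50\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_composition(p)

    @pytest.mark.parametrize(
        "row",
        ["DAPE,PE,DA,DA,4,4,inner,-5", "DAPE,PE,DA,DA,9,4,inner,5", "DAPE,XX,DA,DA,4,4,inner,5"],
        ids=["negative-count", "db-out-of-range", "unknown-headgroup"],
    )
    def test_invalid_rows_rejected(self, tmp_path, row):
        p = tmp_path / "c.csv"
        p.write_text(self.HEADER + row + "\n")
        with pytest.raises(ParseError):
            read_composition(p)

    def test_round_trip(self, tmp_path):
        comp = Composition(
            {"DAPE": CompositionEntry("DAPE", "PE", "DA", "DA", 4, 4, "inner", 100)}
        )
        p = tmp_path / "c.csv"
        write_composition(comp, p)
        assert read_composition(p)["DAPE"] == comp["DAPE"]

    def test_frame_validation_flags_unknown_residue(self):
        comp = Composition(
            {"POPC": CompositionEntry("POPC", "PC", "PO", "PO", 1, 1, "outer", 1)}
        )
        fr = Frame(
            np.zeros((1, 3)) + 1.0, np.array(["DAPC:PO4"]), np.array([1]), np.array([4.0, 4, 4])
        )
        with pytest.raises(ValueError, match="DAPC"):
            comp.validate_frame(fr)

    def test_tail_selector_unknown_code(self):
        comp = Composition(
            {"POPC": CompositionEntry("POPC", "PC", "PO", "PO", 1, 1, "outer", 1)}
        )
        with pytest.raises(ValueError, match="ZZ"):
            tail_bead_labels(comp, "ZZ")


class TestFrameInvariants:
    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            Frame(np.zeros((2, 3)), np.array(["A:B"]), np.array([1, 1]), np.array([1.0, 1, 1]))

    def test_nonfinite_rejected(self):
        pos = np.zeros((1, 3))
        pos[0, 0] = np.nan
        with pytest.raises(ValueError):
            Frame(pos, np.array(["A:B"]), np.array([1]), np.array([1.0, 1, 1]))

    def test_trajectory_requires_common_ordering(self):
        a = _random_frame(n=3)
        b = _random_frame(n=4)
        with pytest.raises(ValueError):
            Trajectory([a, b])
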