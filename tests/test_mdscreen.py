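"""Contact analysis, variance screening, ranking and CPP fusion."""

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from pepgen.mdscreen import (
    AtomRecord,
    ContactSeries,
    ScreenRecord,
    Trajectory,
    TrajectoryError,
    contact_series,
    contact_variance,
    distance_stats,
    fuse_cpp,
    rank_top_k,
    read_trajectory,
    residue_contacts,
    screen,
    write_trajectory,
)
from pepgen.synth import synth_contact_records, synth_trajectory


def two_atom_traj(gap):
    atoms = [
        AtomRecord("CA", "C", "ALA", 1, "A"),
        AtomRecord("CA", "C", "GLY", 1, "B"),
    ]
    coords = np.array([[[0.0, 0.0, 0.0], [gap, 0.0, 0.0]]])
    return Trajectory(atoms=atoms, coords=coords)


class TestReadTrajectory:
    def test_multi_model_round_trip(self, tmp_path):
        traj = synth_trajectory(0, [2, 2, 2], n_residue_pairs=5)
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        assert back.n_frames == 3
        assert len(back.atoms) == 10
        np.testing.assert_allclose(back.coords, traj.coords, atol=1e-3)

    def test_single_model_file(self, tmp_path):
        traj = synth_trajectory(0, [1], n_residue_pairs=3)
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path)
        back = read_trajectory(path)
        assert back.n_frames == 1
        with pytest.raises(ValueError, match="2 frames"):
            contact_variance(contact_series(back, "A", "B"))

    def test_roster_mismatch_names_model(self, tmp_path):
        traj = synth_trajectory(0, [1, 1], n_residue_pairs=3)
        path = tmp_path / "t.pdb"
        write_trajectory(traj, path)
        lines = path.read_text().splitlines()
        # drop one ATOM line from the second MODEL block
        second_model = [i for i, ln in enumerate(lines) if ln.startswith("MODEL")][1]
        del lines[second_model + 1]
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(TrajectoryError, match="model 2"):
            read_trajectory(path)

    def test_no_atoms_rejected(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("END\n")
        with pytest.raises(TrajectoryError):
            read_trajectory(path)


class TestResidueContacts:
    @pytest.mark.parametrize("gap,expected", [(3.9, 1), (4.0, 1), (4.1, 0)])
    def test_closed_threshold_boundary(self, gap, expected):
        traj = two_atom_traj(gap)
        assert len(residue_contacts(traj, 0, "A", "B")) == expected

    def test_unknown_chain_raises(self):
        with pytest.raises(KeyError, match="'C'"):
            residue_contacts(two_atom_traj(3.0), 0, "A", "C")

    def test_hydrogens_excluded_by_default(self):
        atoms = [
            AtomRecord("CA", "C", "ALA", 1, "A"),
            AtomRecord("H", "H", "GLY", 1, "B"),
            AtomRecord("CA", "C", "GLY", 1, "B"),
        ]
        coords = np.array([[[0, 0, 0], [2.0, 0, 0], [9.0, 0, 0]]], dtype=float)
        traj = Trajectory(atoms=atoms, coords=coords)
        assert residue_contacts(traj, 0, "A", "B") == set()
        assert len(residue_contacts(traj, 0, "A", "B", heavy_only=False)) == 1

    def test_matches_brute_force_oracle_on_random_frames(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            atoms = []
            for j in range(15):
                atoms.append(AtomRecord("CA", "C", "ALA", j // 3 + 1, "A"))
            for j in range(15):
                atoms.append(AtomRecord("CA", "C", "GLY", j // 3 + 1, "B"))
            coords = rng.uniform(0, 12, size=(1, 30, 3))
            traj = Trajectory(atoms=atoms, coords=coords)
            expected = set()
            for ia in range(15):
                for ib in range(15, 30):
                    d = np.linalg.norm(coords[0, ia] - coords[0, ib])
                    if d <= 4.0:
                        expected.add((atoms[ia].res_index, atoms[ib].res_index))
            assert residue_contacts(traj, 0, "A", "B") == expected


class TestContactSeries:
    def test_engineered_schedule(self):
        traj = synth_trajectory(3, [2, 2, 2])
        series = contact_series(traj, "A", "B")
        assert series.counts.tolist() == [2, 2, 2]

    def test_per_frame_oracle(self):
        traj = synth_trajectory(5, [0, 1, 4, 2, 3], n_residue_pairs=6)
        series = contact_series(traj, "A", "B")
        expected = [len(residue_contacts(traj, m, "A", "B"))
                    for m in range(traj.n_frames)]
        assert series.counts.tolist() == expected

    def test_positive_only_without_basic_residues_errors(self):
        traj = synth_trajectory(0, [1])  # chains are ALA/GLY only
        with pytest.raises(ValueError, match="positive"):
            contact_series(traj, "A", "B", positive_only=True)

    def test_positive_only_restricts_selection(self):
        atoms = [
            AtomRecord("CA", "C", "LYS", 1, "A"),
            AtomRecord("CA", "C", "ALA", 2, "A"),
            AtomRecord("CA", "C", "GLY", 1, "B"),
        ]
        coords = np.array([[[0, 0, 0], [0, 3, 0], [0, 1.5, 0]]], dtype=float)
        traj = Trajectory(atoms=atoms, coords=coords)
        full = contact_series(traj, "A", "B")
        pos = contact_series(traj, "A", "B", positive_only=True)
        assert full.counts.tolist() == [2]
        assert pos.counts.tolist() == [1]


class TestContactVariance:
    def test_constant_series_zero(self):
        assert contact_variance(ContactSeries("p", [5, 5, 5])) == 0.0

    def test_forced_n_minus_one_formula(self):
        assert contact_variance(ContactSeries("p", [1, 2, 3, 4, 5])) == 2.5

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(0)
        counts = rng.poisson(6, size=100)
        mean = sum(counts) / len(counts)
        oracle = sum((c - mean) ** 2 for c in counts) / (len(counts) - 1)
        assert contact_variance(ContactSeries("p", counts)) == pytest.approx(
            oracle, abs=1e-10)

    def test_invariant_under_reordering_and_scales_quadratically(self):
        rng = np.random.default_rng(1)
        counts = rng.poisson(4, size=50)
        v = contact_variance(ContactSeries("p", counts))
        shuffled = counts[rng.permutation(50)]
        assert contact_variance(ContactSeries("p", shuffled)) == pytest.approx(v)
        assert contact_variance(ContactSeries("p", 3 * counts)) == pytest.approx(9 * v)

    def test_population_variance_option(self):
        assert contact_variance(ContactSeries("p", [1, 2, 3, 4, 5]), ddof=0) == 2.0

    def test_too_few_frames(self):
        with pytest.raises(ValueError):
            contact_variance(ContactSeries("p", [3]))


class TestDistanceStats:
    def test_static_trajectory(self):
        traj = synth_trajectory(0, [1, 1, 1], n_residue_pairs=2)
        mean, sd = distance_stats(traj, (("A", 1), ("B", 1)))
        assert sd == pytest.approx(0.0, abs=1e-6)
        assert mean == pytest.approx(3.5, abs=0.01)

    def test_two_frame_forced_mean(self):
        atoms = [AtomRecord("CA", "C", "ALA", 1, "A"),
                 AtomRecord("CA", "C", "GLY", 1, "B")]
        coords = np.array([
            [[0, 0, 0], [3.0, 0, 0]],
            [[0, 0, 0], [5.0, 0, 0]],
        ], dtype=float)
        mean, sd = distance_stats(Trajectory(atoms, coords), (("A", 1), ("B", 1)))
        assert mean == pytest.approx(4.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(12)
        atoms = (
            [AtomRecord("CA", "C", "ALA", 1, "A") for _ in range(4)]
            + [AtomRecord("CB", "C", "GLY", 2, "B") for _ in range(5)]
        )
        coords = rng.uniform(0, 10, size=(10, 9, 3))
        traj = Trajectory(atoms=atoms, coords=coords)
        mean, sd = distance_stats(traj, (("A", 1), ("B", 2)))
        per_frame = [cdist(coords[m, :4], coords[m, 4:]).min() for m in range(10)]
        assert mean == pytest.approx(np.mean(per_frame), abs=1e-10)
        assert sd == pytest.approx(np.std(per_frame, ddof=1), abs=1e-10)

    def test_unresolvable_residue(self):
        traj = synth_trajectory(0, [1])
        with pytest.raises(KeyError):
            distance_stats(traj, (("A", 99), ("B", 1)))


class TestScreen:
    def test_variance_boundary_closed(self):
        [rec] = screen([("p", 3.0, -20.0)])
        assert rec.passes_variance

    def test_planted_low_variance_count_recovered(self):
        records = synth_contact_records(seed=2, n_total=127, n_low_variance=57)
        screened = screen([(a, b, c) for a, b, c in records])
        assert sum(r.passes_variance for r in screened) == 57
        assert len(screened) == 127  # nothing dropped

    def test_energy_magnitude_convention(self):
        screened = screen([
            ("favorable", 1.0, -20.0),
            ("weak", 1.0, -10.0),
            ("positive_magnitude", 1.0, 18.0),
            ("missing", 1.0, None),
        ])
        flags = {r.peptide_id: r.passes_energy for r in screened}
        assert flags == {"favorable": True, "weak": False,
                         "positive_magnitude": True, "missing": False}

    def test_all_failing_returns_annotated_list(self):
        screened = screen([("a", 10.0, -1.0), ("b", 9.0, None)])
        assert len(screened) == 2
        assert not any(r.passes_variance and r.passes_energy for r in screened)


class TestRankTopK:
    def make(self, pid, var, energy):
        return ScreenRecord(pid, var, energy, True, True)

    def test_k_exceeds_pool(self):
        recs = [self.make(f"p{i}", 1.0, -20.0 - i) for i in range(3)]
        top = rank_top_k(recs, k=20)
        assert [r.peptide_id for r in top] == ["p2", "p1", "p0"]
        assert [r.rank for r in top] == [1, 2, 3]

    def test_tie_broken_by_lower_variance_then_id(self):
        recs = [self.make("b", 2.0, -20.0), self.make("a", 1.0, -20.0),
                self.make("c", 1.0, -20.0)]
        assert [r.peptide_id for r in rank_top_k(recs, 3)] == ["a", "c", "b"]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(3)
        recs = [
            self.make(f"p{i:02d}", float(rng.integers(0, 4)),
                      -float(rng.uniform(17, 30)))
            for i in range(30)
        ]
        top = rank_top_k(list(recs), k=30)
        oracle = sorted(recs, key=lambda r: (-abs(r.binding_energy),
                                             r.contact_variance, r.peptide_id))
        assert [r.peptide_id for r in top] == [r.peptide_id for r in oracle]

    def test_failing_records_excluded(self):
        recs = [self.make("a", 1.0, -20.0),
                ScreenRecord("b", 1.0, -30.0, True, False)]
        assert [r.peptide_id for r in rank_top_k(recs, 5)] == ["a"]

    def test_invalid_k(self):
        with pytest.raises(ValueError):
            rank_top_k([], k=0)


class TestFuseCpp:
    def test_default_penetratin_fusion(self):
        assert fuse_cpp("AAA") == "RQIKIWFQNRRMKWKKAAA"

    def test_empty_cpp_identity(self):
        assert fuse_cpp("ACD", cpp="") == "ACD"

    def test_length_additivity(self):
        assert len(fuse_cpp("ACDEFGHIK")) == 16 + 9

    def test_noncanonical_cpp_rejected(self):
        with pytest.raises(ValueError):
            fuse_cpp("AAA", cpp="XBZ")
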