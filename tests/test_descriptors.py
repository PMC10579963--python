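"""Physicochemical descriptors, scaling, distances, Welch tests, baselines."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pepgen import descriptors as D
from pepgen.corpus import CANONICAL, Corpus, Peptide
from pepgen.mdscreen import PENETRATIN

seq_strategy = st.text(alphabet=CANONICAL, min_size=2, max_size=20)


def hh_charge_oracle(seq, pH):
    """Independent per-group Henderson-Hasselbalch summation."""
    pka_neg = {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
    pka_pos = {"K": 10.0, "R": 12.0, "H": 5.98}
    total = 1.0 / (1.0 + 10 ** (pH - 7.5))       # N-terminus
    total -= 1.0 / (1.0 + 10 ** (3.55 - pH))     # C-terminus
    for aa in seq:
        if aa in pka_pos:
            total += 1.0 / (1.0 + 10 ** (pH - pka_pos[aa]))
        elif aa in pka_neg:
            total -= 1.0 / (1.0 + 10 ** (pka_neg[aa] - pH))
    return total


class TestNetCharge:
    def test_no_ionizable_sidechains(self):
        assert D.net_charge("GG", include_termini=False) == 0.0

    def test_monotone_in_lysine_count(self):
        assert D.net_charge("KK") > D.net_charge("K")

    def test_penetratin_matches_oracle(self):
        ours = D.net_charge(PENETRATIN, pH=7.4)
        assert ours == pytest.approx(hh_charge_oracle(PENETRATIN, 7.4), abs=1e-9)

    def test_monotone_non_increasing_in_pH(self):
        seq = "ACDEFGHIKR"
        grid = np.arange(0.0, 14.5, 0.5)
        charges = [D.net_charge(seq, pH) for pH in grid]
        assert all(a >= b for a, b in zip(charges, charges[1:]))


class TestIsoelectricPoint:
    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(seq_strategy)
    def test_defining_property(self, seq):
        pI = D.isoelectric_point(seq)
        assert abs(D.net_charge(seq, pI)) < 1e-3

    def test_basic_above_acidic(self):
        assert D.isoelectric_point("KKKKK") > D.isoelectric_point("DDDDD")

    def test_matches_grid_scan_oracle(self):
        seq = "ACDEFGHIK"
        grid = np.arange(0.0, 14.0001, 1e-4)
        charges = np.array([D.net_charge(seq, pH) for pH in grid])
        oracle = grid[np.argmin(np.abs(charges))]
        assert D.isoelectric_point(seq) == pytest.approx(oracle, abs=1e-3)


class TestHydrophobicity:
    def test_single_residue_is_table_value(self):
        assert D.eisenberg_mean("W") == D.EISENBERG["W"]

    def test_mean_of_two(self):
        expected = (D.EISENBERG["A"] + D.EISENBERG["I"]) / 2
        assert D.eisenberg_mean("AI") == pytest.approx(expected)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seq_strategy, st.randoms(use_true_random=False))
    def test_permutation_invariance(self, seq, rnd):
        shuffled = list(seq)
        rnd.shuffle(shuffled)
        assert D.eisenberg_mean("".join(shuffled)) == pytest.approx(
            D.eisenberg_mean(seq), abs=1e-12)


def moment_oracle(seq, angle=100.0):
    delta = math.radians(angle)
    s = c = 0.0
    for i, aa in enumerate(seq):
        s += D.EISENBERG[aa] * math.sin(i * delta)
        c += D.EISENBERG[aa] * math.cos(i * delta)
    return math.sqrt(s * s + c * c) / len(seq)


class TestHydrophobicMoment:
    def test_single_residue_is_absolute_value(self):
        assert D.hydrophobic_moment("R") == pytest.approx(abs(D.EISENBERG["R"]))

    def test_gg_closed_form(self):
        expected = D.EISENBERG["G"] * math.cos(math.radians(50))
        assert D.hydrophobic_moment("GG") == pytest.approx(expected, abs=1e-10)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seq_strategy)
    def test_matches_trig_sum_oracle(self, seq):
        assert D.hydrophobic_moment(seq) == pytest.approx(
            moment_oracle(seq), abs=1e-10)

    def test_phase_invariance(self):
        # shifting every residue angle by a constant leaves the magnitude
        seq = "ACDEFKLIV"
        delta = math.radians(100.0)
        for offset in (0.3, 1.2, 2.9):
            s = sum(D.EISENBERG[aa] * math.sin(i * delta + offset)
                    for i, aa in enumerate(seq))
            c = sum(D.EISENBERG[aa] * math.cos(i * delta + offset)
                    for i, aa in enumerate(seq))
            assert math.hypot(s, c) / len(seq) == pytest.approx(
                D.hydrophobic_moment(seq), abs=1e-10)


class TestCompositionDescriptors:
    @pytest.mark.parametrize("seq,expected", [("FWY", 1.0), ("AAAA", 0.0),
                                              ("FAAA", 0.25)])
    def test_aromaticity(self, seq, expected):
        assert D.aromaticity(seq) == expected

    @pytest.mark.parametrize("seq,expected", [("AAAA", 100.0), ("VVVV", 290.0),
                                              ("GGGG", 0.0)])
    def test_aliphatic_index(self, seq, expected):
        assert D.aliphatic_index(seq) == pytest.approx(expected)

    def test_instability_length_one_convention(self):
        assert D.instability_index("W") == 0.0

    def test_instability_dipeptide_is_diwv(self):
        # II = (10/L) * sum over dipeptides; one dipeptide at L = 2
        from Bio.SeqUtils.ProtParamData import DIWV
        assert D.instability_index("AC") == pytest.approx(5 * DIWV["A"]["C"])

    def test_instability_tripeptide_sum(self):
        from Bio.SeqUtils.ProtParamData import DIWV
        expected = (10 / 3) * (DIWV["A"]["C"] + DIWV["C"]["D"])
        assert D.instability_index("ACD") == pytest.approx(expected)


class TestDescribe:
    def test_single_row_all_finite(self):
        table = D.describe(Corpus([Peptide("p", "ACDEFKLIV")]))
        assert len(table) == 1
        assert np.isfinite(table.to_numpy()).all()
        assert list(table.columns) == D.DESCRIPTOR_COLUMNS

    def test_column_stats_match_two_pass_oracle(self):
        rng = np.random.default_rng(5)
        c = Corpus([
            Peptide(f"p{i}", "".join(rng.choice(list(CANONICAL), size=10)))
            for i in range(30)
        ])
        table = D.describe(c)
        for col in table.columns:
            vals = [table.loc[p.id, col] for p in c]
            mean = sum(vals) / len(vals)
            sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / (len(vals) - 1))
            assert table[col].mean() == pytest.approx(mean, abs=1e-9)
            assert table[col].std(ddof=1) == pytest.approx(sd, abs=1e-9)

    def test_row_order_follows_corpus_order(self):
        c = Corpus([Peptide("b", "ACDEF"), Peptide("a", "KLMNP")])
        assert list(D.describe(c).index) == ["b", "a"]


class TestScaling:
    @pytest.fixture()
    def reference(self):
        rng = np.random.default_rng(8)
        return pd.DataFrame(rng.normal(size=(20, 3)), columns=list("xyz"))

    def test_reference_maps_to_unit_interval(self, reference):
        params = D.fit_scaling(reference)
        scaled = D.apply_scaling(reference, params)
        assert scaled.min().min() == pytest.approx(0.0)
        assert scaled.max().max() == pytest.approx(1.0)

    def test_round_trip(self, reference):
        params = D.fit_scaling(reference)
        back = D.unscale(D.apply_scaling(reference, params), params)
        np.testing.assert_allclose(back.to_numpy(), reference.to_numpy(),
                                   atol=1e-12)

    def test_constant_column_dropped_with_warning(self, reference, caplog):
        reference = reference.assign(const=1.0)
        with caplog.at_level("WARNING"):
            params = D.fit_scaling(reference)
        assert "const" not in params.columns
        assert "const" in caplog.text

    def test_missing_column_raises(self, reference):
        params = D.fit_scaling(reference)
        with pytest.raises(KeyError, match="z"):
            D.apply_scaling(reference[["x", "y"]], params)


class TestCentroidDistance:
    def test_query_at_centroid_has_zero_distance(self):
        ref = pd.DataFrame({"x": [0.0, 2.0], "y": [1.0, 3.0]})
        query = pd.DataFrame({"x": [1.0], "y": [2.0]})
        dist, mean, _ = D.euclidean_to_centroid(query, ref)
        assert mean == pytest.approx(0.0)

    def test_unit_offset_single_descriptor(self):
        ref = pd.DataFrame({"x": [0.0, 0.0]})
        query = pd.DataFrame({"x": [1.0]})
        _, mean, _ = D.euclidean_to_centroid(query, ref)
        assert mean == pytest.approx(1.0)

    def test_matches_naive_norm_oracle(self):
        rng = np.random.default_rng(2)
        ref = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        query = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
        dist, mean, sd = D.euclidean_to_centroid(query, ref)
        centroid = ref.to_numpy().mean(axis=0)
        expected = [
            math.sqrt(((row - centroid) ** 2).sum())
            for row in query.to_numpy()
        ]
        np.testing.assert_allclose(dist.to_numpy(), expected, atol=1e-12)
        assert mean == pytest.approx(np.mean(expected), abs=1e-12)

    def test_column_mismatch_raises(self):
        ref = pd.DataFrame({"x": [0.0, 1.0]})
        query = pd.DataFrame({"y": [1.0]})
        with pytest.raises(KeyError):
            D.euclidean_to_centroid(query, ref)


class TestWelch:
    def test_identical_samples_null(self):
        res = D.welch_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a, b = [1.0, 2.0, 3.5, 4.0], [2.0, 5.0, 6.0]
        r1 = D.welch_ttest(a, b)
        r2 = D.welch_ttest(b, a)
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_matches_reference_implementation(self):
        a, b = [1, 2, 3, 4, 5], [2, 4, 6, 8, 10]
        res = D.welch_ttest(a, b)
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.t == pytest.approx(ref.statistic, abs=1e-9)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-9)
        assert res.df == pytest.approx(ref.df, abs=1e-9)

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError):
            D.welch_ttest([1.0], [1.0, 2.0])


class TestBaselines:
    def test_zero_and_determinism(self):
        assert len(D.random_baseline(0, [10], seed=1)) == 0
        a = D.random_baseline(20, [9, 12], seed=3)
        b = D.random_baseline(20, [9, 12], seed=3)
        assert a.sequences == b.sequences

    def test_uniform_residue_frequencies(self):
        c = D.random_baseline(10000, [12], seed=0)
        joined = "".join(c.sequences)
        for aa in CANONICAL:
            freq = joined.count(aa) / len(joined)
            assert freq == pytest.approx(0.05, abs=0.01)

    def test_helical_all_amphipathic(self):
        c = D.helical_baseline(50, [12, 15], seed=4)
        assert all(D.hydrophobic_moment(s) > 0 for s in c.sequences)

    def test_helical_moment_exceeds_random(self):
        lengths = [12] * 200
        hel = D.helical_baseline(200, lengths, seed=5)
        ran = D.random_baseline(200, lengths, seed=5)
        mu_hel = np.mean([D.hydrophobic_moment(s) for s in hel.sequences])
        mu_ran = np.mean([D.hydrophobic_moment(s) for s in ran.sequences])
        assert mu_hel > mu_ran

    def test_helical_determinism(self):
        a = D.helical_baseline(10, [9], seed=6)
        b = D.helical_baseline(10, [9], seed=6)
        assert a.sequences == b.sequences
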