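"""SSC, Kendall tau, Spearman rho, MCC, Pearson, and the meta-predictor."""

import itertools

import numpy as np
import pytest
import scipy.stats

from pocketbench.chem import AtomEquivalence
from pocketbench.geometry import PocketAlignment
from pocketbench.metrics import (
    ConfusionCounts,
    MethodScore,
    RankVector,
    alignment_mcc,
    binary_mcc,
    kendall_tau,
    kendall_tau_from_positions,
    meta_score,
    pearson_cc,
    spearman_rho,
    ssc,
)
from pocketbench.structures import Contact, ResidueId


def _contact(atom, seq, group):
    return Contact(atom, ResidueId("A", seq, ""), group, 3.5)


class TestSsc:
    def test_identical_profiles_identity_eq(self, positive_pair):
        rec_a, _, _ = positive_pair
        eq = AtomEquivalence.identity(len(rec_a.ligand.atoms))
        assert ssc(rec_a.contacts, rec_a.contacts, eq) == 1.0

    def test_no_shared_contact_types(self):
        a = [_contact(0, 1, "I"), _contact(1, 2, "II")]
        b = [_contact(0, 5, "VI"), _contact(1, 6, "VII")]
        assert ssc(a, b, AtomEquivalence.identity(2)) == 0.0

    def test_forced_half_overlap(self):
        # |A|=4, |B|=6, exactly 2 matchable -> 2 / min(4,6) = 0.5
        a = [_contact(0, 1, "I"), _contact(1, 2, "II"),
             _contact(2, 3, "III"), _contact(3, 4, "IV")]
        b = [_contact(0, 11, "I"), _contact(1, 12, "II"),
             _contact(2, 13, "VI"), _contact(3, 14, "VII"),
             _contact(0, 15, "V"), _contact(1, 16, "VIII")]
        assert ssc(a, b, AtomEquivalence.identity(4)) == 0.5

    def test_maximum_matching_not_greedy(self):
        # ligand atom 0 contacts two groups in A; a greedy pairing that
        # spends B's only group-I contact on the wrong copy undercounts
        a = [_contact(0, 1, "I"), _contact(0, 2, "I")]
        b = [_contact(0, 5, "I"), _contact(0, 6, "I")]
        assert ssc(a, b, AtomEquivalence.identity(1)) == 1.0

    def test_one_empty_profile_is_zero(self):
        a = [_contact(0, 1, "I")]
        assert ssc(a, [], AtomEquivalence.identity(1)) == 0.0

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError):
            ssc([], [], AtomEquivalence.identity(1))

    def test_symmetric_under_swap_with_inverted_eq(self, negative_pair, rng):
        a = [_contact(int(rng.integers(0, 3)), int(s), g)
             for s, g in zip(range(1, 8), "I II III I II VI VII".split())]
        b = [_contact(int(rng.integers(0, 3)), int(s) + 20, g)
             for s, g in zip(range(1, 6), "I VI II III VII".split())]
        eq = AtomEquivalence([(0, 2), (1, 0), (2, 1)])
        assert ssc(a, b, eq) == pytest.approx(ssc(b, a, eq.inverted()))


class TestKendallTau:
    def test_sequential_alignment_is_one(self):
        stats = kendall_tau_from_positions([1, 4, 9, 12], [2, 5, 7, 30])
        assert stats.tau == 1.0
        assert stats.n_discordant == 0

    def test_reversed_alignment_is_minus_one(self):
        stats = kendall_tau_from_positions([1, 2, 3, 4], [40, 30, 20, 10])
        assert stats.tau == -1.0

    def test_single_swap_counts(self):
        # B-order (1,2,4,3): 5 concordant, 1 discordant, tau = 4/6
        stats = kendall_tau_from_positions([1, 2, 3, 4], [1, 2, 4, 3])
        assert (stats.n_concordant, stats.n_discordant) == (5, 1)
        assert stats.tau == pytest.approx(4 / 6)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(20):
            n = int(rng.integers(3, 12))
            pos_a = (rng.permutation(50)[:n] + 1).tolist()
            pos_b = (rng.permutation(50)[:n] + 1).tolist()
            stats = kendall_tau_from_positions(pos_a, pos_b)
            nc = nd = 0
            for (a1, b1), (a2, b2) in itertools.combinations(
                    zip(pos_a, pos_b), 2):
                s = (a2 - a1) * (b2 - b1)
                nc += s > 0
                nd += s < 0
            assert (stats.n_concordant, stats.n_discordant) == (nc, nd)
            ref = scipy.stats.kendalltau(pos_a, pos_b).statistic
            assert stats.tau == pytest.approx(ref, abs=1e-12)

    def test_antisymmetric_under_reversal(self, rng):
        pos_a = (rng.permutation(30)[:8] + 1).tolist()
        pos_b = (rng.permutation(30)[:8] + 1).tolist()
        tau = kendall_tau_from_positions(pos_a, pos_b).tau
        rev = kendall_tau_from_positions(pos_a, [-p for p in pos_b]).tau
        assert rev == pytest.approx(-tau)

    def test_invariant_under_monotone_renumbering(self, rng):
        pos_a = sorted((rng.permutation(30)[:8] + 1).tolist())
        pos_b = (rng.permutation(30)[:8] + 1).tolist()
        tau = kendall_tau_from_positions(pos_a, pos_b).tau
        mono = kendall_tau_from_positions([3 * p + 7 for p in pos_a],
                                          [p ** 2 for p in pos_b]).tau
        assert mono == pytest.approx(tau)

    def test_from_records(self, positive_pair):
        rec_a, rec_b, truth = positive_pair
        aln = PocketAlignment(truth.mapping)
        stats = kendall_tau(aln, rec_a, rec_b)
        pos_a = [rec_a.sequence_position(a) for a, _ in truth.mapping]
        pos_b = [rec_b.sequence_position(b) for _, b in truth.mapping]
        assert stats.tau == kendall_tau_from_positions(pos_a, pos_b).tau

    def test_short_alignment_error(self):
        with pytest.raises(ValueError):
            kendall_tau_from_positions([1], [1])


def _rv(name, values):
    return RankVector(name, [f"c{i}" for i in range(len(values))], values)


class TestSpearman:
    def test_identical_rankings(self):
        a = _rv("a", [3.0, 1.0, 2.0, 5.0])
        b = _rv("b", [30.0, 10.0, 20.0, 50.0])
        assert spearman_rho(a, b) == 1.0

    def test_reversed_rankings(self):
        a = _rv("a", [1.0, 2.0, 3.0, 4.0])
        b = _rv("b", [4.0, 3.0, 2.0, 1.0])
        assert spearman_rho(a, b) == -1.0

    def test_three_point_formula(self):
        # ranks (1,2,3) vs (1,3,2): sum d^2 = 2 -> rho = 1 - 12/24 = 0.5
        assert spearman_rho(_rv("a", [1.0, 2.0, 3.0]),
                            _rv("b", [1.0, 3.0, 2.0])) == pytest.approx(0.5)

    def test_no_ties_equals_pearson_on_ranks(self, rng):
        for _ in range(30):
            n = int(rng.integers(4, 40))
            a = _rv("a", rng.permutation(n).astype(float))
            b = _rv("b", rng.permutation(n).astype(float))
            direct = spearman_rho(a, b)
            on_ranks = pearson_cc(a.ranks, b.ranks)
            assert direct == pytest.approx(on_ranks, abs=1e-12)

    def test_ties_match_scipy(self, rng):
        vals_a = rng.integers(0, 5, 30).astype(float)
        vals_b = rng.integers(0, 5, 30).astype(float)
        a, b = _rv("a", vals_a), _rv("b", vals_b)
        ref = scipy.stats.spearmanr(vals_a, vals_b).statistic
        assert spearman_rho(a, b) == pytest.approx(ref, abs=1e-12)

    def test_constant_vector_error(self):
        with pytest.raises(ValueError, match="constant"):
            spearman_rho(_rv("a", [1.0, 1.0, 1.0]), _rv("b", [1.0, 2.0, 3.0]))


class TestMcc:
    def test_perfect_prediction(self):
        assert binary_mcc(ConfusionCounts(5, 0, 7, 0)) == 1.0

    def test_inverted_prediction(self):
        assert binary_mcc(ConfusionCounts(0, 4, 0, 3)) == -1.0

    def test_direct_formula_example(self):
        # (2*6 - 1*1) / sqrt(3*3*7*7) = 11/21
        assert binary_mcc(ConfusionCounts(2, 1, 6, 1)) == pytest.approx(11 / 21)

    def test_null_mean_near_zero(self, rng):
        vals = []
        for _ in range(1000):
            truth = rng.random(40) < 0.5
            pred = rng.random(40) < 0.5
            tp = int(np.sum(pred & truth))
            fp = int(np.sum(pred & ~truth))
            fn = int(np.sum(~pred & truth))
            tn = int(np.sum(~pred & ~truth))
            if min(tp + fn, tn + fp, tp + fp, tn + fn) == 0:
                continue
            vals.append(binary_mcc(ConfusionCounts(tp, fp, tn, fn)))
        assert abs(np.mean(vals)) < 0.05

    def test_all_zero_error(self):
        with pytest.raises(ValueError):
            binary_mcc(ConfusionCounts(0, 0, 0, 0))


def _pairs(spec):
    return [(ResidueId("A", a, ""), ResidueId("B", b, "")) for a, b in spec]


class TestAlignmentMcc:
    def test_test_equals_reference(self):
        ref = PocketAlignment(_pairs([(1, 10), (2, 11), (3, 12)]))
        assert alignment_mcc(ref, ref, 10, 10) == 1.0

    def test_disjoint_pair_sets_negative(self):
        ref = PocketAlignment(_pairs([(1, 10), (2, 11), (3, 12)]))
        test = PocketAlignment(_pairs([(4, 13), (5, 14), (6, 15)]))
        got = alignment_mcc(test, ref, 20, 20)
        # count-based oracle: TP=0, FP=FN=3, TN=400-6
        expect = binary_mcc(ConfusionCounts(0, 3, 400 - 6, 3))
        assert got == pytest.approx(expect)
        assert got < 0

    def test_one_missing_pair(self):
        ref = PocketAlignment(_pairs([(1, 10), (2, 11), (3, 12), (4, 13)]))
        test = PocketAlignment(_pairs([(1, 10), (2, 11), (3, 12)]))
        expect = binary_mcc(ConfusionCounts(3, 0, 15 * 15 - 4, 1))
        assert alignment_mcc(test, ref, 15, 15) == pytest.approx(expect)

    def test_empty_reference_error(self):
        with pytest.raises(ValueError):
            alignment_mcc(PocketAlignment([]), PocketAlignment([]), 5, 5)


class TestPearsonAndMeta:
    def test_linear_relation(self):
        x = np.arange(10.0)
        assert pearson_cc(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_cc(x, -x) == pytest.approx(-1.0)

    def test_independent_series_near_zero(self, rng):
        assert abs(pearson_cc(rng.normal(size=1000),
                              rng.normal(size=1000))) < 0.1

    def test_constant_error(self):
        with pytest.raises(ValueError):
            pearson_cc(np.ones(5), np.arange(5.0))

    def test_meta_score_product(self):
        assert meta_score(MethodScore("ga-score", 0.6), 0.5).value \
            == pytest.approx(0.30)
        for s in (0.1, 0.5, 0.9):
            assert meta_score(MethodScore("other", s), 1.0).value == s
        assert meta_score(MethodScore("other", 0.0), -0.3).value == 0.0
        assert meta_score(MethodScore("other", 0.5), 0.5).method == "meta"
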