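"""Agency scores, the four-perspective pairing rules, and global estimators."""

from __future__ import annotations

import numpy as np
import pytest

from netagree import (
    PERSPECTIVES,
    AgencyScore,
    RatingMatrixPair,
    agency_scores,
    defined_scores,
    global_mean,
    global_weighted,
    score_table,
)
from conftest import build_group_agreement_network, random_pair
from _oracles import brute_force_scores


class TestAgencyScores:
    def test_illustrative_example_all_perspectives(self, illustrative_pair):
        """Hand enumeration of Agency A's 3 pairs per perspective: the
        group-perceived (2,3,4) vs group-expected (1,1,1) never agree,
        self-perceived (1,1,1) matches group-expected (1,1,1) everywhere,
        and self-expected (1,2,3) agrees with self-perceived only once."""
        ss = agency_scores(illustrative_pair, "A")
        assert (ss.p1.agreed, ss.p1.valid) == (0, 3)
        assert (ss.p2.agreed, ss.p2.valid) == (3, 3)
        assert (ss.p3.agreed, ss.p3.valid) == (0, 3)
        assert (ss.p4.agreed, ss.p4.valid) == (1, 3)

    def test_eighty_percent_illustration(self):
        """8 of 10 raters agreeing on X's involvement gives P1 = 80%."""
        pair = build_group_agreement_network(10, 8)
        assert agency_scores(pair, "X").p1.score == pytest.approx(0.8)

    def test_perfect_agreement_when_matrices_equal(self):
        """perceived == expected makes the same-cell perspectives P1 and P4
        perfect everywhere; if ratings are additionally reciprocal
        (cell [i,j] == cell [j,i]) the cross-cell P2 and P3 are perfect too."""
        rng = np.random.default_rng(7)
        pair = random_pair(rng, 6)
        equal = RatingMatrixPair(pair.agencies, pair.perceived, pair.perceived)
        for ss in score_table(equal):
            assert ss.p1.score == 1.0 and ss.p4.score == 1.0
        sym = np.triu(np.nan_to_num(pair.perceived), 1)
        sym = sym + sym.T
        np.fill_diagonal(sym, np.nan)
        recip = RatingMatrixPair(pair.agencies, sym, sym)
        for ss in score_table(recip):
            for p in PERSPECTIVES:
                assert ss.get(p).score == 1.0

    def test_unknown_agency(self, illustrative_pair):
        with pytest.raises(KeyError, match="unknown agency"):
            agency_scores(illustrative_pair, "Zed")

    def test_nonrespondent_gets_p1_only(self):
        rng = np.random.default_rng(3)
        pair = random_pair(rng, 5)
        p = pair.perceived.copy()
        e = pair.expected.copy()
        p[:, 2] = np.nan
        e[:, 2] = np.nan
        blanked = RatingMatrixPair(pair.agencies, p, e)
        ss = agency_scores(blanked, pair.agencies[2])
        assert ss.p1 is not None and ss.p1.valid == 4
        assert ss.p2 is None and ss.p3 is None and ss.p4 is None

    def test_tolerance_counts_adjacent_categories(self, illustrative_pair):
        # group-perceived (2,3,4) vs group-expected (1,1,1): offsets 1,2,3
        strict = agency_scores(illustrative_pair, "A").p1
        loose = agency_scores(illustrative_pair, "A", tolerance=1).p1
        assert (strict.agreed, loose.agreed) == (0, 1)

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_bruteforce_on_random_networks(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        pair = random_pair(rng, n, missing_prob=0.25, nonrespondent_prob=0.25)
        for agency in pair.agencies:
            ours = agency_scores(pair, agency)
            oracle = brute_force_scores(pair, agency)
            for p in PERSPECTIVES:
                sc = ours.get(p)
                got = (sc.agreed, sc.valid) if sc else (0, 0)
                assert got == oracle[p], (agency, p)

    def test_relabeling_leaves_scores_unchanged(self, illustrative_pair):
        renamed = illustrative_pair.relabel(
            {a: f"#{i}" for i, a in enumerate(illustrative_pair.agencies)}
        )
        for old, new in zip(illustrative_pair.agencies, renamed.agencies):
            a = agency_scores(illustrative_pair, old)
            b = agency_scores(renamed, new)
            for p in PERSPECTIVES:
                sa, sb = a.get(p), b.get(p)
                assert (sa is None) == (sb is None)
                if sa is not None:
                    assert (sa.agreed, sa.valid) == (sb.agreed, sb.valid)


class TestScoreTable:
    def test_one_row_per_agency_in_order(self, illustrative_pair):
        table = score_table(illustrative_pair)
        assert [t.agency for t in table] == list(illustrative_pair.agencies)

    def test_all_missing_data_gives_undefined_scores(self):
        n = 3
        p = np.full((n, n), np.nan)
        pair = RatingMatrixPair(["a", "b", "c"], p, p)
        for ss in score_table(pair):
            assert all(ss.get(persp) is None for persp in PERSPECTIVES)

    def test_defined_scores_filters_per_perspective(self):
        rng = np.random.default_rng(11)
        pair = random_pair(rng, 8, nonrespondent_prob=0.4)
        table = score_table(pair)
        n_resp = int(pair.respondent_flags.sum())
        assert len(defined_scores(table, "P1")) == len(table)
        assert len(defined_scores(table, "P4")) == n_resp


class TestGlobalMean:
    def test_mean_of_two(self):
        est = global_mean([0.4, 0.6])
        assert est.estimate == pytest.approx(0.5)
        assert est.method == "mean" and est.interval_kind == "normal"

    def test_equal_scores_zero_width_interval(self):
        est = global_mean([0.7] * 5)
        assert est.estimate == est.interval_low == est.interval_high == 0.7

    def test_matches_direct_summation(self):
        rng = np.random.default_rng(5)
        vals = rng.random(30)
        assert global_mean(vals).estimate == pytest.approx(
            float(np.sum(vals) / 30), abs=1e-15
        )

    def test_interval_clipped_to_unit(self):
        est = global_mean([0.95, 1.0, 0.9, 1.0])
        assert est.interval_high <= 1.0

    def test_accepts_agency_scores(self):
        scores = [AgencyScore("P1", 2, 4), AgencyScore("P1", 3, 4)]
        assert global_mean(scores).estimate == pytest.approx(0.625)

    def test_needs_two_scores(self):
        with pytest.raises(ValueError, match=">= 2"):
            global_mean([0.5])


class TestGlobalWeighted:
    def test_identical_counts_match_unweighted(self):
        scores = [AgencyScore("P1", 3, 10) for _ in range(6)]
        w = global_weighted(scores)
        assert w.estimate == pytest.approx(global_mean(scores).estimate)

    def test_equal_scores_different_precision(self):
        scores = [AgencyScore("P1", 5, 10), AgencyScore("P1", 1, 2)]
        assert global_weighted(scores).estimate == pytest.approx(0.5)

    def test_pulled_toward_precise_score(self):
        """Hand calculation: s=(0.2, 0.8) with valid=(50, 5).
        ptilde = (10.5/51, 4.5/6); var = ptilde(1-ptilde)/valid;
        w = 1/var; estimate = (w1*0.2 + w2*0.8)/(w1+w2)."""
        scores = [AgencyScore("P1", 10, 50), AgencyScore("P1", 4, 5)]
        pt1, pt2 = 10.5 / 51, 4.5 / 6
        w1 = 50 / (pt1 * (1 - pt1))
        w2 = 5 / (pt2 * (1 - pt2))
        expect = (w1 * 0.2 + w2 * 0.8) / (w1 + w2)
        got = global_weighted(scores)
        assert got.estimate == pytest.approx(expect, abs=1e-12)
        assert got.estimate < 0.5

    def test_boundary_scores_get_finite_weight(self):
        scores = [AgencyScore("P1", 0, 10), AgencyScore("P1", 10, 10)]
        est = global_weighted(scores)
        assert 0.0 < est.estimate < 1.0

    def test_interval_width_comparable_to_unweighted(self):
        rng = np.random.default_rng(2)
        scores = [
            AgencyScore("P1", int(a), 20)
            for a in rng.integers(4, 17, size=25)
        ]
        w = global_weighted(scores)
        m = global_mean(scores)
        assert (w.interval_high - w.interval_low) <= (
            m.interval_high - m.interval_low
        ) * 1.5

    def test_requires_counts(self):
        with pytest.raises(TypeError, match="AgencyScore"):
            global_weighted([0.4, 0.6])
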