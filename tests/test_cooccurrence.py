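"""Occurrence binarization and the pairwise co-occurrence probability."""

import itertools
from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import minimeta as mm
from minimeta.cooccurrence import OccurrenceMatrix

from conftest import supplement_patterns


def exact_point_probability(a: int, b: int, c: int, d: int) -> Fraction:
    """Independent oracle: hypergeometric pmf by exact rational arithmetic.

    Fix margins (a+b successes, c+d failures) and draw a+c items; the
    probability of exactly a successes is C(a+b,a)*C(c+d,c)/C(n,a+c).
    """
    n = a + b + c + d
    return Fraction(comb(a + b, a) * comb(c + d, c), comb(n, a + c))


class TestBinarize:
    def make_cov(self, values):
        values = np.atleast_2d(values)
        ids = [f"c{i}" for i in range(values.shape[0])]
        subs = [f"s{j}" for j in range(values.shape[1])]
        return mm.CoverageMatrix(ids, subs, values)

    @pytest.mark.parametrize(
        "covered,expected", [(4096, 1), (1024, 0), (2048, 1)]  # boundary counts as present
    )
    def test_threshold_rule(self, covered, expected):
        occ = mm.binarize_coverage(self.make_cov([[covered]]), 2048)
        assert occ.presence[0, 0] == expected

    def test_presence_count_matches_elementwise_oracle(self, rng):
        values = rng.integers(0, 5000, size=(100, 96))
        occ = mm.binarize_coverage(self.make_cov(values), 2048)
        expected = sum(
            1 for i in range(100) for j in range(96) if values[i, j] >= 2048
        )
        assert int(occ.presence.sum()) == expected

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            mm.binarize_coverage(self.make_cov([[1]]), 0)

    @given(st.integers(1, 5000), st.integers(1, 5000))
    @settings(max_examples=50, deadline=None)
    def test_raising_threshold_never_creates_presence(self, t1, t2):
        lo, hi = sorted((t1, t2))
        values = np.random.default_rng(0).integers(0, 6000, size=(20, 30))
        cov = self.make_cov(values)
        p_lo = mm.binarize_coverage(cov, lo).presence
        p_hi = mm.binarize_coverage(cov, hi).presence
        assert np.all(p_hi <= p_lo)


class TestContingency:
    def test_worked_example_counts(self):
        x, y = supplement_patterns()
        assert mm.tabulate_contingency(x, y) == (8, 1, 2, 6)

    def test_identical_patterns_have_no_discordance(self):
        x = np.array([1, 0, 1, 1, 0])
        counts = mm.tabulate_contingency(x, x)
        assert (counts.b, counts.c) == (0, 0)

    def test_complementary_patterns_never_cooccur(self):
        x = np.array([1, 0, 1, 1, 0])
        counts = mm.tabulate_contingency(x, 1 - x)
        assert (counts.a, counts.d) == (0, 0)

    def test_counts_sum_to_length(self, rng):
        x, y = rng.integers(0, 2, 40), rng.integers(0, 2, 40)
        assert mm.tabulate_contingency(x, y).total == 40

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mm.tabulate_contingency(np.array([1, 0]), np.array([1]))

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError):
            mm.tabulate_contingency(np.array([2, 0]), np.array([1, 0]))


class TestPointProbability:
    def test_worked_example(self):
        assert round(mm.fisher_point_probability((8, 1, 2, 6)), 3) == 0.013

    def test_empty_margins_force_probability_one(self):
        assert mm.fisher_point_probability((0, 0, 0, 9)) == 1.0

    def test_all_small_tables_match_exact_rational_oracle(self):
        for n in range(13):
            for a, b, c in itertools.product(range(n + 1), repeat=3):
                d = n - a - b - c
                if d < 0:
                    continue
                exact = exact_point_probability(a, b, c, d)
                assert mm.fisher_point_probability((a, b, c, d)) == pytest.approx(
                    float(exact), rel=1e-12
                )

    @pytest.mark.parametrize("n,n_present_x,n_present_y", [(60, 25, 40), (50, 10, 10), (37, 37, 5)])
    def test_hypergeometric_normalization(self, n, n_present_x, n_present_y):
        """Point probabilities over all feasible tables with fixed margins sum to 1."""
        total = 0.0
        for a in range(max(0, n_present_x + n_present_y - n), min(n_present_x, n_present_y) + 1):
            b = n_present_y - a
            c = n_present_x - a
            d = n - a - b - c
            total += mm.fisher_point_probability((a, b, c, d))
        assert total == pytest.approx(1.0, abs=1e-12)

    @given(st.tuples(*(st.integers(0, 30),) * 4))
    @settings(max_examples=100, deadline=None)
    def test_transposition_symmetries(self, counts):
        a, b, c, d = counts
        p = mm.fisher_point_probability((a, b, c, d))
        assert mm.fisher_point_probability((a, c, b, d)) == pytest.approx(p, rel=1e-12)
        assert mm.fisher_point_probability((b, a, d, c)) == pytest.approx(p, rel=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            mm.fisher_point_probability((-1, 0, 0, 5))


def _occurrence(presence):
    presence = np.asarray(presence)
    return OccurrenceMatrix(
        [f"c{i}" for i in range(presence.shape[0])],
        [f"s{j}" for j in range(presence.shape[1])],
        presence,
        2048,
    )


class TestPairwiseMatrix:
    def test_worked_example_off_diagonal(self):
        x, y = supplement_patterns()
        pm = mm.pairwise_pvalues(_occurrence(np.vstack([x, y])))
        assert round(pm.p[0, 1], 3) == 0.013
        assert pm.p[0, 1] == pm.p[1, 0]

    def test_duplicated_contig_is_minimum_over_shared_margins(self, rng):
        """p(X, X) equals the smallest point probability among all tables
        with X's margins on both sides (enumeration oracle)."""
        m = 30
        x = (rng.random(m) < 0.4).astype(int)
        r = int(x.sum())
        pm = mm.pairwise_pvalues(_occurrence(np.vstack([x, x])))
        candidates = []
        for a in range(max(0, 2 * r - m), r + 1):
            candidates.append(mm.fisher_point_probability((a, r - a, r - a, m - 2 * r + a)))
        assert pm.p[0, 1] == pytest.approx(min(candidates), rel=1e-12)
        assert pm.p[0, 1] == pytest.approx(
            mm.fisher_point_probability((r, 0, 0, m - r)), rel=1e-12
        )

    def test_matrix_symmetric_for_random_occurrence(self, rng):
        occ = _occurrence(rng.integers(0, 2, size=(15, 40)))
        pm = mm.pairwise_pvalues(occ)
        assert np.array_equal(pm.p, pm.p.T)
        assert np.all(pm.p > 0) and np.all(pm.p <= 1)

    def test_matches_scalar_path(self, rng):
        """Vectorized matrix equals per-pair scalar computation."""
        pres = rng.integers(0, 2, size=(8, 25))
        pm = mm.pairwise_pvalues(_occurrence(pres))
        for i in range(8):
            for j in range(i + 1, 8):
                expected = mm.fisher_point_probability(
                    mm.tabulate_contingency(pres[i], pres[j])
                )
                assert pm.p[i, j] == pytest.approx(expected, rel=1e-10)

    def test_contig_reordering_permutes_matrix(self, rng):
        pres = rng.integers(0, 2, size=(10, 30))
        perm = rng.permutation(10)
        pm = mm.pairwise_pvalues(_occurrence(pres))
        pm_perm = mm.pairwise_pvalues(_occurrence(pres[perm]))
        assert np.allclose(pm_perm.p, pm.p[np.ix_(perm, perm)])

    def test_two_sided_tail_option(self):
        x, y = supplement_patterns()
        pm = mm.pairwise_pvalues(_occurrence(np.vstack([x, y])), tail="two-sided")
        from scipy.stats import fisher_exact

        expected = fisher_exact([[8, 2], [1, 6]], alternative="two-sided")[1]
        assert pm.p[0, 1] == pytest.approx(expected)

    def test_empty_matrix_rejected(self):
        with pytest.raises(Exception):
            mm.pairwise_pvalues(_occurrence(np.ones((1, 5))))


def bh_stepup_oracle(pvals):
    """Brute-force Benjamini-Hochberg step-up adjusted p-values."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * m / rank)
        adjusted[i] = running
    return adjusted


class TestCorrection:
    def test_bonferroni_multiplies(self):
        pm = mm.PValueMatrix(["a", "b"], np.array([[1e-4, 1e-4], [1e-4, 1e-4]]))
        out = mm.correct_pvalues(pm, "bonferroni", m=100)
        assert out.p[0, 1] == pytest.approx(0.01)
        assert out.corrected and out.correction_method == "bonferroni"

    def test_bonferroni_caps_at_one(self):
        pm = mm.PValueMatrix(["a", "b"], np.array([[0.02, 0.02], [0.02, 0.02]]))
        assert mm.correct_pvalues(pm, "bonferroni", m=100).p[0, 1] == 1.0

    def test_bh_matches_stepup_oracle(self, rng):
        n = 7  # 21 distinct pairs
        raw = np.exp(rng.uniform(np.log(1e-6), 0, size=(n, n)))
        raw = np.triu(raw, 1)
        raw = raw + raw.T + np.eye(n) * 1e-7
        pm = mm.PValueMatrix([f"c{i}" for i in range(n)], raw)
        out = mm.correct_pvalues(pm, "benjamini-hochberg")
        iu = np.triu_indices(n, 1)
        expected = bh_stepup_oracle(list(raw[iu]))
        assert np.allclose(out.p[iu], expected)

    def test_unknown_method_rejected(self):
        pm = mm.PValueMatrix(["a", "b"], np.full((2, 2), 0.5))
        with pytest.raises(ValueError, match="correction"):
            mm.correct_pvalues(pm, "holmes")
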