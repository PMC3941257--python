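import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import expit
from scipy.stats import norm

from sichscore import (
    CIMethod,
    ConvergenceError,
    DegenerateInputError,
    RiskLabel,
    ValidationError,
    auc_with_ci,
    compare_auc_delong,
    evaluate_pair,
    fit_univariate_logistic,
    hosmer_lemeshow,
    nri,
    nri_from_categories,
    reclassification,
)
from sichscore.evalstats import ReclassificationTable


# ---------------------------------------------------------------------------
# independent oracles

def auc_brute_force(scores, y):
    """Pairwise enumeration: P(score_pos > score_neg) with ties at 1/2."""
    pos = [s for s, yi in zip(scores, y) if yi]
    neg = [s for s, yi in zip(scores, y) if not yi]
    total = sum(
        1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
    )
    return total / (len(pos) * len(neg))


def delong_brute_force(s1, s2, y):
    """Naive O(m*n) structural components and the paired z statistic."""

    def psi(a, b):
        return 1.0 if a > b else (0.5 if a == b else 0.0)

    def components(scores):
        pos = [s for s, yi in zip(scores, y) if yi]
        neg = [s for s, yi in zip(scores, y) if not yi]
        v10 = np.array([np.mean([psi(p, n) for n in neg]) for p in pos])
        v01 = np.array([np.mean([psi(p, n) for p in pos]) for n in neg])
        return float(np.mean(v10)), v10, v01

    a1, v10_1, v01_1 = components(s1)
    a2, v10_2, v01_2 = components(s2)
    m, n = len(v10_1), len(v01_1)
    var = (
        np.var(v10_1, ddof=1) / m + np.var(v01_1, ddof=1) / n
        + np.var(v10_2, ddof=1) / m + np.var(v01_2, ddof=1) / n
        - 2 * (np.cov(v10_1, v10_2, ddof=1)[0, 1] / m
               + np.cov(v01_1, v01_2, ddof=1)[0, 1] / n)
    )
    diff = a2 - a1
    z = diff / np.sqrt(var) if var > 0 else 0.0
    return a1, a2, z


# ---------------------------------------------------------------------------
# logistic regression

class TestLogistic:
    def test_two_by_two_closed_form(self):
        # (events|score=1, nonevents|1, events|0, nonevents|0) = (10,40,5,45)
        scores = [1] * 50 + [0] * 50
        y = [True] * 10 + [False] * 40 + [True] * 5 + [False] * 45
        fit = fit_univariate_logistic(scores, y)
        assert fit.odds_ratio_per_point == pytest.approx(
            (10 * 45) / (40 * 5), rel=1e-6
        )

    def test_null_slope_recovered(self, rng):
        scores = rng.integers(0, 13, size=2000)
        y = rng.random(2000) < 0.3
        fit = fit_univariate_logistic(scores, y)
        assert abs(fit.slope) < 3 * fit.slope_se

    def test_known_slope_recovered(self, rng):
        beta = 0.30
        scores = rng.integers(0, 13, size=2000)
        y = rng.random(2000) < expit(-3.0 + beta * scores)
        fit = fit_univariate_logistic(scores, y)
        assert abs(fit.slope - beta) < 3 * fit.slope_se

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        scores = rng.integers(0, 16, size=500).astype(float)
        y = (rng.random(500) < expit(-2.5 + 0.2 * scores)).astype(float)
        fit = fit_univariate_logistic(scores, y)
        ref = sm.Logit(y, sm.add_constant(scores)).fit(disp=0)
        assert fit.intercept == pytest.approx(ref.params[0], abs=1e-6)
        assert fit.slope == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.slope_se == pytest.approx(ref.bse[1], rel=1e-4)

    def test_or_equals_exp_slope_and_ci_brackets(self, rng):
        scores = rng.integers(0, 13, size=800)
        y = rng.random(800) < expit(-2 + 0.2 * scores)
        fit = fit_univariate_logistic(scores, y)
        assert fit.odds_ratio_per_point == pytest.approx(np.exp(fit.slope))
        lo, hi = fit.ci95
        assert lo <= fit.odds_ratio_per_point <= hi

    def test_complete_separation_raises(self):
        scores = [0, 0, 0, 1, 1, 1]
        y = [False, False, False, True, True, True]
        with pytest.raises(ConvergenceError):
            fit_univariate_logistic(scores, y)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            fit_univariate_logistic([1, 2, 3], [True, True, True])


# ---------------------------------------------------------------------------
# calibration

class TestHosmerLemeshow:
    def test_perfect_calibration_constant_predictor(self):
        predicted = [0.5] * 100
        y = [True] * 50 + [False] * 50
        res = hosmer_lemeshow(predicted, y, n_groups=2)
        assert res.hl_statistic == pytest.approx(0.0)

    def test_df_is_groups_minus_two(self, rng):
        predicted = rng.uniform(0.05, 0.95, size=500)
        y = rng.random(500) < predicted
        res = hosmer_lemeshow(predicted, y, n_groups=10)
        assert res.df == len(res.groups) - 2 == 8

    def test_hand_evaluated_toy(self):
        # 20 subjects, 2 groups of 10 split at the predicted median
        predicted = np.array([0.1] * 10 + [0.4] * 10)
        y = np.array([False] * 9 + [True] + [False] * 6 + [True] * 4)
        res = hosmer_lemeshow(predicted, y, n_groups=2)
        stat = 0.0
        for p_g, o_g, n_g in [(0.1, 1, 10), (0.4, 4, 10)]:
            e_g = p_g * n_g
            stat += (o_g - e_g) ** 2 / (e_g * (1 - e_g / n_g))
        assert res.hl_statistic == pytest.approx(stat)
        assert [g[:2] for g in res.groups] == [(10, 1), (10, 4)]

    def test_ties_grouped_together(self):
        # a run of identical predictions must land in one group
        predicted = [0.2] * 50 + [0.8] * 50
        y = [False] * 40 + [True] * 10 + [False] * 10 + [True] * 40
        res = hosmer_lemeshow(predicted, y, n_groups=10)
        assert len(res.groups) == 2

    def test_permutation_invariance(self, rng):
        predicted = rng.uniform(0.05, 0.95, size=200)
        y = rng.random(200) < predicted
        res1 = hosmer_lemeshow(predicted, y)
        perm = rng.permutation(200)
        res2 = hosmer_lemeshow(predicted[perm], y[perm])
        assert res1.hl_statistic == pytest.approx(res2.hl_statistic)

    def test_degenerate_group_raises(self):
        predicted = [0.0] * 10 + [0.5] * 10
        y = [False] * 10 + [True] * 5 + [False] * 5
        with pytest.raises(DegenerateInputError):
            hosmer_lemeshow(predicted, y, n_groups=2)

    def test_probabilities_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            hosmer_lemeshow([0.5, 1.2] * 10, [True, False] * 10)


# ---------------------------------------------------------------------------
# AUC

class TestAUC:
    def test_perfect_separation(self):
        res = auc_with_ci([1, 2, 3, 4], [False, False, True, True])
        assert res.auc == pytest.approx(1.0)

    def test_derived_075(self):
        res = auc_with_ci([3, 1, 2, 4], [False, False, True, True])
        assert res.auc == pytest.approx(0.75)

    def test_tie_counts_half(self):
        res = auc_with_ci([1, 1, 2], [False, True, True])
        assert res.auc == pytest.approx(0.75)

    @given(st.data())
    @settings(max_examples=200, deadline=None)
    def test_matches_brute_force_small_n(self, data):
        n = data.draw(st.integers(3, 12))
        scores = data.draw(
            st.lists(st.integers(0, 5), min_size=n, max_size=n)
        )
        n_pos = data.draw(st.integers(1, n - 1))
        y = [True] * n_pos + [False] * (n - n_pos)
        res = auc_with_ci(scores, y)
        assert res.auc == pytest.approx(auc_brute_force(scores, y))

    def test_bootstrap_ci_seeded_and_reproducible(self, rng):
        scores = rng.integers(0, 16, size=120)
        y = rng.random(120) < expit(-2 + 0.25 * scores)
        r1 = auc_with_ci(scores, y, CIMethod.BOOTSTRAP, n_boot=200, seed=7)
        r2 = auc_with_ci(scores, y, CIMethod.BOOTSTRAP, n_boot=200, seed=7)
        assert r1.ci95 == r2.ci95
        assert r1.n_boot == 200
        lo, hi = r1.ci95
        assert lo < r1.auc < hi

    def test_delong_variance_close_to_bootstrap(self, rng):
        scores = rng.integers(0, 16, size=400)
        y = rng.random(400) < expit(-2 + 0.25 * scores)
        d = auc_with_ci(scores, y, CIMethod.DELONG)
        b = auc_with_ci(scores, y, CIMethod.BOOTSTRAP, n_boot=1000, seed=3)
        assert b.variance == pytest.approx(d.variance, rel=0.35)

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            auc_with_ci([1, 2], [True, True])


class TestDeLongComparison:
    def test_self_comparison_is_null(self, rng):
        scores = list(rng.integers(0, 13, size=60))
        y = [True] * 20 + [False] * 40
        res = compare_auc_delong(scores, scores, y)
        assert res.difference == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_monotone_transform_preserves_auc(self, rng):
        scores = rng.integers(0, 13, size=80).astype(float)
        y = list(rng.random(80) < 0.3)
        y[0], y[1] = True, False
        res = compare_auc_delong(scores, np.exp(scores / 3.0), y)
        assert res.difference == pytest.approx(0.0)

    def test_matches_brute_force_fixture(self):
        s1 = [3, 1, 4, 1, 5, 9, 2, 6]
        s2 = [2, 7, 1, 8, 2, 8, 1, 8]
        y = [True, False, True, False, True, True, False, False]
        res = compare_auc_delong(s1, s2, y)
        a1, a2, z = delong_brute_force(s1, s2, y)
        assert res.auc1 == pytest.approx(a1)
        assert res.auc2 == pytest.approx(a2)
        assert res.z == pytest.approx(z)
        assert res.p_value == pytest.approx(2 * norm.sf(abs(z)))

    @given(st.data())
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force_random_small_n(self, data):
        # at least two subjects per class: the sample variance of the
        # structural components needs ddof=1 in both the oracle and the path
        n = data.draw(st.integers(5, 12))
        s1 = data.draw(st.lists(st.integers(0, 6), min_size=n, max_size=n))
        s2 = data.draw(st.lists(st.integers(0, 6), min_size=n, max_size=n))
        n_pos = data.draw(st.integers(2, n - 2))
        y = [True] * n_pos + [False] * (n - n_pos)
        res = compare_auc_delong(s1, s2, y)
        a1, a2, z = delong_brute_force(s1, s2, y)
        assert res.auc1 == pytest.approx(a1)
        assert res.auc2 == pytest.approx(a2)
        assert res.z == pytest.approx(z, abs=1e-9)


# ---------------------------------------------------------------------------
# reclassification / NRI

L, A, E = RiskLabel.LOW, RiskLabel.AVERAGE, RiskLabel.ELEVATED


class TestReclassification:
    def test_no_change_gives_diagonal(self):
        cats = [L, A, E, A, L]
        y = [True, False, True, False, False]
        t = reclassification(cats, cats, y)
        ev = np.asarray(t.events)
        ne = np.asarray(t.nonevents)
        assert np.all(ev == np.diag(np.diag(ev)))
        assert np.all(ne == np.diag(np.diag(ne)))

    def test_hand_built_fixture(self):
        old = [L, L, A, A, E, E]
        new = [A, L, L, E, E, A]
        y = [True, False, True, False, True, False]
        t = reclassification(old, new, y)
        assert t.events == ((0, 1, 0), (1, 0, 0), (0, 0, 1))
        assert t.nonevents == ((1, 0, 0), (0, 0, 1), (0, 1, 0))

    def test_event_matrix_conserves_counts(self, rng):
        labels = [L, A, E]
        old = [labels[i] for i in rng.integers(0, 3, size=100)]
        new = [labels[i] for i in rng.integers(0, 3, size=100)]
        y = rng.random(100) < 0.3
        t = reclassification(old, new, y)
        assert t.n_events == int(np.sum(y))
        ev = np.asarray(t.events)
        for i, lab in enumerate(labels):
            n_in_stratum = sum(
                1 for o, yi in zip(old, y) if yi and o is lab
            )
            assert ev[i].sum() == n_in_stratum


class TestNRI:
    def test_diagonal_table_gives_zero(self):
        t = ReclassificationTable(
            events=((5, 0, 0), (0, 5, 0), (0, 0, 5)),
            nonevents=((10, 0, 0), (0, 10, 0), (0, 0, 10)),
        )
        res = nri(t)
        assert res.nri == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_fixture_02(self):
        # events n=10: 2 up, 1 down; nonevents n=30: 3 up, 6 down
        t = ReclassificationTable(
            events=((5, 2, 0), (1, 2, 0), (0, 0, 0)),
            nonevents=((15, 2, 1), (4, 6, 0), (2, 0, 0)),
        )
        res = nri(t)
        assert res.nri == pytest.approx(0.2)
        assert res.event_up == pytest.approx(0.2)
        assert res.nonevent_down == pytest.approx(0.2)
        # var = (0.2+0.1)/10 + (0.1+0.2)/30 = 0.04 -> z = 1
        assert res.z == pytest.approx(1.0)
        assert res.p_value == pytest.approx(2 * norm.sf(1.0))

    def test_maximum_nri_is_two(self):
        t = ReclassificationTable(
            events=((0, 3, 2), (0, 0, 5), (0, 0, 0)),
            nonevents=((0, 0, 0), (4, 0, 0), (2, 4, 0)),
        )
        assert nri(t).nri == pytest.approx(2.0)

    def test_table_and_vector_paths_agree(self, rng):
        labels = [L, A, E]
        old = [labels[i] for i in rng.integers(0, 3, size=200)]
        new = [labels[i] for i in rng.integers(0, 3, size=200)]
        y = rng.random(200) < 0.25
        y[0], y[1] = True, False
        a = nri(reclassification(old, new, y))
        b = nri_from_categories(old, new, y)
        assert a == b

    def test_multi_step_moves_count_once(self):
        t = ReclassificationTable(
            events=((0, 0, 1), (0, 0, 0), (0, 0, 0)),
            nonevents=((0, 0, 0), (0, 0, 0), (1, 0, 0)),
        )
        res = nri(t)
        assert res.event_up == 1.0 and res.nonevent_down == 1.0
        assert res.nri == pytest.approx(2.0)

    def test_no_events_rejected(self):
        t = ReclassificationTable(
            events=((0, 0, 0), (0, 0, 0), (0, 0, 0)),
            nonevents=((1, 0, 0), (0, 1, 0), (0, 0, 1)),
        )
        with pytest.raises(ValidationError):
            nri(t)


# ---------------------------------------------------------------------------
# paired evaluation

class TestEvaluatePair:
    @pytest.fixture
    def scored_cohort(self, rng):
        sits = rng.integers(0, 13, size=400)
        taci = rng.random(400) < 0.35
        ext = sits + 3 * taci
        y = rng.random(400) < expit(-4.0 + 0.3 * ext)
        y[:3] = True
        y[-3:] = False
        return sits, ext, y

    def test_structural_contents(self, scored_cohort):
        sits, ext, y = scored_cohort
        rep = evaluate_pair(sits, ext, y, definition="ninds",
                           n_boot=50, seed=1)
        assert rep.n == 400
        assert rep.n_events == int(np.sum(y))
        assert rep.auc_comparison.auc1 == pytest.approx(rep.sits.auc.auc)
        assert rep.auc_comparison.auc2 == pytest.approx(rep.extended.auc.auc)
        assert rep.reclassification.n_events == rep.n_events

    def test_identical_scores_null_comparison(self, rng):
        # totals avoid bands where the two stratum maps disagree (3, 6, 7)
        pool = np.array([0, 1, 2, 4, 5, 8, 9, 10])
        scores = pool[rng.integers(0, len(pool), size=300)]
        y = rng.random(300) < expit(-3.5 + 0.3 * scores)
        y[:2] = True
        y[-2:] = False
        rep = evaluate_pair(scores, scores, y, n_boot=50, seed=2)
        assert rep.auc_comparison.difference == pytest.approx(0.0)
        assert rep.nri.nri == pytest.approx(0.0)

    def test_deterministic_under_seed(self, scored_cohort):
        sits, ext, y = scored_cohort
        r1 = evaluate_pair(sits, ext, y, n_boot=50, seed=42)
        r2 = evaluate_pair(sits, ext, y, n_boot=50, seed=42)
        assert r1 == r2
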