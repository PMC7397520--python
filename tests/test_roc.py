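"""ROC construction, Youden cutoffs, and DeLong AUC comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from hipspect import (
    auc_delong_variance,
    auc_mann_whitney,
    delong_test,
    roc_curve,
    youden_cutoff,
)
from hipspect.errors import InputError, RocError
from hipspect.roc import _psi_matrix
from oracles import exhaustive_youden, pair_count_auc

FOUR_POINT = dict(scores=[0.3, 0.9, 0.6, 1.2], outcomes=[1, 1, 0, 0])


class TestRocCurve:
    def test_perfect_separation_has_auc_one(self):
        c = roc_curve([0.3, 0.4, 1.0, 1.2], [1, 1, 0, 0])
        assert c.auc == 1.0

    def test_all_tied_scores_give_half(self):
        c = roc_curve([0.7] * 6, [1, 1, 0, 0, 0, 0])
        assert c.auc == pytest.approx(0.5)

    def test_four_point_fixture_by_pair_counting(self):
        # 3 concordant pairs, 1 discordant, 0 tied -> 0.75
        c = roc_curve(**FOUR_POINT)
        assert c.auc == pytest.approx(0.75)
        assert c.auc == pytest.approx(
            pair_count_auc(FOUR_POINT["scores"], FOUR_POINT["outcomes"])
        )

    def test_curve_anchored_and_monotone(self, rng):
        scores = rng.normal(size=40)
        outcomes = rng.integers(0, 2, size=40)
        outcomes[:2] = [0, 1]
        c = roc_curve(scores, outcomes)
        assert (c.fpr[0], c.tpr[0]) == (0.0, 0.0)
        assert (c.fpr[-1], c.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(c.fpr) >= 0) and np.all(np.diff(c.tpr) >= 0)

    def test_single_class_outcomes_undefined(self):
        with pytest.raises(RocError):
            roc_curve([0.1, 0.2], [1, 1])

    def test_nonfinite_scores_rejected(self):
        with pytest.raises(InputError):
            roc_curve([0.1, np.nan], [1, 0])

    def test_string_outcome_labels(self):
        c = roc_curve([0.3, 1.2], ["onfh", "union"])
        assert c.n_pos == 1 and c.n_neg == 1 and c.auc == 1.0


class TestAucIdentity:
    @given(
        n=st.integers(4, 50),
        n_pos=st.integers(1, 10),
        seed=st.integers(0, 2**16),
        tie_grid=st.sampled_from([None, 0.25, 0.5]),
    )
    def test_trapezoid_equals_mann_whitney(self, n, n_pos, seed, tie_grid):
        r = np.random.default_rng(seed)
        n_pos = min(n_pos, n - 1)
        scores = r.normal(size=n)
        if tie_grid:  # coarsen to force ties
            scores = np.round(scores / tie_grid) * tie_grid
        outcomes = np.zeros(n, int)
        outcomes[:n_pos] = 1
        c = roc_curve(scores, outcomes)
        mw = auc_mann_whitney(scores, outcomes)
        assert abs(c.auc - mw) < 1e-12
        assert mw == pytest.approx(pair_count_auc(scores, outcomes), abs=1e-12)

    def test_matches_scipy_mann_whitney_u(self, rng):
        """U / (m*n) from an independent implementation equals our AUC."""
        scores = np.round(rng.normal(size=30), 1)
        outcomes = np.zeros(30, int)
        outcomes[:12] = 1
        # lower scores indicate positives: concordance = P(neg > pos)
        u = stats.mannwhitneyu(
            scores[outcomes == 0], scores[outcomes == 1], alternative="two-sided"
        ).statistic
        expected = u / (12 * 18)
        assert auc_mann_whitney(scores, outcomes) == pytest.approx(expected, abs=1e-12)

    @given(n=st.integers(4, 30), seed=st.integers(0, 2**16))
    def test_orientation_duality(self, n, seed):
        r = np.random.default_rng(seed)
        scores = np.round(r.normal(size=n), 1)
        outcomes = np.zeros(n, int)
        outcomes[: max(1, n // 3)] = 1
        low = auc_mann_whitney(scores, outcomes, "lower_is_positive")
        high_neg = auc_mann_whitney(-scores, outcomes, "higher_is_positive")
        flipped = auc_mann_whitney(scores, outcomes, "higher_is_positive")
        assert low == pytest.approx(high_neg, abs=1e-12)
        assert low == pytest.approx(1 - flipped, abs=1e-12)

    def test_invariant_under_monotone_decreasing_transform_with_flip(self, rng):
        scores = rng.uniform(0.1, 3.0, size=20)
        outcomes = np.zeros(20, int)
        outcomes[:7] = 1
        a = auc_mann_whitney(scores, outcomes, "lower_is_positive")
        b = auc_mann_whitney(1.0 / scores, outcomes, "higher_is_positive")
        assert a == pytest.approx(b, abs=1e-12)


class TestYouden:
    def test_separated_groups_report_midpoint_cutoff(self):
        # positives up to 0.45, negatives from 0.55: midpoint 0.5, sens=spec=1
        scores = [0.30, 0.45, 0.55, 1.2, 1.3]
        outcomes = [1, 1, 0, 0, 0]
        y = youden_cutoff(roc_curve(scores, outcomes))
        assert y.cutoff == pytest.approx(0.5)
        assert y.sensitivity == 1.0 and y.specificity == 1.0
        assert y.youden_j == pytest.approx(1.0)

    def test_uninformative_scores_have_zero_youden_index(self):
        y = youden_cutoff(roc_curve([0.7] * 6, [1, 1, 0, 0, 0, 0]))
        assert y.youden_j == 0.0

    def test_four_point_fixture_matches_exhaustive_scan(self):
        c = roc_curve(**FOUR_POINT)
        y = youden_cutoff(c)
        j, sens, spec = exhaustive_youden(FOUR_POINT["scores"], FOUR_POINT["outcomes"])
        assert y.youden_j == pytest.approx(j)
        assert (y.sensitivity, y.specificity) == (sens, spec)
        # tie at J=0.5 broken toward higher specificity: threshold 0.3
        assert y.threshold == 0.3
        assert y.cutoff == pytest.approx(0.45)  # midpoint to next score 0.6

    @given(n=st.integers(4, 25), seed=st.integers(0, 2**16))
    def test_youden_j_matches_exhaustive_scan(self, n, seed):
        r = np.random.default_rng(seed)
        scores = np.round(r.uniform(0, 2, size=n), 1)
        outcomes = np.zeros(n, int)
        outcomes[: max(1, n // 3)] = 1
        y = youden_cutoff(roc_curve(scores, outcomes))
        j, _, _ = exhaustive_youden(scores, outcomes)
        assert y.youden_j == pytest.approx(max(j, 0.0))


class TestDelong:
    def test_self_comparison_is_exactly_null(self, rng):
        scores = rng.normal(size=20)
        outcomes = np.zeros(20, int)
        outcomes[:8] = 1
        res = delong_test(scores, scores.copy(), outcomes, paired=True)
        assert res.z_statistic == 0.0 and res.p_value == 1.0
        assert res.auc_a == res.auc_b

    def test_frozen_cross_check_against_independent_reference(self):
        """14-case fixture previously verified against R pROC's paired DeLong."""
        a = [-1.519, -0.715, -2.715, -2.711, -3.286, -1.894, -1.229,
             1.176, -1.379, -0.431, 0.6, 0.226, -1.656, -1.308]
        b = [-1.533, -1.122, -2.845, -2.725, -2.64, -1.558, 0.803,
             0.775, -0.515, -0.001, 0.081, 0.279, 0.183, -0.886]
        y = [1] * 5 + [0] * 9
        res = delong_test(a, b, y, paired=True)
        assert res.auc_a == pytest.approx(0.8444444444, abs=1e-9)
        assert res.auc_b == pytest.approx(0.9555555556, abs=1e-9)
        assert res.z_statistic == pytest.approx(-1.1250879009, abs=1e-9)
        assert res.p_value == pytest.approx(0.2605517878, abs=1e-9)
        assert auc_delong_variance(a, y)[1] == pytest.approx(0.0149382716, abs=1e-9)

    def test_variance_close_to_stratified_bootstrap(self, rng):
        m, n, B = 10, 20, 10_000
        z = rng.normal(size=30)
        a = z + 0.8 * rng.normal(size=30)
        b = z + 0.8 * rng.normal(size=30)
        pos = np.zeros(30, bool)
        pos[:m] = True
        a[pos] -= 1.2
        b[pos] -= 1.2
        res = delong_test(a, b, pos, paired=True)
        var_diff = res.variance_a + res.variance_b - 2 * res.covariance
        pa = _psi_matrix(a[pos], a[~pos], "lower_is_positive")
        pb = _psi_matrix(b[pos], b[~pos], "lower_is_positive")
        pi = rng.integers(0, m, size=(B, m))
        ni = rng.integers(0, n, size=(B, n))
        da = pa[pi[:, :, None], ni[:, None, :]].mean(axis=(1, 2))
        db = pb[pi[:, :, None], ni[:, None, :]].mean(axis=(1, 2))
        boot = np.var(da - db, ddof=1)
        assert abs(var_diff - boot) / boot < 0.15

    def test_monotone_transforms_of_one_latent_score_agree(self, rng):
        """Two monotone views of the same score rank identically: p = 1."""
        latent = rng.uniform(0.2, 2.0, size=30)
        outcomes = np.zeros(30, int)
        outcomes[:6] = 1
        latent[:6] *= 0.25
        res = delong_test(latent, np.sqrt(latent), outcomes, paired=True)
        assert res.auc_a == res.auc_b
        assert res.p_value == pytest.approx(1.0)

    def test_unpaired_mode_has_zero_covariance(self, rng):
        a = rng.normal(size=20)
        ya = np.zeros(20, int)
        ya[:8] = 1
        b = rng.normal(size=26)
        yb = np.zeros(26, int)
        yb[:10] = 1
        res = delong_test(a, b, ya, paired=False, outcomes_b=yb)
        assert res.covariance == 0.0
        assert not res.paired

    def test_requires_two_cases_per_class(self):
        with pytest.raises(RocError):
            delong_test([0.1, 0.5, 0.6], [0.2, 0.4, 0.7], [1, 0, 0], paired=True)

    def test_covariance_bounded_by_variances(self, rng):
        z = rng.normal(size=24)
        a = z + 0.3 * rng.normal(size=24)
        b = z + 0.3 * rng.normal(size=24)
        pos = np.zeros(24, bool)
        pos[:9] = True
        a[pos] -= 1.0
        b[pos] -= 1.0
        res = delong_test(a, b, pos, paired=True)
        assert abs(res.covariance) <= np.sqrt(res.variance_a * res.variance_b) + 1e-15

    def test_single_placement_variance_is_zero(self):
        auc, var = auc_delong_variance([0.2, 0.9], [1, 0])
        assert auc == 1.0 and var == 0.0
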