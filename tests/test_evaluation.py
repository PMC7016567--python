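"""ROC metrics, non-parametric tests, rmcorr and VI-trend contracts."""

import numpy as np
import pytest
from scipy import stats

from vigilwatch.evaluation import (
    kruskal_wallis,
    rmcorr,
    roc_evaluate,
    tukey_posthoc,
    vi_trend,
    wilcoxon_signed_rank,
)
from vigilwatch.model import VigilanceIndexSeries


class TestRocEvaluate:
    def test_hand_counted_example(self):
        scores = np.array([0.9, 0.4, 0.6, 0.1])
        labels = np.array([1, 1, 0, 0])
        res = roc_evaluate(scores, labels)
        assert res.auc == pytest.approx(0.75)
        assert res.max_accuracy == pytest.approx(0.75)

    def test_perfect_separation(self):
        res = roc_evaluate(np.array([3.0, 2.0, 1.0, 0.0]),
                           np.array([1, 1, 0, 0]))
        assert res.auc == 1.0
        assert res.max_accuracy == 1.0

    def test_constant_scores_give_chance_auc_and_prevalence_accuracy(self):
        res = roc_evaluate(np.ones(10), np.array([1] * 7 + [0] * 3))
        assert res.auc == pytest.approx(0.5)
        assert res.max_accuracy == pytest.approx(0.7)

    def test_single_class_is_an_error(self):
        with pytest.raises(ValueError, match="classes"):
            roc_evaluate(np.arange(4.0), np.ones(4, dtype=int))

    def test_auc_equals_mann_whitney_probability(self):
        """Trapezoidal AUC with tie half-credit equals U / (n1 * n0)."""
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1, n0 = rng.integers(3, 15, size=2)
            # coarse grid forces ties
            s = rng.integers(0, 6, size=n1 + n0).astype(float)
            y = np.array([1] * n1 + [0] * n0)
            u = stats.mannwhitneyu(s[y == 1], s[y == 0],
                                   alternative="two-sided").statistic
            assert roc_evaluate(s, y).auc == pytest.approx(u / (n1 * n0))

    def test_auc_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        s = rng.normal(size=40)
        y = rng.integers(0, 2, 40)
        if len(np.unique(y)) < 2:
            y[0] = 1 - y[0]
        base = roc_evaluate(s, y).auc
        for f in (np.exp, np.tanh, lambda x: 3 * x + 7):
            assert roc_evaluate(f(s), y).auc == pytest.approx(base)

    def test_accepts_vigilance_index_series(self):
        series = VigilanceIndexSeries(times=np.arange(4.0),
                                      vi=np.array([0.9, 0.4, 0.6, 0.1]))
        assert roc_evaluate(series, np.array([1, 1, 0, 0])).auc == 0.75


class TestKruskalWallis:
    def test_hand_rank_computation(self):
        res = kruskal_wallis([np.array([1, 2, 3]), np.array([4, 5, 6])])
        assert res.statistic == pytest.approx(3.857, abs=0.005)

    def test_identical_groups_are_clearly_null(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        res = kruskal_wallis([g, g.copy()])
        assert res.p >= 0.95

    def test_degenerate_ties_are_an_error(self):
        with pytest.raises(ValueError, match="identical"):
            kruskal_wallis([np.ones(3), np.ones(3)])

    def test_type_one_error_rate_under_the_null(self):
        rng = np.random.default_rng(2)
        rej = sum(
            kruskal_wallis([rng.normal(size=10) for _ in range(4)]).p < 0.05
            for _ in range(1000))
        assert abs(rej / 1000 - 0.05) <= 0.02


class TestTukeyPosthoc:
    def test_identical_groups_all_non_significant(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(size=12) for _ in range(3)]
        p = tukey_posthoc(groups)
        assert (p[~np.eye(3, dtype=bool)] > 0.05).all()

    def test_shifted_group_stands_out(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=15), rng.normal(size=15),
                  rng.normal(size=15) + 6.0]
        p = tukey_posthoc(groups)
        assert p[0, 2] < 0.05 and p[1, 2] < 0.05
        assert p[0, 1] > 0.05

    def test_matrix_symmetric_with_unit_diagonal(self):
        rng = np.random.default_rng(5)
        p = tukey_posthoc([rng.normal(size=8) for _ in range(4)])
        assert np.allclose(p, p.T)
        assert np.allclose(np.diag(p), 1.0)


class TestWilcoxonSignedRank:
    def test_uniform_positive_shift_has_exact_one_sided_p(self):
        a = np.arange(10.0)
        b = a + 1.0
        _stat, p = wilcoxon_signed_rank(b, a, alternative="greater")
        assert p == pytest.approx(1.0 / 1024.0)

    def test_identical_pairs_are_an_error(self):
        a = np.arange(8.0)
        with pytest.raises(ValueError, match="zero"):
            wilcoxon_signed_rank(a, a.copy())

    def test_type_one_error_rate_under_a_symmetric_null(self):
        rng = np.random.default_rng(6)
        rej = 0
        for _ in range(1000):
            a = rng.normal(size=15)
            b = rng.normal(size=15)
            rej += wilcoxon_signed_rank(a, b)[1] < 0.05
        assert abs(rej / 1000 - 0.05) <= 0.02


class TestRmcorr:
    def test_perfect_common_slope_gives_r_of_minus_one(self):
        subjects = np.repeat(["a", "b", "c"], 5)
        x = np.tile(np.arange(5.0), 3)
        y = -x + np.repeat([0.0, 10.0, 20.0], 5)
        res = rmcorr(subjects, x, y)
        assert res.r == -1.0
        assert res.dof == 15 - 3 - 1

    def test_matches_within_subject_centring_oracle(self):
        """ANCOVA-fit r equals plain correlation on per-subject-centred data
        (the classic two-step construction) to 1e-10."""
        rng = np.random.default_rng(7)
        subjects = np.repeat(np.arange(6), 8)
        x = rng.normal(size=48)
        y = 0.4 * x + rng.normal(size=48) + np.repeat(rng.normal(0, 3, 6), 8)
        res = rmcorr(subjects, x, y)
        xc = x.copy().astype(float)
        yc = y.copy().astype(float)
        for s in np.unique(subjects):
            m = subjects == s
            xc[m] -= xc[m].mean()
            yc[m] -= yc[m].mean()
        r_oracle = np.corrcoef(xc, yc)[0, 1]
        assert res.r == pytest.approx(r_oracle, abs=1e-10)

    def test_matches_pingouin_reference_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        subjects = np.repeat(np.arange(5), 6)
        x = rng.normal(size=30)
        y = -0.5 * x + rng.normal(size=30)
        res = rmcorr(subjects, x, y)
        df = pd.DataFrame({"s": subjects, "x": x, "y": y})
        ref = pingouin.rm_corr(data=df, x="x", y="y", subject="s")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert res.dof == int(ref["dof"].iloc[0])
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-6)

    def test_single_observation_subjects_dropped_with_warning(self):
        subjects = np.array(["a", "a", "a", "b"])
        x = np.array([1.0, 2.0, 3.0, 9.0])
        y = np.array([2.0, 3.0, 4.0, 1.0])
        with pytest.raises(ValueError, match="2 subjects"):
            with pytest.warns(UserWarning, match="dropping"):
                rmcorr(subjects, x, y)

    def test_null_rejection_rate(self):
        rng = np.random.default_rng(9)
        rej = 0
        rs = []
        for _ in range(1000):
            subjects = np.repeat(np.arange(4), 5)
            x = rng.normal(size=20)
            y = rng.normal(size=20)
            res = rmcorr(subjects, x, y)
            rs.append(res.r)
            rej += res.p < 0.05
        assert abs(np.mean(rs)) < 0.05
        assert abs(rej / 1000 - 0.05) <= 0.02


class TestViTrend:
    def series(self, values, times=None):
        v = np.asarray(values, float)
        t = np.arange(len(v), dtype=float) if times is None else times
        return VigilanceIndexSeries(times=t, vi=v)

    def test_strictly_decreasing_vi_has_negative_slope(self):
        s = self.series(np.linspace(1.0, 0.0, 30))
        res = vi_trend(s, [0, 10, 20, 30])
        assert res.slope < 0
        assert np.all(np.diff(res.mean_trajectory) < 0)

    def test_constant_vi_has_zero_slope(self):
        s = self.series(np.full(30, 0.4))
        res = vi_trend(s, [0, 10, 20, 30])
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_empty_block_is_an_error(self):
        s = self.series(np.ones(10))
        with pytest.raises(ValueError, match="empty"):
            vi_trend(s, [0, 5, 10, 15])

    def test_cohort_contrast_detects_a_planted_decline(self):
        rng = np.random.default_rng(10)
        series = {}
        for subj in range(12):
            vi = np.concatenate([rng.normal(1.0, 0.2, 20),
                                 rng.normal(0.0, 0.2, 20)])
            series[subj] = self.series(vi)
        res = vi_trend(series, [0, 20, 40])
        assert res.contrast_p is not None and res.contrast_p < 0.05

    def test_constant_cohort_has_no_contrast(self):
        series = {s: self.series(np.full(20, 0.5)) for s in range(6)}
        res = vi_trend(series, [0, 10, 20])
        assert res.contrast_p is None
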