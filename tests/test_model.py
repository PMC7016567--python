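"""SWLDA selection/scoring and channel-configuration reduction."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from vigilwatch.model import (
    FeatureMap,
    SWLDAModel,
    build_ladder,
    prune_redundant,
    significant_channels,
    swlda_fit,
    swlda_score,
)
from vigilwatch.spectral import BAND_NAMES, FeatureTable


def exhaustive_best_rss(X: np.ndarray, y: np.ndarray, size: int) -> float:
    """Oracle: smallest OLS residual sum of squares over all subsets of
    ``size`` columns."""
    n = len(y)
    best = np.inf
    for subset in combinations(range(X.shape[1]), size):
        design = np.column_stack([np.ones(n), X[:, subset]])
        coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
        resid = y - design @ coef
        best = min(best, float(resid @ resid))
    return best


def model_rss(model: SWLDAModel, frame: pd.DataFrame, y: np.ndarray) -> float:
    pred = swlda_score(model, frame).vi
    return float(((y - pred) ** 2).sum())


class TestSwldaFit:
    def test_single_informative_feature_dominates_selection(self):
        """With one near-perfect predictor among pure noise the informative
        feature always enters first; noise features enter only at the
        alpha_enter false-positive rate (expected exact-model rate
        0.95^9 ~ 0.63)."""
        exact = 0
        seeds = range(20)
        for seed in seeds:
            rng = np.random.default_rng(seed)
            n = 200
            y = rng.integers(0, 2, n)
            X = rng.standard_normal((n, 10))
            X[:, 4] = y + 0.05 * rng.standard_normal(n)
            frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(10)])
            model = swlda_fit(frame, y)
            assert model.selected_features[0] == "f4"
            exact += model.selected_features == ["f4"]
        assert exact / len(seeds) >= 0.4

    def test_all_constant_features_give_an_empty_model(self):
        y = np.array([0, 1] * 20)
        frame = pd.DataFrame({"a": np.ones(40), "b": np.full(40, 3.0)})
        model = swlda_fit(frame, y)
        assert model.is_empty
        assert model.intercept == pytest.approx(0.5)

    def test_null_feature_enters_at_the_alpha_enter_rate(self):
        """Type-I rate of the forward step ~ alpha_enter = 0.05."""
        rng = np.random.default_rng(1)
        n = 200
        entered = 0
        runs = 1000
        for _ in range(runs):
            y = rng.integers(0, 2, n)
            frame = pd.DataFrame({"f0": rng.standard_normal(n)})
            entered += not swlda_fit(frame, y).is_empty
        assert abs(entered / runs - 0.05) <= 0.02

    def test_stepwise_rss_matches_exhaustive_subset_oracle(self):
        """Final-model RSS within 1% of the best same-size subset, and the
        planted feature recovered, over seeded problems (<= 10 candidates)."""
        hits = 0
        seeds = range(30)
        for seed in seeds:
            rng = np.random.default_rng(seed)
            n, p = 200, 10
            y = rng.integers(0, 2, n).astype(float)
            X = rng.standard_normal((n, p))
            X[:, 3] += 0.8 * y  # moderate planted effect
            frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])
            model = swlda_fit(frame, y.astype(int))
            if "f3" in model.selected_features:
                hits += 1
            if model.is_empty:
                continue
            rss = model_rss(model, frame, y)
            best = exhaustive_best_rss(X, y, len(model.selected_features))
            assert rss <= 1.01 * best, f"seed {seed}: {rss} vs oracle {best}"
        assert hits / len(seeds) >= 0.9

    def test_label_swap_negates_the_discriminant_direction(self):
        rng = np.random.default_rng(2)
        n = 300
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 6))
        X[:, 0] += 1.0 * y
        X[:, 5] -= 0.7 * y
        frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(6)])
        m1 = swlda_fit(frame, y)
        m2 = swlda_fit(frame, 1 - y)
        assert set(m1.selected_features) == set(m2.selected_features)
        w2 = dict(zip(m2.selected_features, m2.weights))
        for feat, w in zip(m1.selected_features, m1.weights):
            assert w2[feat] == pytest.approx(-w, rel=1e-8)

    def test_selection_probability_increases_with_effect_size(self):
        rates = []
        for effect in (0.2, 0.5, 1.0):
            hits = 0
            for seed in range(50):
                rng = np.random.default_rng(1000 + seed)
                n = 120
                y = rng.integers(0, 2, n)
                X = rng.standard_normal((n, 5))
                X[:, 2] += effect * y
                frame = pd.DataFrame(X, columns=[f"f{i}" for i in range(5)])
                hits += "f2" in swlda_fit(frame, y).selected_features
            rates.append(hits / 50)
        assert rates[0] <= rates[1] <= rates[2]

    def test_single_class_labels_are_an_error(self):
        frame = pd.DataFrame({"a": np.arange(10.0)})
        with pytest.raises(ValueError, match="class"):
            swlda_fit(frame, np.ones(10, dtype=int))


class TestSwldaScore:
    def test_empty_model_scores_its_intercept(self):
        model = SWLDAModel([], np.empty(0), 0.5)
        frame = pd.DataFrame({"a": np.arange(4.0)})
        out = swlda_score(model, frame)
        assert np.allclose(out.vi, 0.5)

    def test_zero_features_score_the_intercept(self):
        model = SWLDAModel(["a"], np.array([2.0]), 0.3)
        frame = pd.DataFrame({"a": np.zeros(5)})
        assert np.allclose(swlda_score(model, frame).vi, 0.3)

    def test_training_scores_separate_the_classes(self):
        rng = np.random.default_rng(3)
        n = 200
        y = rng.integers(0, 2, n)
        X = rng.standard_normal((n, 4))
        X[:, 1] += 1.5 * y
        frame = pd.DataFrame(X, columns=list("abcd"))
        model = swlda_fit(frame, y)
        vi = swlda_score(model, frame).vi
        assert vi[y == 1].mean() > vi[y == 0].mean()

    def test_missing_model_column_is_a_schema_error(self):
        model = SWLDAModel(["zz"], np.array([1.0]), 0.0)
        with pytest.raises(KeyError, match="zz"):
            swlda_score(model, pd.DataFrame({"a": [1.0]}))


def cohort_tables(seed, montage, effects, n_subjects=10, n_epochs=60):
    """Synthetic per-subject HV/LV feature tables with planted mean shifts.

    ``effects`` maps <channel>_<band> columns to the LV/HV power ratio.
    Returns (features dict, labels dict, hv frame, lv frame).
    """
    rng = np.random.default_rng(seed)
    cols = [f"{ch}_{band}" for ch in montage for band in BAND_NAMES]
    features, labels = {}, {}
    hv_rows, lv_rows = [], []
    for subj in range(n_subjects):
        subj_scale = rng.uniform(0.8, 1.25, size=len(cols))
        y = np.repeat([1, 0], n_epochs // 2)
        rows = rng.gamma(8.0, 1.0 / 8.0, size=(n_epochs, len(cols))) * subj_scale
        for j, col in enumerate(cols):
            ratio = effects.get(col, 1.0)
            rows[y == 0, j] *= ratio
        frame = pd.DataFrame(rows, columns=cols)
        features[subj] = FeatureTable(frame)
        labels[subj] = y
        hv_rows.append(frame[y == 1].mean())
        lv_rows.append(frame[y == 0].mean())
    return features, labels, pd.DataFrame(hv_rows), pd.DataFrame(lv_rows)


MONTAGE = ["Fpz", "Fz", "F3", "Cz", "Pz", "P3", "Oz"]
PLANTED = {"Pz_alpha": 2.0, "Fz_beta": 1.6, "Fz_gamma": 1.6}


class TestSignificantChannels:
    def test_planted_effects_found_and_nulls_not(self):
        _, _, hv, lv = cohort_tables(0, MONTAGE, PLANTED, n_subjects=12)
        sig = significant_channels(hv, lv)
        assert ("Pz", "alpha") in sig
        assert ("Fz", "beta") in sig
        assert ("F3", "theta") not in sig

    def test_identical_conditions_give_an_empty_set(self):
        _, _, hv, lv = cohort_tables(1, MONTAGE, {}, n_subjects=12)
        assert significant_channels(hv, hv.copy()) == set()

    def test_central_channel_excluded_despite_huge_effect(self):
        _, _, hv, lv = cohort_tables(2, MONTAGE, {"Cz_alpha": 5.0},
                                     n_subjects=12)
        sig = significant_channels(hv, lv)
        assert all(ch != "Cz" for ch, _ in sig)

    def test_few_subjects_warns_but_proceeds(self):
        _, _, hv, lv = cohort_tables(3, MONTAGE, PLANTED, n_subjects=4)
        with pytest.warns(UserWarning, match="subjects"):
            significant_channels(hv, lv)


class TestPruneRedundant:
    def frames(self):
        """Pz and P3 carry the same vigilance effect (redundant, noisy
        copies); Oz carries a far larger one (distinct information)."""
        rng = np.random.default_rng(4)
        n = 12
        base = rng.gamma(8.0, 1.0, size=n)
        hv = pd.DataFrame({
            "Pz_alpha": base + rng.normal(0, 0.1, n),
            "P3_alpha": base + rng.normal(0, 0.1, n),
            "Oz_alpha": base + rng.normal(0, 0.1, n),
        })
        lv = pd.DataFrame({
            "Pz_alpha": hv["Pz_alpha"] * 2.0 + rng.normal(0, 0.3, n),
            "P3_alpha": hv["P3_alpha"] * 2.0 + rng.normal(0, 0.3, n),
            "Oz_alpha": hv["Oz_alpha"] * 6.0 + rng.normal(0, 0.3, n),
        })
        return hv, lv

    def test_redundant_pair_keeps_the_larger_gap(self):
        hv, lv = self.frames()
        pruned = prune_redundant({("Pz", "alpha"), ("P3", "alpha")}, hv, lv)
        assert len(pruned) == 1
        (kept_ch, _), = pruned
        gap = {ch: abs(hv[f"{ch}_alpha"].mean() - lv[f"{ch}_alpha"].mean())
               for ch in ("Pz", "P3")}
        assert gap[kept_ch] == max(gap.values())

    def test_significantly_different_pair_is_kept_whole(self):
        hv, lv = self.frames()
        pruned = prune_redundant({("Pz", "alpha"), ("Oz", "alpha")}, hv, lv)
        assert pruned == {("Pz", "alpha"), ("Oz", "alpha")}

    def test_singleton_area_is_unchanged(self):
        hv, lv = self.frames()
        assert prune_redundant({("Oz", "alpha")}, hv, lv) == {("Oz", "alpha")}


class TestFeatureMap:
    def test_counts_bounded_by_subjects(self):
        with pytest.raises(ValueError, match="n_subjects"):
            FeatureMap({("Pz", "alpha"): 5}, n_subjects=3)

    def test_frame_layout(self):
        fm = FeatureMap({("Pz", "alpha"): 2, ("Fz", "beta"): 1}, n_subjects=3)
        frame = fm.to_frame()
        assert frame.loc["Pz", "alpha"] == 2
        assert frame.loc["Fz", "theta"] == 0


class TestBuildLadder:
    def test_planted_world_recovers_the_two_key_channels(self):
        """Effects only in Pz-alpha and Fz-beta/gamma: the minima
        configuration is {Pz, Fz} in the majority of seeded cohorts."""
        hits = 0
        seeds = range(20)
        for seed in seeds:
            features, labels, _, _ = cohort_tables(seed, MONTAGE, PLANTED,
                                                   n_subjects=10)
            ladder = build_ladder(features, labels, MONTAGE)
            if "2Ch" in ladder.configurations and \
                    ladder.configurations["2Ch"].channels == {"Pz", "Fz"}:
                hits += 1
        assert hits / len(seeds) > 0.5

    def test_ladder_sizes_are_non_increasing_and_nested(self):
        features, labels, _, _ = cohort_tables(7, MONTAGE, PLANTED,
                                               n_subjects=10)
        ladder = build_ladder(features, labels, MONTAGE)
        sizes = ladder.sizes
        assert sizes["AllCh"] >= sizes["HV-LV"] >= sizes["LAB"] >= sizes["2Ch"] == 2
        cfgs = ladder.configurations
        assert cfgs["HV-LV"].channels <= cfgs["AllCh"].channels
        assert cfgs["LAB"].channels <= cfgs["HV-LV"].channels
        assert cfgs["2Ch"].channels <= cfgs["LAB"].channels

    def test_central_and_prefrontal_channels_never_enter_allch(self):
        features, labels, _, _ = cohort_tables(8, MONTAGE, PLANTED,
                                               n_subjects=8)
        ladder = build_ladder(features, labels, MONTAGE)
        assert "Cz" not in ladder.configurations["AllCh"].channels
        assert "Fpz" not in ladder.configurations["AllCh"].channels

    def test_null_world_truncates_at_allch_with_warning(self):
        features, labels, _, _ = cohort_tables(9, MONTAGE, {}, n_subjects=8)
        with pytest.warns(UserWarning, match="truncated"):
            ladder = build_ladder(features, labels, MONTAGE)
        assert list(ladder.configurations) == ["AllCh"]

    def test_single_subject_cohort_is_an_error(self):
        features, labels, _, _ = cohort_tables(10, MONTAGE, PLANTED,
                                               n_subjects=1)
        with pytest.raises(ValueError, match="2 subjects"):
            build_ladder(features, labels, MONTAGE)
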