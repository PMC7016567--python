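"""SWLDA vigilance index and channel-configuration reduction.

The discriminant is a stepwise linear discriminant analysis (SWLDA): an
ordinary-least-squares regression of the class labels (1 = high vigilance,
0 = low vigilance) on (channel, band) power features, with iterative
forward entry (partial-t p-value < alpha_enter = 0.05) and backward removal
(p-value > alpha_remove = 0.1).  The fitted discriminant function scored on
test epochs is the vigilance index (VI); it is not clamped to [0, 1].

Channel configurations are reduced in a ladder:

* AllCh  - every montage channel except central (FC*/C*/CP*) and
           prefrontal (Fp*) sites;
* HV-LV  - features with a significant high- vs low-vigilance difference
           across subjects (Wilcoxon signed rank, p < 0.05), pruned of
           redundant same-area channels;
* LAB    - the union over subjects of SWLDA-selected features on HV-LV;
* 2Ch    - the most-selected channel per band in the cross-subject feature
           map, reduced/padded to exactly two channels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .montage import area_map, is_central, is_prefrontal
from .spectral import BAND_NAMES, FeatureTable

logger = logging.getLogger(__name__)

LADDER_ORDER = ("AllCh", "HV-LV", "LAB", "2Ch")


@dataclass
class SWLDAModel:
    """Stepwise-selected linear discriminant: VI = intercept + w . x."""

    selected_features: list[str]
    weights: np.ndarray
    intercept: float
    alpha_enter: float = 0.05
    alpha_remove: float = 0.10

    def __post_init__(self) -> None:
        if self.alpha_enter >= self.alpha_remove:
            raise ValueError("alpha_enter must be below alpha_remove")
        if len(set(self.selected_features)) != len(self.selected_features):
            raise ValueError("selected features must be unique")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @property
    def is_empty(self) -> bool:
        return not self.selected_features

    def to_dict(self) -> dict:
        return {
            "selected_features": list(self.selected_features),
            "weights": np.asarray(self.weights).tolist(),
            "intercept": float(self.intercept),
            "alpha_enter": self.alpha_enter,
            "alpha_remove": self.alpha_remove,
        }


@dataclass
class VigilanceIndexSeries:
    times: np.ndarray
    vi: np.ndarray

    def __len__(self) -> int:
        return len(self.vi)


@dataclass
class FeatureMap:
    """How many subjects' models selected each (channel, band) feature."""

    counts: dict[tuple[str, str], int]
    n_subjects: int

    def __post_init__(self) -> None:
        for key, c in self.counts.items():
            if not (0 <= c <= self.n_subjects):
                raise ValueError(f"count for {key} outside [0, n_subjects]")

    def channel_totals(self) -> dict[str, int]:
        totals: dict[str, int] = {}
        for (ch, _band), c in self.counts.items():
            totals[ch] = totals.get(ch, 0) + c
        return totals

    def to_frame(self) -> pd.DataFrame:
        channels = sorted({ch for ch, _ in self.counts})
        frame = pd.DataFrame(0, index=channels, columns=list(BAND_NAMES))
        for (ch, band), c in self.counts.items():
            frame.loc[ch, band] = c
        return frame


@dataclass
class ChannelConfiguration:
    """A named channel subset with its admissible (channel, band) features."""

    name: str
    channels: set[str]
    features: set[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.name == "2Ch" and len(self.channels) != 2:
            raise ValueError("2Ch configuration must contain exactly 2 channels")

    @property
    def n_channels(self) -> int:
        return len(self.channels)


@dataclass
class Ladder:
    configurations: dict[str, ChannelConfiguration]
    models: dict[str, dict] = field(default_factory=dict)  # config -> subject -> SWLDAModel
    feature_map: FeatureMap | None = None

    @property
    def sizes(self) -> dict[str, int]:
        return {name: cfg.n_channels for name, cfg in self.configurations.items()}


# ---------------------------------------------------------------------------
# stepwise OLS machinery
# ---------------------------------------------------------------------------

def _ols_pvalues(X: np.ndarray, y: np.ndarray):
    """OLS fit with intercept; returns (coefs, intercept, pvalues, rss, ok).

    ``pvalues`` are the partial-t p-values of the feature coefficients.
    ``ok`` is False when the design is rank deficient.
    """
    n, k = X.shape
    design = np.column_stack([np.ones(n), X])
    coef, _res, rank, _sv = np.linalg.lstsq(design, y, rcond=None)
    if rank < k + 1 or n <= k + 1:
        return coef[1:], coef[0], np.ones(k), np.inf, False
    resid = y - design @ coef
    rss = float(resid @ resid)
    dof = n - k - 1
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 1e-300))
    tvals = coef / se
    pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
    return coef[1:], coef[0], pvals[1:], rss, True


def swlda_fit(
    features: FeatureTable | pd.DataFrame,
    labels: np.ndarray,
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
    max_iter: int = 60,
) -> SWLDAModel:
    """Forward-entry / backward-removal stepwise OLS on class labels.

    Each iteration first tries to admit the excluded feature with the
    smallest partial-t p-value (if < ``alpha_enter``; ties broken by p-value
    then lexicographic name), then removes included features whose p-value
    exceeds ``alpha_remove``, worst first.  Iteration stops when no change
    occurs, a previously visited feature set recurs (cycle guard), or
    ``max_iter`` is reached.  With no admissible feature the model is empty
    (VI = mean label), a valid and logged outcome.
    """
    frame = features.data if isinstance(features, FeatureTable) else features
    y = np.asarray(labels, dtype=float)
    if len(frame) != len(y):
        raise ValueError("features and labels disagree in length")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2 or counts.min() < 2:
        raise ValueError("need at least 2 rows per class")

    # screen constant columns: they can never obtain a finite t-statistic
    variances = frame.var(axis=0, ddof=0)
    candidates = [c for c in frame.columns if variances[c] > 1e-18]
    X_all = frame[candidates].to_numpy(dtype=float)
    col_idx = {c: i for i, c in enumerate(candidates)}

    included: list[str] = []
    seen: set[frozenset] = {frozenset()}
    n = len(y)
    for _ in range(max_iter):
        changed = False
        # forward step: the partial-t p-value of each excluded candidate
        # equals the p-value of the partial correlation between the current
        # residuals of y and of the candidate, so one residualisation of all
        # candidates replaces one OLS refit per candidate
        excluded = sorted(c for c in candidates if c not in included)
        dof = n - len(included) - 2
        if excluded and dof > 0:
            design = np.column_stack(
                [np.ones(n)] + [X_all[:, col_idx[c]] for c in included])
            coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
            e_y = y - design @ coef
            C = X_all[:, [col_idx[c] for c in excluded]]
            B, _, _, _ = np.linalg.lstsq(design, C, rcond=None)
            E = C - design @ B
            ss_e = (E * E).sum(axis=0)
            ss_y = float(e_y @ e_y)
            with np.errstate(invalid="ignore", divide="ignore"):
                r = np.where(ss_e > 1e-18 * np.abs(C).max(axis=0) ** 2 * n,
                             E.T @ e_y / np.sqrt(ss_e * ss_y), 0.0)
                r = np.clip(np.nan_to_num(r), -1 + 1e-15, 1 - 1e-15)
                tvals = r * np.sqrt(dof / (1.0 - r * r))
            pvals = 2.0 * stats.t.sf(np.abs(tvals), dof)
            best = int(np.argmin(pvals))  # ties: lexicographic (sorted names)
            if pvals[best] < alpha_enter:
                included.append(excluded[best])
                changed = True
        # backward sweep
        while len(included) > 0:
            X = X_all[:, [col_idx[c] for c in included]]
            _w, _b, pvals, _rss, ok = _ols_pvalues(X, y)
            if not ok:
                # collinear selected set: drop the latest entrant
                dropped = included.pop()
                logger.info("dropping collinear feature %s", dropped)
                changed = True
                continue
            worst = int(np.argmax(pvals))
            if pvals[worst] > alpha_remove:
                included.pop(worst)
                changed = True
            else:
                break
        state = frozenset(included)
        if not changed:
            break
        if state in seen:
            logger.info("stepwise cycle detected; stopping")
            break
        seen.add(state)

    if not included:
        logger.info("SWLDA selected no features; returning empty model")
        return SWLDAModel([], np.empty(0), float(y.mean()),
                          alpha_enter, alpha_remove)

    X = X_all[:, [col_idx[c] for c in included]]
    weights, intercept, _p, _rss, _ok = _ols_pvalues(X, y)
    return SWLDAModel(list(included), np.asarray(weights), float(intercept),
                      alpha_enter, alpha_remove)


def swlda_score(model: SWLDAModel,
                features: FeatureTable | pd.DataFrame) -> VigilanceIndexSeries:
    """Score features with the discriminant function: the vigilance index."""
    frame = features.data if isinstance(features, FeatureTable) else features
    missing = set(model.selected_features) - set(frame.columns)
    if missing:
        raise KeyError(f"features missing model columns: {sorted(missing)}")
    if model.is_empty:
        vi = np.full(len(frame), model.intercept)
    else:
        vi = model.intercept + frame[model.selected_features].to_numpy() @ model.weights
    if isinstance(features, FeatureTable) and "epoch_start" in features.meta:
        times = features.meta["epoch_start"].to_numpy()
    else:
        times = np.arange(len(frame), dtype=float)
    return VigilanceIndexSeries(times=times, vi=np.asarray(vi, dtype=float))


# ---------------------------------------------------------------------------
# high- vs low-vigilance channel statistics
# ---------------------------------------------------------------------------

def _paired_wilcoxon_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided signed-rank p; identical vectors count as maximally
    non-significant (p = 1)."""
    diff = np.asarray(a) - np.asarray(b)
    if np.allclose(diff, 0):
        return 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(stats.wilcoxon(a, b, zero_method="wilcox").pvalue)


def significant_channels(
    hv: pd.DataFrame,
    lv: pd.DataFrame,
    alpha: float = 0.05,
) -> set[tuple[str, str]]:
    """Features with a significant high- vs low-vigilance difference.

    ``hv`` and ``lv`` are per-subject mean band powers (rows = subjects,
    columns = ``<channel>_<band>``).  Central (FC*/C*/CP*) and prefrontal
    (Fp*) channels are excluded a priori: central sites reflect hand
    movements rather than vigilance, prefrontal sites carry ocular residue.
    """
    if list(hv.columns) != list(lv.columns):
        raise ValueError("HV and LV tables must share columns")
    if len(hv) < 6:
        warnings.warn("fewer than 6 subjects: signed-rank resolution is "
                      "limited", stacklevel=2)
    out: set[tuple[str, str]] = set()
    for col in hv.columns:
        ch, band = col.rsplit("_", 1)
        if is_central(ch) or is_prefrontal(ch):
            continue
        if _paired_wilcoxon_p(hv[col].to_numpy(), lv[col].to_numpy()) < alpha:
            out.add((ch, band))
    return out


def prune_redundant(
    candidates: set[tuple[str, str]],
    hv: pd.DataFrame,
    lv: pd.DataFrame,
    areas: Mapping[str, str] | None = None,
    alpha: float = 0.05,
) -> set[tuple[str, str]]:
    """Drop same-area channels that carry statistically redundant signal.

    Within each (scalp area, band) group, two channels are compared on their
    per-subject high-minus-low-vigilance power changes (signed rank).  A
    non-significant difference (p >= alpha) marks the pair as redundant and
    only the channel with the larger |mean HV - mean LV| gap is retained; a
    significant difference means the channels carry distinct information and
    both are kept.  Channels are screened in decreasing gap order so the
    strongest representative of each redundancy group survives.
    """
    if areas is None:
        areas = area_map({ch for ch, _ in candidates})
    for ch, _band in candidates:
        if ch not in areas:
            raise KeyError(f"channel {ch} missing from area map")

    kept: set[tuple[str, str]] = set()
    groups: dict[tuple[str, str], list[str]] = {}
    for ch, band in candidates:
        groups.setdefault((areas[ch], band), []).append(ch)

    for (_area, band), channels in sorted(groups.items()):
        def gap(ch: str) -> float:
            col = f"{ch}_{band}"
            return abs(float(hv[col].mean() - lv[col].mean()))

        ordered = sorted(channels, key=lambda c: (-gap(c), c))
        retained: list[str] = []
        for ch in ordered:
            col = f"{ch}_{band}"
            change = hv[col].to_numpy() - lv[col].to_numpy()
            redundant = False
            for other in retained:
                ocol = f"{other}_{band}"
                other_change = hv[ocol].to_numpy() - lv[ocol].to_numpy()
                if _paired_wilcoxon_p(change, other_change) >= alpha:
                    redundant = True
                    break
            if not redundant:
                retained.append(ch)
        kept.update((ch, band) for ch in retained)
    return kept


# ---------------------------------------------------------------------------
# configuration ladder
# ---------------------------------------------------------------------------

def _subject_condition_means(
    features: Mapping[str, FeatureTable],
    labels: Mapping[str, np.ndarray],
    columns: Sequence[str],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    hv_rows, lv_rows, index = [], [], []
    for subject, table in features.items():
        y = np.asarray(labels[subject])
        frame = table.data[list(columns)]
        hv_rows.append(frame[y == 1].mean(axis=0))
        lv_rows.append(frame[y == 0].mean(axis=0))
        index.append(subject)
    return (pd.DataFrame(hv_rows, index=index),
            pd.DataFrame(lv_rows, index=index))


def _pick_two_channels(feature_map: FeatureMap,
                       fallback_order: Sequence[str]) -> set[str]:
    """Most-selected channel per band, reduced/padded to exactly two."""
    per_band_best: list[str] = []
    totals = feature_map.channel_totals()
    for band in BAND_NAMES:
        band_counts = {ch: c for (ch, b), c in feature_map.counts.items()
                       if b == band and c > 0}
        if not band_counts:
            continue
        best = max(sorted(band_counts),
                   key=lambda ch: (band_counts[ch], totals.get(ch, 0)))
        per_band_best.append(best)
    chosen = list(dict.fromkeys(per_band_best))
    if len(chosen) > 2:
        chosen = sorted(chosen, key=lambda ch: (-totals.get(ch, 0), ch))[:2]
    for ch in sorted(totals, key=lambda c: (-totals[c], c)):
        if len(chosen) >= 2:
            break
        if ch not in chosen:
            chosen.append(ch)
    for ch in fallback_order:
        if len(chosen) >= 2:
            break
        if ch not in chosen:
            chosen.append(ch)
    return set(chosen[:2])


def build_ladder(
    features: Mapping[str, FeatureTable],
    labels: Mapping[str, np.ndarray],
    montage: Sequence[str],
    alpha_enter: float = 0.05,
    alpha_remove: float = 0.10,
) -> Ladder:
    """Derive the AllCh -> HV-LV -> LAB -> 2Ch configuration ladder.

    ``features``/``labels`` map subject ids to training feature tables and
    their 1/0 vigilance labels.  Per-subject SWLDA models are (re)fitted for
    every configuration; the cross-subject feature map of the HV-LV fits
    drives the 2Ch choice.  If no feature survives the HV-LV statistics the
    ladder truncates at AllCh with a warning.
    """
    if len(features) < 2:
        raise ValueError("a ladder needs at least 2 subjects")

    allch_channels = [c for c in montage
                      if not (is_central(c) or is_prefrontal(c))]
    allch_pairs = {(ch, band) for ch in allch_channels for band in BAND_NAMES}
    configs: dict[str, ChannelConfiguration] = {
        "AllCh": ChannelConfiguration("AllCh", set(allch_channels), allch_pairs),
    }

    allch_cols = [f"{ch}_{band}" for ch in allch_channels for band in BAND_NAMES]
    hv, lv = _subject_condition_means(features, labels, allch_cols)

    sig = significant_channels(hv, lv)
    feature_map = None
    if not sig:
        warnings.warn("no significant HV-LV features; ladder truncated at "
                      "AllCh", stacklevel=2)
    else:
        hvlv_pairs = prune_redundant(sig, hv, lv)
        configs["HV-LV"] = ChannelConfiguration(
            "HV-LV", {ch for ch, _ in hvlv_pairs}, hvlv_pairs)

        # per-subject SWLDA on HV-LV features -> cross-subject feature map
        counts: dict[tuple[str, str], int] = {p: 0 for p in hvlv_pairs}
        lab_pairs: set[tuple[str, str]] = set()
        for subject, table in features.items():
            model = swlda_fit(table.select(hvlv_pairs), labels[subject],
                              alpha_enter, alpha_remove)
            for col in model.selected_features:
                ch, band = col.rsplit("_", 1)
                counts[(ch, band)] = counts.get((ch, band), 0) + 1
                lab_pairs.add((ch, band))
        feature_map = FeatureMap(counts, n_subjects=len(features))

        if lab_pairs:
            configs["LAB"] = ChannelConfiguration(
                "LAB", {ch for ch, _ in lab_pairs}, lab_pairs)
            fallback = sorted({ch for ch, _ in hvlv_pairs})
            two = _pick_two_channels(feature_map, fallback)
            if len(two) == 2:
                configs["2Ch"] = ChannelConfiguration(
                    "2Ch", two,
                    {(ch, band) for ch in two for band in BAND_NAMES})
        else:
            warnings.warn("SWLDA selected no features on HV-LV; ladder "
                          "truncated", stacklevel=2)

    models: dict[str, dict] = {}
    for name, cfg in configs.items():
        models[name] = {}
        for subject, table in features.items():
            models[name][subject] = swlda_fit(
                table.select(cfg.features), labels[subject],
                alpha_enter, alpha_remove)
    return Ladder(configurations=configs, models=models, feature_map=feature_map)
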