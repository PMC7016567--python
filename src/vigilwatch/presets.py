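"""Desk-scale study presets.

The default configurations in :mod:`vigilwatch.pipeline` mirror the full
protocols (61 channels, 10x1-min PVT blocks, 45-min scenarios).  The
presets below keep every structural element of those designs — rest
segments, block layout, training-block assignment, filter dialect, default
effect sizes — but shrink montage, block length and cohort so a full cohort
run completes in seconds.  They are the problem sizes used throughout the
test-suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import evaluation as ev
from . import model as md
from . import synthetic as syn
from .montage import ATM_MONTAGE_16, analysis_channels
from .pipeline import StudyConfig, process_session
from .preprocessing import FilterSpec
from .spectral import BAND_NAMES

#: Minimal probe montage: frontal + parietal/occipital sites plus the
#: ocular-correction channel.
PROBE_MONTAGE_8 = ["Fpz", "Fz", "F3", "F4", "Pz", "P3", "P4", "Oz"]


def fast_pvt_config(seed: int = 0, n_subjects: int = 6,
                    block_length: float = 24.0) -> StudyConfig:
    """Scaled PVT replica: 16-channel montage, 10 shortened task blocks.

    Blocks 1 and 9 remain the high/low-vigilance training conditions; rest
    segments are 30 s (the minimum for a stable IAF estimate).
    """
    return StudyConfig(
        experiment="pvt",
        n_subjects=n_subjects,
        montage=list(ATM_MONTAGE_16),
        sampling_rate=250.0,
        n_blocks=10,
        block_length=block_length,
        rest_length=30.0,
        filter_spec=FilterSpec(1.0, 40.0, 5, notch_frequency=50.0),
        seed=seed,
    )


def fast_atm_config(seed: int = 0, n_subjects: int = 6,
                    block_length: float = 40.0) -> StudyConfig:
    """Scaled ATM replica: 3-block calibration, 3-block test scenarios."""
    return StudyConfig(
        experiment="atm",
        n_subjects=n_subjects,
        montage=list(ATM_MONTAGE_16),
        sampling_rate=256.0,
        n_blocks=3,
        block_length=block_length,
        rest_length=30.0,
        n_test_blocks=3,
        test_block_length=block_length,
        filter_spec=FilterSpec(1.0, 40.0, 5, notch_frequency=None),
        seed=seed,
    )


def two_session_auc(seed: int, effect_sizes: dict | None = None,
                    block_length: float = 40.0) -> float:
    """Single-subject discrimination probe: cross-session test AUC.

    Two 3-block sessions (first block high vigilance, last block low) are
    simulated for one subject; a SWLDA fitted on session 1's labelled blocks
    scores session 2's labelled blocks.  With all effect sizes at 1 this
    probes the null calibration of the whole chain (AUC ~ 0.5); with the
    default planted effects it probes its sensitivity.
    """
    cfg = StudyConfig(
        experiment="atm", n_subjects=1, montage=list(PROBE_MONTAGE_8),
        sampling_rate=250.0, n_blocks=3, block_length=block_length,
        rest_length=30.0, effect_sizes=effect_sizes, seed=seed,
    )
    rng = np.random.default_rng(seed)
    iaf = float(rng.uniform(8.5, 11.5))
    kwargs = {} if effect_sizes is None else {"effect_sizes": dict(effect_sizes)}
    sessions = []
    for sess_seed in rng.integers(0, 2**31 - 1, size=2):
        spec = syn.SimulationSpec(
            channel_labels=cfg.montage, sampling_rate=cfg.sampling_rate,
            duration=cfg.n_blocks * block_length, iaf=iaf,
            rng_seed=int(sess_seed), **kwargs)
        rec, _gt = syn.generate_atm_session(spec, cfg.n_blocks, block_length,
                                            cfg.rest_length)
        sessions.append(process_session(rec, cfg))

    def labelled(sess):
        blocks = sess.table.meta["block"].to_numpy()
        mask = (blocks == 1) | (blocks == cfg.n_blocks)
        table = sess.table.rows(mask)
        return table, (table.meta["block"].to_numpy() == 1).astype(int)

    cols = [(ch, band) for ch in analysis_channels(cfg.montage)
            for band in BAND_NAMES]
    train, y_train = labelled(sessions[0])
    test, y_test = labelled(sessions[1])
    model = md.swlda_fit(train.select(cols), y_train)
    scores = md.swlda_score(model, test.select(cols))
    return ev.roc_evaluate(scores, y_test).auc


def pvt_rmcorr_r(seed: int, n_subjects: int = 3,
                 block_length: float = 18.0) -> float:
    """One scaled PVT cohort's VI-vs-RT repeated-measures correlation.

    Each subject performs one 10-block PVT session; a SWLDA trained on
    blocks 1 (high) and 9 (low) scores the held-out blocks, and per-block
    mean VI is correlated with per-block mean reaction time across subjects.
    Returns the signed rmcorr coefficient.
    """
    cfg = StudyConfig(
        experiment="pvt", n_subjects=n_subjects,
        montage=list(PROBE_MONTAGE_8), sampling_rate=250.0, n_blocks=10,
        block_length=block_length, rest_length=30.0, seed=seed,
    )
    rng = np.random.default_rng(seed)
    cols = [(ch, band) for ch in analysis_channels(cfg.montage)
            for band in BAND_NAMES]
    test_blocks = [b for b in range(1, 11) if b not in (1, 9)]
    subjects, vi_obs, rt_obs = [], [], []
    for subject in range(n_subjects):
        iaf = float(rng.uniform(8.5, 11.5))
        spec = syn.SimulationSpec(
            channel_labels=cfg.montage, sampling_rate=cfg.sampling_rate,
            duration=10 * block_length, iaf=iaf,
            rng_seed=int(rng.integers(0, 2**31 - 1)))
        rec, _gt, rt = syn.generate_pvt_session(spec, 10, block_length,
                                                cfg.rest_length)
        sess = process_session(rec, cfg)
        blocks = sess.table.meta["block"].to_numpy()
        train_mask = (blocks == 1) | (blocks == 9)
        train = sess.table.rows(train_mask)
        y = (train.meta["block"].to_numpy() == 1).astype(int)
        model = md.swlda_fit(train.select(cols), y)
        scores = md.swlda_score(model, sess.table.select(cols))
        for b in test_blocks:
            sel = blocks == b
            if sel.any():
                subjects.append(subject)
                vi_obs.append(float(scores.vi[sel].mean()))
                rt_obs.append(float(rt.block_means[b - 1]))
    return ev.rmcorr(subjects, np.asarray(rt_obs), np.asarray(vi_obs)).r
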