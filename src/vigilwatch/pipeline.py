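"""End-to-end study replicas over synthetic cohorts, plus recording I/O.

Experiment 1 replicates a laboratory psychomotor-vigilance-task (PVT)
design: each subject performs two PVT sessions; block 1 (high vigilance,
label 1) and block 9 (low vigilance, label 0) of the training session fit
the SWLDA, which is evaluated on the other session's labelled blocks and,
in two further validations, on all remaining blocks of the training session
to track the vigilance index (VI) over time.  The VI is finally correlated
with reaction times through the repeated-measures correlation.

Experiment 2 replicates a realistic air-traffic-management (ATM)
supervision design: a 3-block calibration scenario (first block high, last
block low vigilance) trains the models, which are tested on two further
monotonous supervision scenarios (BASELINE and SOLUTION).  The laboratory
LAB channel configuration transfers by intersection with the 16-channel
field montage, and the LAB VI is correlated with the VIs of the other
configurations.

Recordings are exchanged as EDF or as a tab-separated channels x samples
matrix with a JSON sidecar {channels, fs, markers}.
"""

from __future__ import annotations

import json
import logging
import struct
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import evaluation as ev
from . import model as md
from . import preprocessing as pp
from . import spectral as sp
from . import synthetic as syn
from .montage import ATM_MONTAGE_16, PVT_MONTAGE_61, analysis_channels

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Cohort, protocol layout, and processing dialect of one study replica."""

    experiment: str  # "pvt" | "atm"
    n_subjects: int
    montage: list[str]
    sampling_rate: float
    n_blocks: int
    block_length: float
    rest_length: float = 60.0
    n_test_blocks: int = 9        # atm only: test-scenario blocks
    test_block_length: float = 300.0
    filter_spec: pp.FilterSpec = field(default_factory=pp.FilterSpec)
    thresholds: pp.RejectionThresholds = field(
        default_factory=pp.RejectionThresholds)
    epoch_length: float = 2.0
    epoch_step: float = 0.125
    ocular_channel: str = "Fpz"
    high_block: int = 1
    low_block: int | None = None  # default: 9 for pvt, last block for atm
    effect_sizes: dict | None = None  # None -> generator defaults
    iaf_range: tuple[float, float] = (8.5, 11.5)
    artifact_plan: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in ("pvt", "atm"):
            raise ValueError("experiment must be 'pvt' or 'atm'")
        if self.low_block is None:
            self.low_block = min(9, self.n_blocks) if self.experiment == "pvt" \
                else self.n_blocks
        if self.high_block == self.low_block:
            raise ValueError("training blocks must be disjoint")
        for lab in self.montage:
            from .montage import channel_area
            channel_area(lab)  # raises on invalid labels


def default_pvt_config(seed: int = 0) -> StudyConfig:
    """Laboratory replica: 13 subjects, 61 channels at 250 Hz, two 10x1-min
    PVT sessions with 1-min eyes-open/closed rest, 50 Hz notch enabled."""
    return StudyConfig(
        experiment="pvt", n_subjects=13, montage=list(PVT_MONTAGE_61),
        sampling_rate=250.0, n_blocks=10, block_length=60.0, rest_length=60.0,
        filter_spec=pp.FilterSpec(1.0, 40.0, 5, notch_frequency=50.0),
        seed=seed,
    )


def default_atm_config(seed: int = 0) -> StudyConfig:
    """Field replica: 10 ATCOs, 16 channels at 256 Hz, 3x5-min calibration
    and 45-min (9x5-min) test scenarios, no notch (1-40 Hz band only)."""
    return StudyConfig(
        experiment="atm", n_subjects=10, montage=list(ATM_MONTAGE_16),
        sampling_rate=256.0, n_blocks=3, block_length=300.0, rest_length=60.0,
        n_test_blocks=9, test_block_length=300.0,
        filter_spec=pp.FilterSpec(1.0, 40.0, 5, notch_frequency=None),
        seed=seed,
    )


@dataclass
class SessionFeatures:
    """Processed session: baseline-normalised task features + bookkeeping."""

    table: sp.FeatureTable  # task rows, normalised; meta has condition/block
    iaf: float
    rejected_fraction: float
    n_epochs: int


@dataclass
class RunReport:
    experiment: str
    config_channels: dict[str, list[str]]
    ladder_sizes: dict[str, int]
    auc: dict[str, pd.DataFrame]            # validation -> subject x config
    max_accuracy: dict[str, pd.DataFrame]
    feature_map: md.FeatureMap | None
    vi_trends: dict[str, ev.BlockTrend]
    rmcorr_results: dict[str, ev.RmcorrResult]
    rejected_fractions: pd.DataFrame        # subject x session
    iaf_estimates: dict

    def mean_auc(self) -> pd.Series:
        """Mean AUC per configuration over subjects and validations."""
        return pd.concat(self.auc.values()).mean(axis=0)

    def mean_max_accuracy(self) -> pd.Series:
        return pd.concat(self.max_accuracy.values()).mean(axis=0)

    def summary(self) -> dict:
        return {
            "experiment": self.experiment,
            "ladder_sizes": self.ladder_sizes,
            "config_channels": {k: sorted(v) for k, v in
                                self.config_channels.items()},
            "mean_auc": {k: float(v) for k, v in self.mean_auc().items()},
            "mean_max_accuracy": {k: float(v) for k, v in
                                  self.mean_max_accuracy().items()},
            "rmcorr": {name: {"r": res.r, "p": res.p, "dof": res.dof}
                       for name, res in self.rmcorr_results.items()},
            "vi_trend_slopes": {name: tr.slope
                                for name, tr in self.vi_trends.items()},
            "vi_trend_contrast_p": {name: tr.contrast_p
                                    for name, tr in self.vi_trends.items()},
            "mean_rejected_fraction": float(
                self.rejected_fractions.to_numpy().mean()),
            "iaf_estimates": {str(k): float(v)
                              for k, v in self.iaf_estimates.items()},
        }

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(self.summary(), fh, indent=2)
        rows = []
        for validation, frame in self.auc.items():
            macc = self.max_accuracy[validation]
            for subject in frame.index:
                for config in frame.columns:
                    rows.append({
                        "validation": validation, "subject": subject,
                        "config": config,
                        "auc": frame.loc[subject, config],
                        "max_accuracy": macc.loc[subject, config],
                    })
        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
        if self.feature_map is not None:
            self.feature_map.to_frame().to_csv(out / "featuremap.csv")
        with open(out / "ladder.json", "w") as fh:
            json.dump({k: sorted(v) for k, v in self.config_channels.items()},
                      fh, indent=2)


# ---------------------------------------------------------------------------
# per-session processing
# ---------------------------------------------------------------------------

def process_session(rec: syn.Recording, cfg: StudyConfig) -> SessionFeatures:
    """Full conditioning + spectral chain for one marked session.

    Filter, ocular regression, epoching, artifact rejection, per-epoch PSD,
    IAF-anchored band powers, and subtraction of the eyes-open baseline from
    the task rows.  Epochs straddling a segment boundary are dropped.
    """
    filtered = pp.bandpass_filter(rec, cfg.filter_spec)
    if cfg.ocular_channel in rec.channel_labels:
        filtered = pp.regress_out_ocular(filtered, cfg.ocular_channel)
        # the ocular channel serves correction only; it keeps its raw blinks
        # and must not feed the artifact criteria or the features
        keep = [i for i, c in enumerate(filtered.channel_labels)
                if c != cfg.ocular_channel]
        filtered = syn.Recording(
            filtered.samples[keep],
            filtered.sampling_rate,
            [filtered.channel_labels[i] for i in keep],
            list(filtered.markers),
        )
    epochs = pp.epoch(filtered, cfg.epoch_length, cfg.epoch_step)
    epochs = pp.reject_artifacts(epochs, cfg.thresholds)

    # IAF from the eyes-closed rest segment
    oc = [(t0, t1) for t0, t1, lab in rec.segment_bounds() if lab == "OC"]
    if oc:
        iaf = sp.estimate_iaf(filtered.crop(*oc[0]))
    else:
        logger.warning("no OC segment; IAF falls back to default")
        iaf = sp.IAF_FALLBACK
    scheme = sp.define_bands(iaf)

    tensor = sp.compute_psd(epochs)
    features = sp.band_power(tensor, scheme)

    # assign each epoch to the segment fully containing it
    bounds = rec.segment_bounds()
    conditions, blocks = [], []
    for s in features.meta["epoch_start"]:
        seg = next((lab for t0, t1, lab in bounds
                    if s >= t0 - 1e-9 and s + cfg.epoch_length <= t1 + 1e-9),
                   None)
        conditions.append(seg)
        blocks.append(int(seg[1:]) if seg and seg.startswith("B") else 0)
    features.meta["condition"] = conditions
    features.meta["block"] = blocks

    cond = features.meta["condition"]
    baseline = features.rows((cond.isin(["OA", "REF"])).to_numpy())
    task = features.rows(cond.str.startswith("B", na=False).to_numpy())
    if not len(baseline.data) or not len(task.data):
        raise ValueError("session lacks baseline or task epochs")
    task = sp.baseline_normalize(task, baseline)
    return SessionFeatures(
        table=task, iaf=iaf,
        rejected_fraction=epochs.rejected_fraction,
        n_epochs=epochs.n_epochs,
    )


def _train_rows(sess: SessionFeatures, cfg: StudyConfig):
    blocks = sess.table.meta["block"].to_numpy()
    mask = (blocks == cfg.high_block) | (blocks == cfg.low_block)
    table = sess.table.rows(mask)
    y = (table.meta["block"].to_numpy() == cfg.high_block).astype(int)
    return table, y


def _labelled_rows(sess: SessionFeatures, high: int, low: int):
    blocks = sess.table.meta["block"].to_numpy()
    mask = (blocks == high) | (blocks == low)
    table = sess.table.rows(mask)
    y = (table.meta["block"].to_numpy() == high).astype(int)
    return table, y


def _subject_specs(cfg: StudyConfig, n_sessions: int):
    """Per-subject IAF and per-session generator seeds (deterministic)."""
    rng = np.random.default_rng(cfg.seed)
    out = []
    for _ in range(cfg.n_subjects):
        iaf = float(rng.uniform(*cfg.iaf_range))
        seeds = [int(s) for s in rng.integers(0, 2**31 - 1, size=n_sessions)]
        out.append((iaf, seeds))
    return out


def _make_spec(cfg: StudyConfig, iaf: float, seed: int,
               task_duration: float) -> syn.SimulationSpec:
    kwargs = {}
    if cfg.effect_sizes is not None:
        kwargs["effect_sizes"] = dict(cfg.effect_sizes)
    return syn.SimulationSpec(
        channel_labels=list(cfg.montage),
        sampling_rate=cfg.sampling_rate,
        duration=task_duration,
        iaf=iaf,
        artifact_plan=list(cfg.artifact_plan),
        rng_seed=seed,
        **kwargs,
    )


def _fit_score_auc(ladder: md.Ladder, train, test, cfg: StudyConfig):
    """Per-subject, per-configuration fit on train rows, ROC on test rows."""
    auc = {}
    macc = {}
    for name, config in ladder.configurations.items():
        auc[name], macc[name] = {}, {}
        for subject in train:
            table, y = train[subject]
            model = md.swlda_fit(table.select(config.features), y)
            test_table, y_test = test[subject]
            scores = md.swlda_score(model, test_table.select(config.features))
            roc = ev.roc_evaluate(scores, y_test)
            auc[name][subject] = roc.auc
            macc[name][subject] = roc.max_accuracy
    return pd.DataFrame(auc), pd.DataFrame(macc)


# ---------------------------------------------------------------------------
# experiment 1: PVT
# ---------------------------------------------------------------------------

def run_experiment1(cfg: StudyConfig) -> RunReport:
    """Laboratory replica: four validations over a simulated PVT cohort.

    Train on blocks 1/9 of one session, test on the labelled blocks of the
    other session (two cross-session validations) and on all remaining
    blocks of the training session (two within-session VI-trend
    validations); then correlate per-block VI with per-block reaction time.
    """
    if cfg.experiment != "pvt":
        raise ValueError("config is not a PVT study")
    task_duration = cfg.n_blocks * cfg.block_length

    sessions: dict[int, list[SessionFeatures]] = {}
    rts: dict[int, list[syn.RTSeries]] = {}
    rejected = {}
    iafs = {}
    for subject, (iaf, seeds) in enumerate(_subject_specs(cfg, 2)):
        sessions[subject], rts[subject] = [], []
        rejected[subject] = {}
        for s_idx, seed in enumerate(seeds):
            spec = _make_spec(cfg, iaf, seed, task_duration)
            rec, _gt, rt = syn.generate_pvt_session(
                spec, cfg.n_blocks, cfg.block_length, cfg.rest_length)
            sess = process_session(rec, cfg)
            sessions[subject].append(sess)
            rts[subject].append(rt)
            rejected[subject][f"PVT{s_idx + 1}"] = sess.rejected_fraction
        iafs[subject] = sessions[subject][0].iaf

    train1 = {s: _train_rows(sessions[s][0], cfg) for s in sessions}
    train2 = {s: _train_rows(sessions[s][1], cfg) for s in sessions}

    ladder = md.build_ladder({s: t for s, (t, _y) in train1.items()},
                             {s: y for s, (_t, y) in train1.items()},
                             cfg.montage)

    auc, macc = {}, {}
    auc["PVT1->PVT2"], macc["PVT1->PVT2"] = _fit_score_auc(
        ladder, train1, train2, cfg)
    auc["PVT2->PVT1"], macc["PVT2->PVT1"] = _fit_score_auc(
        ladder, train2, train1, cfg)

    # within-session validations: score every non-training block
    trend_config = ladder.configurations.get(
        "LAB", ladder.configurations["AllCh"])
    task_start = 2 * cfg.rest_length
    bounds = [task_start + b * cfg.block_length
              for b in range(cfg.n_blocks + 1)]
    test_blocks = [b for b in range(1, cfg.n_blocks + 1)
                   if b not in (cfg.high_block, cfg.low_block)]

    vi_trends = {}
    rm_subjects, rm_vi, rm_rt = [], [], []
    for s_idx, name in ((0, "PVT1 remaining"), (1, "PVT2 remaining")):
        series = {}
        train = train1 if s_idx == 0 else train2
        for subject in sessions:
            table, y = train[subject]
            model = md.swlda_fit(table.select(trend_config.features), y)
            sess = sessions[subject][s_idx]
            series[subject] = md.swlda_score(
                model, sess.table.select(trend_config.features))
            # per-block observations for the VI-RT repeated-measures corr.,
            # restricted to blocks held out from training
            blocks = sess.table.meta["block"].to_numpy()
            vi = series[subject].vi
            rt_means = rts[subject][s_idx].block_means
            for b in test_blocks:
                sel = blocks == b
                if sel.any():
                    rm_subjects.append(subject)
                    rm_vi.append(float(vi[sel].mean()))
                    rm_rt.append(float(rt_means[b - 1]))
        vi_trends[name] = ev.vi_trend(series, bounds)

    rmcorr_results = {
        "VI~RT": ev.rmcorr(rm_subjects, np.asarray(rm_rt), np.asarray(rm_vi))
    }

    return RunReport(
        experiment="pvt",
        config_channels={k: sorted(c.channels)
                         for k, c in ladder.configurations.items()},
        ladder_sizes=ladder.sizes,
        auc=auc,
        max_accuracy=macc,
        feature_map=ladder.feature_map,
        vi_trends=vi_trends,
        rmcorr_results=rmcorr_results,
        rejected_fractions=pd.DataFrame(rejected).T,
        iaf_estimates=iafs,
    )


# ---------------------------------------------------------------------------
# experiment 2: ATM
# ---------------------------------------------------------------------------

def run_experiment2(cfg: StudyConfig,
                    lab_channels: Sequence[str]) -> RunReport:
    """Field replica: calibration-trained models tested on two scenarios.

    ``lab_channels`` is the LAB configuration from a laboratory run; it is
    intersected with this study's montage (the transfer rule) before
    refitting.  Reports per-scenario ROC metrics plus the repeated-measures
    correlation between the LAB VI and every other configuration's VI.
    """
    if cfg.experiment != "atm":
        raise ValueError("config is not an ATM study")
    cal_duration = cfg.n_blocks * cfg.block_length
    test_duration = cfg.n_test_blocks * cfg.test_block_length
    scenarios = ("BASELINE", "SOLUTION")

    calib: dict[int, SessionFeatures] = {}
    tests: dict[str, dict[int, SessionFeatures]] = {s: {} for s in scenarios}
    rejected, iafs = {}, {}
    for subject, (iaf, seeds) in enumerate(_subject_specs(cfg, 3)):
        rejected[subject] = {}
        spec = _make_spec(cfg, iaf, seeds[0], cal_duration)
        rec, _gt = syn.generate_atm_session(
            spec, cfg.n_blocks, cfg.block_length, cfg.rest_length)
        calib[subject] = process_session(rec, cfg)
        rejected[subject]["CALIBRATION"] = calib[subject].rejected_fraction
        iafs[subject] = calib[subject].iaf
        for scen, seed in zip(scenarios, seeds[1:]):
            spec = _make_spec(cfg, iaf, seed, test_duration)
            rec, _gt = syn.generate_atm_session(
                spec, cfg.n_test_blocks, cfg.test_block_length,
                cfg.rest_length)
            tests[scen][subject] = process_session(rec, cfg)
            rejected[subject][scen] = tests[scen][subject].rejected_fraction

    train = {s: _train_rows(calib[s], cfg) for s in calib}
    ladder = md.build_ladder({s: t for s, (t, _y) in train.items()},
                             {s: y for s, (_t, y) in train.items()},
                             cfg.montage)

    # LAB transfer: intersect the laboratory configuration with this montage
    usable = set(analysis_channels(cfg.montage))
    lab_set = {c for c in lab_channels if c in usable}
    if not lab_set:
        raise ValueError("LAB configuration shares no usable channels with "
                         "the montage")
    lab_pairs = {(ch, band) for ch in lab_set for band in sp.BAND_NAMES}
    lab_cfg = md.ChannelConfiguration("LAB", lab_set, lab_pairs)
    ordered = {}
    for name in md.LADDER_ORDER:
        if name == "LAB":
            ordered["LAB"] = lab_cfg
        elif name in ladder.configurations:
            ordered[name] = ladder.configurations[name]
    ladder.configurations = ordered

    auc, macc = {}, {}
    for scen in scenarios:
        test = {s: _labelled_rows(tests[scen][s], 1, cfg.n_test_blocks)
                for s in tests[scen]}
        auc[scen], macc[scen] = _fit_score_auc(ladder, train, test, cfg)

    # VI trends per scenario (LAB) and LAB-vs-other-config rmcorr
    task_start = 2 * cfg.rest_length
    bounds = [task_start + b * cfg.test_block_length
              for b in range(cfg.n_test_blocks + 1)]
    vi_trends = {}
    vi_blocks: dict[str, dict] = {name: {} for name in ladder.configurations}
    for scen in scenarios:
        series = {}
        for subject in calib:
            table, y = train[subject]
            sess_table = tests[scen][subject].table
            for name, config in ladder.configurations.items():
                model = md.swlda_fit(table.select(config.features), y)
                scores = md.swlda_score(model,
                                        sess_table.select(config.features))
                blocks = sess_table.meta["block"].to_numpy()
                means = [float(scores.vi[blocks == b].mean())
                         for b in range(1, cfg.n_test_blocks + 1)]
                vi_blocks[name].setdefault((scen, subject), means)
                if name == "LAB":
                    series[subject] = scores
        vi_trends[scen] = ev.vi_trend(series, bounds)

    rmcorr_results = {}
    for name in ladder.configurations:
        if name == "LAB":
            continue
        subjects, x, y = [], [], []
        for key, lab_means in vi_blocks["LAB"].items():
            other = vi_blocks[name][key]
            _scen, subject = key
            for a, b in zip(lab_means, other):
                subjects.append(subject)
                x.append(a)
                y.append(b)
        rmcorr_results[f"LAB~{name}"] = ev.rmcorr(
            subjects, np.asarray(x), np.asarray(y))

    return RunReport(
        experiment="atm",
        config_channels={k: sorted(c.channels)
                         for k, c in ladder.configurations.items()},
        ladder_sizes={k: c.n_channels
                      for k, c in ladder.configurations.items()},
        auc=auc,
        max_accuracy=macc,
        feature_map=ladder.feature_map,
        vi_trends=vi_trends,
        rmcorr_results=rmcorr_results,
        rejected_fractions=pd.DataFrame(rejected).T,
        iaf_estimates=iafs,
    )


# ---------------------------------------------------------------------------
# recording I/O
# ---------------------------------------------------------------------------

def save_recording(rec: syn.Recording, path, fmt: str | None = None) -> None:
    """Write a recording as EDF or as TSV matrix + JSON sidecar."""
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "tsv")
    if fmt == "edf":
        _write_edf(rec, path)
        return
    np.savetxt(path, rec.samples, delimiter="\t", fmt="%.6f")
    sidecar = {
        "channels": list(rec.channel_labels),
        "fs": rec.sampling_rate,
        "markers": [[float(t), lab] for t, lab in rec.markers],
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_recording(path, fmt: str | None = None) -> syn.Recording:
    """Read a recording from EDF (via mne) or TSV + JSON sidecar."""
    path = Path(path)
    fmt = fmt or ("edf" if path.suffix.lower() == ".edf" else "tsv")
    if fmt == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        return syn.Recording(
            samples=raw.get_data() * 1e6,  # V -> uV
            sampling_rate=float(raw.info["sfreq"]),
            channel_labels=list(raw.ch_names),
        )
    sidecar_path = path.with_suffix(".json")
    if not sidecar_path.exists():
        raise ValueError(f"missing JSON sidecar for {path}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    for key in ("channels", "fs"):
        if key not in meta:
            raise ValueError(f"sidecar {sidecar_path} lacks key {key!r}")
    samples = np.loadtxt(path, delimiter="\t", ndmin=2)
    return syn.Recording(
        samples=samples,
        sampling_rate=float(meta["fs"]),
        channel_labels=list(meta["channels"]),
        markers=[(float(t), lab) for t, lab in meta.get("markers", [])],
    )


def _write_edf(rec: syn.Recording, path: Path) -> None:
    """Minimal EDF writer: 1-s data records, int16 quantisation per channel.

    The sampling rate must be a whole number of samples per second; the
    trailing partial second (if any) is dropped.
    """
    fs = rec.sampling_rate
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise ValueError("EDF export needs an integer sampling rate")
    n_ch = len(rec.channel_labels)
    n_records = rec.samples.shape[1] // spr
    if n_records == 0:
        raise ValueError("recording shorter than one EDF record")
    data = rec.samples[:, : n_records * spr]

    phys_min = np.floor(data.min(axis=1)) - 1.0
    phys_max = np.ceil(data.max(axis=1)) + 1.0
    dig_min, dig_max = -32768, 32767

    def f8(x) -> bytes:
        s = f"{x:.8g}"[:8]
        return s.ljust(8).encode("ascii")

    header = b"0".ljust(8)
    header += b"X".ljust(80) + b"X".ljust(80)
    header += b"01.01.00" + b"00.00.00"
    header += str(256 * (1 + n_ch)).ljust(8).encode()
    header += b"".ljust(44)
    header += str(n_records).ljust(8).encode()
    header += f8(1.0)
    header += str(n_ch).ljust(4).encode()

    fields = [
        b"".join(lab[:16].ljust(16).encode() for lab in rec.channel_labels),
        b"".ljust(80) * n_ch,
        b"uV".ljust(8) * n_ch,
        b"".join(f8(v) for v in phys_min),
        b"".join(f8(v) for v in phys_max),
        f8(dig_min) * n_ch,
        f8(dig_max) * n_ch,
        b"".ljust(80) * n_ch,
        str(spr).ljust(8).encode() * n_ch,
        b"".ljust(32) * n_ch,
    ]
    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(header + b"".join(fields))
        for r in range(n_records):
            chunk = data[:, r * spr:(r + 1) * spr]
            digital = np.round((chunk - phys_min[:, None]) * scale[:, None]
                               + dig_min).astype("<i2")
            fh.write(digital.tobytes())


def save_report(report: RunReport, out_dir) -> None:
    report.save(out_dir)
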