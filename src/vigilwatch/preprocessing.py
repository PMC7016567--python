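"""Signal conditioning: filtering, ocular correction, epoching, rejection.

The chain reproduces standard offline EEG conditioning for band-power
analyses: a zero-phase 5th-order Butterworth band-pass (1-40 Hz, optional
50 Hz notch), regression-based eye-blink removal against a dedicated ocular
channel, segmentation into 2-s epochs shifted by 0.125 s, and rejection of
epochs violating any of three artifact criteria on any channel:

* amplitude: any sample beyond +/-100 uV;
* trend: the least-squares linear fit of the epoch has |slope| > 10 uV/s;
* step: any consecutive-sample difference above 25 uV.

Reasons accumulate; an epoch may be rejected for several criteria at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
from scipy import signal

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import Recording


@dataclass(frozen=True)
class FilterSpec:
    highpass_cutoff: float = 1.0
    lowpass_cutoff: float = 40.0
    order: int = 5
    notch_frequency: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.highpass_cutoff < self.lowpass_cutoff):
            raise ValueError("need 0 < highpass < lowpass")
        if self.order < 1:
            raise ValueError("filter order must be >= 1")


@dataclass(frozen=True)
class RejectionThresholds:
    amplitude_limit: float = 100.0  # uV
    slope_limit: float = 10.0       # uV/s
    step_limit: float = 25.0        # uV

    def __post_init__(self) -> None:
        if min(self.amplitude_limit, self.slope_limit, self.step_limit) <= 0:
            raise ValueError("all rejection thresholds must be positive")


@dataclass
class EpochSet:
    """Overlapping fixed-length windows with keep/reject bookkeeping."""

    epochs: np.ndarray  # (epoch, channel, sample), uV
    sampling_rate: float
    channel_labels: list[str]
    epoch_length: float
    step: float
    start_times: np.ndarray
    status: np.ndarray = field(default=None)  # True = keep
    reject_reasons: list[set] = field(default=None)

    def __post_init__(self) -> None:
        if self.status is None:
            self.status = np.ones(len(self.epochs), dtype=bool)
        if self.reject_reasons is None:
            self.reject_reasons = [set() for _ in range(len(self.epochs))]

    @property
    def n_epochs(self) -> int:
        return len(self.epochs)

    @property
    def n_kept(self) -> int:
        return int(self.status.sum())

    @property
    def rejected_fraction(self) -> float:
        return 1.0 - self.n_kept / self.n_epochs

    def report_frame(self):
        """Keep/reject report: epoch start, status, comma-joined reasons."""
        import pandas as pd

        return pd.DataFrame({
            "epoch_start": self.start_times,
            "status": np.where(self.status, "keep", "reject"),
            "reasons": [",".join(sorted(r)) for r in self.reject_reasons],
        })


def bandpass_filter(rec: "Recording", spec: FilterSpec = FilterSpec()) -> "Recording":
    """Zero-phase Butterworth band-pass (and optional notch) filtering.

    Forward-backward application cancels phase distortion, preserving epoch
    alignment for the sliding-window spectral analysis.
    """
    from .synthetic import Recording

    nyq = rec.sampling_rate / 2.0
    if spec.lowpass_cutoff >= nyq:
        raise ValueError("low-pass cutoff must lie below the Nyquist frequency")
    if not np.all(np.isfinite(rec.samples)):
        raise ValueError("recording contains non-finite samples")

    sos = signal.butter(
        spec.order,
        [spec.highpass_cutoff, spec.lowpass_cutoff],
        btype="bandpass",
        fs=rec.sampling_rate,
        output="sos",
    )
    filtered = signal.sosfiltfilt(sos, rec.samples, axis=-1)
    if spec.notch_frequency is not None:
        if spec.notch_frequency >= nyq:
            raise ValueError("notch frequency must lie below Nyquist")
        b, a = signal.iirnotch(spec.notch_frequency, Q=30.0, fs=rec.sampling_rate)
        filtered = signal.filtfilt(b, a, filtered, axis=-1)
    return Recording(filtered, rec.sampling_rate, list(rec.channel_labels),
                     list(rec.markers))


def regress_out_ocular(rec: "Recording", ocular_channel: str = "Fpz") -> "Recording":
    """Remove the ocular channel's blink contribution by linear regression.

    The regression coefficient of each channel onto the ocular channel is
    estimated over blink-active samples (|ocular| beyond 3 robust SDs of its
    median), where the blink source dominates, and the scaled ocular signal
    is subtracted everywhere.  The ocular channel itself is left untouched;
    it carries no brain signal of interest and is excluded downstream.
    """
    from .synthetic import Recording

    if ocular_channel not in rec.channel_labels:
        raise ValueError(f"ocular channel {ocular_channel!r} not in recording")
    oc_idx = rec.channel_labels.index(ocular_channel)
    ocular = rec.samples[oc_idx]
    if np.var(ocular) < 1e-12:
        raise ValueError("ocular channel has zero variance (degenerate regressor)")

    med = np.median(ocular)
    mad_sigma = 1.4826 * np.median(np.abs(ocular - med))
    if mad_sigma > 0:
        active = np.abs(ocular - med) > 3.0 * mad_sigma
    else:
        active = np.zeros_like(ocular, dtype=bool)
    if active.mean() < 1e-3:  # no blinks detected: fall back to full-signal fit
        active = np.ones_like(ocular, dtype=bool)

    oc_a = ocular[active] - ocular[active].mean()
    denom = float(oc_a @ oc_a)
    cleaned = rec.samples.copy()
    oc_centred = ocular - ocular[active].mean()
    for i in range(rec.samples.shape[0]):
        if i == oc_idx:
            continue
        x_a = rec.samples[i, active]
        beta = float((x_a - x_a.mean()) @ oc_a) / denom
        cleaned[i] = rec.samples[i] - beta * oc_centred
    return Recording(cleaned, rec.sampling_rate, list(rec.channel_labels),
                     list(rec.markers))


def epoch(rec: "Recording", epoch_length: float = 2.0,
          step: float = 0.125) -> EpochSet:
    """Cut a recording into left-aligned half-open windows [t, t+length).

    The last partial window is discarded; epoch count equals
    ``floor((duration - length) / step) + 1``.
    """
    if epoch_length <= 0 or step <= 0:
        raise ValueError("epoch_length and step must be positive")
    fs = rec.sampling_rate
    n = rec.samples.shape[1]
    win = int(round(epoch_length * fs))
    hop = int(round(step * fs))
    if n < win:
        raise ValueError("recording shorter than one epoch")
    n_epochs = (n - win) // hop + 1
    view = np.lib.stride_tricks.sliding_window_view(rec.samples, win, axis=-1)
    # float32 keeps the heavily overlapping epoch tensor affordable; uV-scale
    # EEG loses nothing at the tolerances of the downstream statistics
    epochs = np.ascontiguousarray(
        view[:, ::hop].transpose(1, 0, 2)[:n_epochs], dtype=np.float32)
    start_times = np.arange(n_epochs) * (hop / fs)
    return EpochSet(
        epochs=epochs,
        sampling_rate=fs,
        channel_labels=list(rec.channel_labels),
        epoch_length=epoch_length,
        step=step,
        start_times=start_times,
    )


def reject_artifacts(epochs: EpochSet,
                     thresholds: RejectionThresholds = RejectionThresholds()
                     ) -> EpochSet:
    """Flag epochs violating any artifact criterion on any channel.

    The trend criterion fits an ordinary least-squares line per channel per
    epoch and compares |slope| (uV/s) against the threshold.  An empty
    keep-set is a valid outcome.
    """
    if epochs.n_epochs == 0:
        raise ValueError("empty epoch set")
    data = epochs.epochs
    fs = epochs.sampling_rate

    amp_bad = np.abs(data).max(axis=(1, 2)) > thresholds.amplitude_limit

    nsamp = data.shape[-1]
    t = np.arange(nsamp) / fs
    tc = (t - t.mean())
    denom = float(tc @ tc)
    slopes = data @ tc.astype(data.dtype) / denom  # (epoch, channel)
    trend_bad = np.abs(slopes).max(axis=1) > thresholds.slope_limit

    step_bad = np.abs(np.diff(data, axis=-1)).max(axis=(1, 2)) > thresholds.step_limit

    status = epochs.status.copy()
    reasons = [set(r) for r in epochs.reject_reasons]
    for i in range(epochs.n_epochs):
        if amp_bad[i]:
            reasons[i].add("amplitude")
        if trend_bad[i]:
            reasons[i].add("trend")
        if step_bad[i]:
            reasons[i].add("step")
        if reasons[i]:
            status[i] = False
    return EpochSet(
        epochs=epochs.epochs,
        sampling_rate=fs,
        channel_labels=list(epochs.channel_labels),
        epoch_length=epochs.epoch_length,
        step=epochs.step,
        start_times=epochs.start_times,
        status=status,
        reject_reasons=reasons,
    )
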