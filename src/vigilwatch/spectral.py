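"""Per-epoch spectra, individual alpha frequency, and band-power features.

The spectral pipeline mirrors standard practice in passive mental-state
monitoring: a single-taper periodogram with a full-epoch Hanning window is
computed for every 2-s epoch (0.5 Hz resolution), frequency bands are
anchored to the subject's individual alpha frequency (IAF) estimated from an
eyes-closed rest segment, and band powers are summarised per (channel, band)
and optionally normalised by subtracting an eyes-open baseline.

Band scheme (all edges in Hz, half-open intervals)::

    theta = [IAF-6, IAF-2)   alpha = [IAF-2, IAF+2)
    beta  = [IAF+2, IAF+16)  gamma = [IAF+16, IAF+30)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable

import numpy as np
import pandas as pd
from scipy import signal

if TYPE_CHECKING:  # pragma: no cover
    from .preprocessing import EpochSet
    from .synthetic import Recording

logger = logging.getLogger(__name__)

BAND_NAMES = ("theta", "alpha", "beta", "gamma")

#: IAF search range (Hz); the alpha peak of healthy adults lies within it.
IAF_SEARCH_RANGE = (7.0, 13.0)
IAF_FALLBACK = 10.0


@dataclass(frozen=True)
class BandScheme:
    """IAF-anchored frequency bands, contiguous and non-overlapping."""

    iaf: float
    bands: dict[str, tuple[float, float]]

    def __post_init__(self) -> None:
        edges = [self.bands[name] for name in BAND_NAMES]
        for (_, hi), (lo2, _) in zip(edges, edges[1:]):
            if hi != lo2:
                raise ValueError("bands must tile contiguously")
        if edges[0][0] <= 0:
            raise ValueError("band edges must be positive")

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.bands[name]


@dataclass
class SpectralTensor:
    """Per-epoch, per-channel power spectral densities (uV^2/Hz)."""

    psd: np.ndarray  # (epoch, channel, frequency)
    frequencies: np.ndarray
    resolution: float
    channel_labels: list[str]
    start_times: np.ndarray


@dataclass
class FeatureTable:
    """Band powers per kept epoch, one column per ``<channel>_<band>``.

    ``data`` holds the numeric features; ``meta`` carries per-row context
    (subject, condition, block, epoch start).  After baseline subtraction
    values may legitimately be negative.
    """

    data: pd.DataFrame
    meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    normalised: bool = False

    @property
    def feature_pairs(self) -> list[tuple[str, str]]:
        return [tuple(c.rsplit("_", 1)) for c in self.data.columns]

    def select(self, pairs: Iterable[tuple[str, str]]) -> "FeatureTable":
        cols = [f"{ch}_{band}" for ch, band in pairs]
        missing = set(cols) - set(self.data.columns)
        if missing:
            raise KeyError(f"missing feature columns: {sorted(missing)}")
        return FeatureTable(self.data[cols].copy(), self.meta.copy(), self.normalised)

    def rows(self, mask: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            self.data.loc[mask].reset_index(drop=True),
            self.meta.loc[mask].reset_index(drop=True) if len(self.meta) else self.meta,
            self.normalised,
        )

    def to_csv(self, path) -> None:
        frame = pd.concat([self.meta.reset_index(drop=True),
                           self.data.reset_index(drop=True)], axis=1)
        frame.to_csv(path, index=False)


def _hann_periodogram(data: np.ndarray, fs: float):
    """Single-taper Hanning periodogram along the last axis, density scaling.

    Matches ``scipy.signal.periodogram(window="hann", detrend="constant",
    scaling="density")`` but runs one batched rfft over all epochs/channels.
    """
    n = data.shape[-1]
    win = signal.windows.hann(n, sym=False).astype(data.dtype, copy=False)
    demeaned = data - data.mean(axis=-1, keepdims=True)
    demeaned *= win
    spec = np.fft.rfft(demeaned, axis=-1)
    scale = 1.0 / (fs * float(win.astype(np.float64) @ win))
    psd = (spec.real ** 2 + spec.imag ** 2).astype(np.float64) * scale
    psd[..., 1:] *= 2.0
    if n % 2 == 0:  # Nyquist bin is not doubled
        psd[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, psd


def compute_psd(epochs: "EpochSet") -> SpectralTensor:
    """Single-taper Hanning periodogram per kept epoch per channel.

    Density scaling is used, so integrating the PSD over frequency recovers
    the (taper-corrected) epoch variance; the frequency resolution equals
    1 / epoch_length.
    """
    kept = epochs.status
    if not np.any(kept):
        raise ValueError("all epochs rejected; no spectra to compute")
    data = epochs.epochs[kept]
    freqs, psd = _hann_periodogram(data, epochs.sampling_rate)
    return SpectralTensor(
        psd=psd,
        frequencies=freqs,
        resolution=1.0 / epochs.epoch_length,
        channel_labels=list(epochs.channel_labels),
        start_times=np.asarray(epochs.start_times)[kept],
    )


def estimate_iaf(
    rest_eyes_closed: "Recording",
    search_range: tuple[float, float] = IAF_SEARCH_RANGE,
    fallback: float = IAF_FALLBACK,
    epoch_length: float = 2.0,
    channels: list[str] | None = None,
) -> float:
    """Estimate the individual alpha frequency from eyes-closed rest.

    The channel-averaged periodogram over posterior channels is searched for
    its maximum within ``search_range``.  A maximum is only trusted when it is
    prominent (power > 2x the in-range median); otherwise the configured
    fallback (10 Hz by default) is returned with a logged warning, as happens
    on recordings without a discernible alpha peak.
    """
    from .montage import posterior_channels  # local import avoids cycles

    rec = rest_eyes_closed
    n_samp = rec.samples.shape[1]
    fs = rec.sampling_rate
    if n_samp / fs < 30.0:
        raise ValueError("need at least 30 s of eyes-closed rest for IAF")

    if channels is None:
        channels = posterior_channels(rec.channel_labels)
        if not channels:
            logger.warning("no posterior channels; estimating IAF from all channels")
            channels = list(rec.channel_labels)
    idx = [rec.channel_labels.index(c) for c in channels]

    nper = int(round(epoch_length * fs))
    freqs, psd = signal.welch(
        rec.samples[idx],
        fs=fs,
        window="hann",
        nperseg=nper,
        noverlap=nper // 2,
        detrend="constant",
        scaling="density",
        axis=-1,
    )
    mean_psd = psd.mean(axis=0)
    lo, hi = search_range
    in_range = (freqs >= lo) & (freqs <= hi)
    seg = mean_psd[in_range]
    peak_idx = int(np.argmax(seg))
    if seg[peak_idx] <= 2.0 * np.median(seg):
        logger.warning(
            "no prominent alpha peak in %.1f-%.1f Hz; falling back to %.1f Hz",
            lo, hi, fallback,
        )
        return float(fallback)
    return float(freqs[in_range][peak_idx])


def define_bands(iaf: float) -> BandScheme:
    """IAF-anchored theta/alpha/beta/gamma bands (half-open intervals)."""
    if not (7.0 <= iaf <= 13.0):
        raise ValueError(f"IAF {iaf} Hz outside the physiological range [7, 13]")
    return BandScheme(
        iaf=float(iaf),
        bands={
            "theta": (iaf - 6.0, iaf - 2.0),
            "alpha": (iaf - 2.0, iaf + 2.0),
            "beta": (iaf + 2.0, iaf + 16.0),
            "gamma": (iaf + 16.0, iaf + 30.0),
        },
    )


def band_power(spec: SpectralTensor, scheme: BandScheme) -> FeatureTable:
    """Integrate per-epoch PSDs over each band: mean density x band width.

    A frequency bin belongs to the band whose half-open interval
    ``[low, high)`` contains the bin centre, so adjacent bands never double
    count a bin.  Powers are in uV^2.
    """
    freqs = spec.frequencies
    cols: dict[str, np.ndarray] = {}
    for band in BAND_NAMES:
        lo, hi = scheme[band]
        mask = (freqs >= lo) & (freqs < hi)
        if not mask.any():
            raise ValueError(f"band {band} [{lo}, {hi}) contains no frequency bins")
        power = spec.psd[:, :, mask].mean(axis=-1) * (hi - lo)
        for j, ch in enumerate(spec.channel_labels):
            cols[f"{ch}_{band}"] = power[:, j]
    # channel-major column order
    ordered = [f"{ch}_{band}" for ch in spec.channel_labels for band in BAND_NAMES]
    data = pd.DataFrame(cols)[ordered]
    meta = pd.DataFrame({"epoch_start": spec.start_times})
    return FeatureTable(data=data, meta=meta, normalised=False)


def baseline_normalize(task: FeatureTable, baseline: FeatureTable) -> FeatureTable:
    """Subtract the per-column baseline mean (eyes-open rest) from task rows.

    Linear-scale subtraction reduces between-subject variability in absolute
    power; the result is flagged so it cannot be normalised twice.
    """
    if task.normalised:
        raise ValueError("feature table already baseline-normalised")
    if list(task.data.columns) != list(baseline.data.columns):
        raise ValueError("task and baseline feature columns differ")
    data = task.data - baseline.data.mean(axis=0)
    return FeatureTable(data=data, meta=task.meta.copy(), normalised=True)
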