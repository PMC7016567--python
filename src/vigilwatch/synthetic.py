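"""Synthetic EEG sessions with a controllable latent vigilance state.

The generator produces multi-channel recordings with the statistical
structure the downstream analysis assumes, so the whole chain is testable
without real data:

* per-channel 1/f^gamma coloured background noise;
* a band-limited alpha oscillator centred at the subject's individual alpha
  frequency (IAF) on posterior channels;
* multiplicative band-power modulation tied to a latent vigilance state
  v(t) in [0, 1]: for each configured (scalp area, band) the realised band
  power scales by ``effect_size ** (1 - v)``, so vigilance 1 -> 0 multiplies
  power by the configured effect size (parietal alpha and frontal beta/gamma
  rise as vigilance falls);
* stereotyped ~400 ms biphasic eye blinks on an ocular source mixed into
  anterior channels with distance-decaying coefficients;
* three classes of planted artifacts matching the rejection criteria
  (amplitude plateaus, slow ramps, step discontinuities);
* reaction-time series whose per-block medians drift upward as the latent
  vigilance declines (lognormal trial noise).

The modulated band components are synthesised with in-band variance well
above the background's in-band power (``oscillator_snr``), so the realised
high/low-vigilance band-power ratio converges to the configured effect size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
from scipy import signal

from .montage import POSTERIOR_AREAS, area_map, channel_area, channel_prefix
from .spectral import define_bands

#: Default multiplicative power change from vigilance 1 -> 0 per (area, band).
#: Directions follow the vigilance literature (alpha/beta/gamma power rise as
#: vigilance falls); magnitudes are moderate-to-large spectral effects.
DEFAULT_EFFECT_SIZES: dict[tuple[str, str], float] = {
    ("parietal", "alpha"): 2.0,
    ("frontal", "beta"): 1.5,
    ("frontal", "gamma"): 1.5,
}

#: Null world: the same oscillatory components, none modulated by vigilance.
NULL_EFFECT_SIZES: dict[tuple[str, str], float] = {
    key: 1.0 for key in DEFAULT_EFFECT_SIZES
}

#: Blink-source mixing coefficient by 10-20 site prefix (distance decay from
#: the eyes); unlisted prefixes get the far-field residual.
_BLINK_MIXING = {"Fp": 1.0, "AF": 0.55, "F": 0.30, "FC": 0.12, "C": 0.06}
_BLINK_FAR_FIELD = 0.02

ARTIFACT_CLASSES = ("amplitude", "trend", "step")


def constant_vigilance(u: np.ndarray) -> np.ndarray:
    return np.ones_like(np.asarray(u, dtype=float))


def linear_decline(u: np.ndarray) -> np.ndarray:
    return 1.0 - np.asarray(u, dtype=float)


@dataclass
class SimulationSpec:
    """Parameters of one simulated subject/session.

    ``vigilance_profile`` maps normalised session time u in [0, 1] to the
    latent vigilance v in [0, 1] (1 = fully vigilant).  ``effect_sizes`` maps
    (scalp area, band name) to the multiplicative power change realised
    between vigilance 1 and vigilance 0; values must be strictly positive
    (1.0 = no modulation).  ``artifact_plan`` lists (onset s, class,
    magnitude uV) triples; classes are ``amplitude``, ``trend``, ``step``.
    """

    channel_labels: Sequence[str]
    sampling_rate: float = 250.0
    duration: float = 600.0
    iaf: float = 10.0
    background_exponent: float = 1.0
    vigilance_profile: Callable[[np.ndarray], np.ndarray] = constant_vigilance
    effect_sizes: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_SIZES)
    )
    blink_rate: float = 15.0  # events / minute
    artifact_plan: list[tuple[float, str, float]] = field(default_factory=list)
    rng_seed: int = 0
    background_rms: float = 4.0  # uV over the synthesised band
    oscillator_snr: float = 9.0  # modulated in-band variance / background's
    artifact_length: float = 2.0  # s, for amplitude and trend classes

    def validate(self) -> None:
        labels = list(self.channel_labels)
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        for lab in labels:
            channel_area(lab)  # raises on unknown labels
        if not (7.0 <= self.iaf <= 13.0):
            raise ValueError("iaf must lie within [7, 13] Hz")
        highest = self.iaf + 30.0  # gamma high edge
        if self.sampling_rate <= 2.0 * highest:
            raise ValueError("sampling_rate must exceed twice the highest "
                             f"synthesised frequency ({highest} Hz)")
        if self.duration < 2.0:
            raise ValueError("duration too short for a single 2-s epoch")
        for key, val in self.effect_sizes.items():
            if val <= 0:
                raise ValueError(f"effect size for {key} must be positive")
        probe = np.asarray(self.vigilance_profile(np.linspace(0, 1, 64)), float)
        if probe.min() < -1e-9 or probe.max() > 1 + 1e-9:
            raise ValueError("vigilance_profile must map into [0, 1]")
        for t0, kind, _mag in self.artifact_plan:
            if kind not in ARTIFACT_CLASSES:
                raise ValueError(f"unknown artifact class {kind!r}")
            if not (0 <= t0 < self.duration):
                raise ValueError("artifact onset outside recording duration")


@dataclass
class Recording:
    """Continuous multi-channel EEG in uV with condition markers.

    ``markers`` is a time-sorted list of (time s, label) annotations; each
    marker opens the segment that runs until the next marker (or the end of
    the recording).
    """

    samples: np.ndarray  # (channels, time)
    sampling_rate: float
    channel_labels: list[str]
    markers: list[tuple[float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if any(t1 > t2 for (t1, _), (t2, _) in zip(self.markers, self.markers[1:])):
            raise ValueError("markers must be sorted by time")

    @property
    def duration(self) -> float:
        return self.samples.shape[1] / self.sampling_rate

    def segment_bounds(self) -> list[tuple[float, float, str]]:
        """(start, end, label) for every marked segment."""
        out = []
        for i, (t0, lab) in enumerate(self.markers):
            t1 = self.markers[i + 1][0] if i + 1 < len(self.markers) else self.duration
            out.append((t0, t1, lab))
        return out

    def crop(self, t0: float, t1: float) -> "Recording":
        i0 = int(round(t0 * self.sampling_rate))
        i1 = int(round(t1 * self.sampling_rate))
        return Recording(self.samples[:, i0:i1].copy(), self.sampling_rate,
                         list(self.channel_labels), [])


@dataclass
class GroundTruth:
    """Planted structure of a simulated session (test oracle).

    ``artifact_windows`` holds (start s, end s, class) of every planted
    artifact; ``latent_vigilance`` is the realised v(t) sampled at the
    recording rate; ``ocular_mixing`` gives the blink-source coefficient per
    channel.
    """

    artifact_windows: list[tuple[float, float, str]]
    latent_vigilance: np.ndarray
    ocular_mixing: dict[str, float]
    sampling_rate: float = 250.0
    blink_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    blink_source: np.ndarray | None = None

    @property
    def duration(self) -> float:
        return len(self.latent_vigilance) / self.sampling_rate

    def overlaps(self, start_times: np.ndarray, epoch_length: float,
                 pad: float = 0.0) -> np.ndarray:
        """Boolean mask: which epochs overlap a planted-artifact window.

        ``pad`` widens each window symmetrically, e.g. to account for the
        edge support of a zero-phase filter applied before rejection.
        """
        starts = np.asarray(start_times, float)
        mask = np.zeros(len(starts), dtype=bool)
        for a0, a1, _kind in self.artifact_windows:
            mask |= (starts < a1 + pad) & (starts + epoch_length > a0 - pad)
        return mask

    @property
    def artifact_epochs(self) -> set[float]:
        """Start times of default-grid (2 s / 0.125 s, sample-quantised)
        epochs overlapping a planted artifact window."""
        hop = round(0.125 * self.sampling_rate) / self.sampling_rate
        n_ep = int(math.floor((self.duration - 2.0) / hop + 1e-9)) + 1
        grid = np.arange(max(n_ep, 0)) * hop
        return set(grid[self.overlaps(grid, 2.0)])


@dataclass
class RTSeries:
    """Per-block reaction times (ms); lapses are RTs above the threshold."""

    reaction_times: list[np.ndarray]
    lapse_threshold: float = 500.0

    def __post_init__(self) -> None:
        for block in self.reaction_times:
            if np.any(np.asarray(block) <= 0):
                raise ValueError("reaction times must be positive")

    @property
    def n_blocks(self) -> int:
        return len(self.reaction_times)

    @property
    def block_means(self) -> np.ndarray:
        return np.array([np.mean(b) for b in self.reaction_times])

    @property
    def lapse_fractions(self) -> np.ndarray:
        return np.array([np.mean(np.asarray(b) > self.lapse_threshold)
                         for b in self.reaction_times])


# ---------------------------------------------------------------------------
# signal components
# ---------------------------------------------------------------------------

def _powerlaw_noise(rng: np.random.Generator, n: int, fs: float,
                    exponent: float) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(len(freqs))
                  + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _background_band_fraction(n: int, fs: float, exponent: float,
                              lo: float, hi: float) -> float:
    """Fraction of the shaped-noise variance lying in [lo, hi)."""
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)[1:]
    dens = freqs ** (-exponent)
    total = dens.sum()
    band = dens[(freqs >= lo) & (freqs < hi)].sum()
    return float(band / total)


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       lo: float, hi: float, order: int = 4) -> np.ndarray:
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = signal.sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def _blink_waveform(fs: float) -> np.ndarray:
    """Biphasic ~400 ms blink transient, unit positive peak."""
    n_pos = int(round(0.25 * fs))
    n_neg = int(round(0.15 * fs))
    pos = np.hanning(n_pos)
    neg = -0.35 * np.hanning(n_neg)
    return np.concatenate([pos, neg])


def _blink_source(rng: np.random.Generator, n: int, fs: float,
                  rate_per_min: float, amplitude: float = 80.0):
    """Poisson train of blink transients; returns (signal, onset times)."""
    source = np.zeros(n)
    wave = _blink_waveform(fs) * amplitude
    times = []
    t = rng.exponential(60.0 / rate_per_min) if rate_per_min > 0 else np.inf
    while t * fs + len(wave) < n:
        i0 = int(round(t * fs))
        source[i0:i0 + len(wave)] += wave * rng.uniform(0.8, 1.2)
        times.append(t)
        t += rng.exponential(60.0 / rate_per_min)
    return source, np.asarray(times)


def _insert_artifact(samples: np.ndarray, fs: float, ch: int,
                     t0: float, kind: str, magnitude: float,
                     length: float) -> tuple[float, float]:
    """Plant one artifact on channel ``ch``; returns its (start, end) window."""
    n = samples.shape[1]
    i0 = int(round(t0 * fs))
    if kind == "step":
        # instantaneous DC level shift persisting to the end of the recording;
        # only the jump sample violates the sample-to-sample criterion
        samples[ch, i0:] += magnitude
        return (t0, t0 + 1.0 / fs)
    i1 = min(n, i0 + int(round(length * fs)))
    m = i1 - i0
    if kind == "amplitude":
        # saturation-like plateau with 100 ms raised-cosine edges
        win = signal.windows.tukey(m, alpha=min(1.0, 2 * 0.1 * fs / m))
        samples[ch, i0:i1] += magnitude * win
    elif kind == "trend":
        # monotone slow ramp; slope = magnitude / length uV/s
        samples[ch, i0:i1] += np.linspace(0.0, magnitude, m)
    else:  # pragma: no cover - validated upstream
        raise ValueError(kind)
    return (t0, i1 / fs)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_recording(spec: SimulationSpec) -> tuple[Recording, GroundTruth]:
    """Synthesise one continuous EEG recording plus its ground truth.

    Deterministic given ``spec.rng_seed``; see the module docstring for the
    generative model.
    """
    spec.validate()
    rng = np.random.default_rng(spec.rng_seed)
    fs = spec.sampling_rate
    n = int(round(spec.duration * fs))
    labels = list(spec.channel_labels)
    areas = area_map(labels)
    t = np.arange(n) / fs
    v = np.clip(np.asarray(spec.vigilance_profile(t / spec.duration), float), 0, 1)

    scheme = define_bands(spec.iaf)
    bg_var = spec.background_rms ** 2

    samples = np.empty((len(labels), n))
    for i in range(len(labels)):
        samples[i] = spec.background_rms * _powerlaw_noise(
            rng, n, fs, spec.background_exponent)

    # modulated band components; posterior alpha is always present so the
    # IAF peak exists even in a null (all effects = 1) world
    components: dict[tuple[str, str], float] = dict(spec.effect_sizes)
    for area in POSTERIOR_AREAS:
        components.setdefault((area, "alpha"), 1.0)

    for (area, band), effect in components.items():
        lo, hi = scheme[band]
        if band == "alpha":
            # narrowband around the IAF so the spectral peak sits at spec.iaf
            comp_lo, comp_hi = spec.iaf - 0.6, spec.iaf + 0.6
            order = 2
        else:
            comp_lo, comp_hi = lo, hi
            order = 4
        frac = _background_band_fraction(n, fs, spec.background_exponent, lo, hi)
        target_sd = math.sqrt(spec.oscillator_snr * bg_var * frac)
        gain = np.power(effect, (1.0 - v) / 2.0)
        for i, lab in enumerate(labels):
            if areas[lab] != area:
                continue
            comp = _bandlimited_noise(rng, n, fs, comp_lo, comp_hi, order)
            samples[i] += target_sd * gain * comp

    # ocular contamination
    blink_src, blink_times = _blink_source(rng, n, fs, spec.blink_rate)
    mixing = {
        lab: _BLINK_MIXING.get(channel_prefix(lab), _BLINK_FAR_FIELD)
        for lab in labels
    }
    for i, lab in enumerate(labels):
        samples[i] += mixing[lab] * blink_src

    # planted artifacts on a deterministic (seeded) channel per event
    windows: list[tuple[float, float, str]] = []
    for t0, kind, magnitude in spec.artifact_plan:
        ch = int(rng.integers(len(labels)))
        a0, a1 = _insert_artifact(samples, fs, ch, t0, kind, magnitude,
                                  spec.artifact_length)
        windows.append((a0, a1, kind))

    rec = Recording(samples=samples, sampling_rate=fs, channel_labels=labels)
    gt = GroundTruth(
        artifact_windows=windows,
        latent_vigilance=v,
        ocular_mixing=mixing,
        sampling_rate=fs,
        blink_times=blink_times,
        blink_source=blink_src,
    )
    return rec, gt


def _session_profile(rest_length: float, task_duration: float,
                     base_profile: Callable[[np.ndarray], np.ndarray],
                     total: float) -> Callable[[np.ndarray], np.ndarray]:
    """Vigilance stays at 1 through the rest segments, then follows the task
    profile over the task portion."""
    def profile(u: np.ndarray) -> np.ndarray:
        tt = np.asarray(u, float) * total
        task_u = np.clip((tt - 2 * rest_length) / task_duration, 0.0, 1.0)
        out = np.asarray(base_profile(task_u), float)
        return np.where(tt < 2 * rest_length, 1.0, out)
    return profile


def _block_markers(rest_labels: tuple[str, str], rest_length: float,
                   n_blocks: int, block_length: float) -> list[tuple[float, str]]:
    markers = [(0.0, rest_labels[0]), (rest_length, rest_labels[1])]
    for b in range(n_blocks):
        markers.append((2 * rest_length + b * block_length, f"B{b + 1}"))
    return markers


def _generate_session(
    spec: SimulationSpec, n_blocks: int, block_length: float,
    rest_length: float, rest_labels: tuple[str, str],
) -> tuple[Recording, GroundTruth]:
    if n_blocks < 2:
        raise ValueError("a session needs at least 2 task blocks")
    task_duration = n_blocks * block_length
    if task_duration > spec.duration + 1e-9:
        raise ValueError("n_blocks x block_length exceeds spec.duration")
    total = 2 * rest_length + task_duration
    profile = _session_profile(rest_length, task_duration,
                               spec.vigilance_profile, total)
    sess_spec = replace(spec, duration=total, vigilance_profile=profile)
    rec, gt = generate_recording(sess_spec)
    rec.markers = _block_markers(rest_labels, rest_length, n_blocks, block_length)
    return rec, gt


def generate_pvt_session(
    spec: SimulationSpec,
    n_blocks: int = 10,
    block_length: float = 60.0,
    rest_length: float = 60.0,
    rt_base: float = 250.0,
    rt_drift: float = 150.0,
    rt_sigma: float = 0.2,
    trials_per_minute: float = 12.0,
) -> tuple[Recording, GroundTruth, RTSeries]:
    """One psychomotor-vigilance-task session.

    Layout: eyes-open rest (OA), eyes-closed rest (OC), then ``n_blocks``
    task blocks over which the latent vigilance declines per
    ``spec.vigilance_profile`` (linear decline by default).  Per-block median
    reaction times drift from ``rt_base`` upward by ``rt_drift`` ms as the
    latent vigilance reaches 0, with lognormal trial-to-trial noise
    ``rt_sigma``; RTs therefore correlate negatively with the latent state.
    ``spec.duration`` is interpreted as the available task duration.
    """
    task_spec = spec if spec.vigilance_profile is not constant_vigilance \
        else replace(spec, vigilance_profile=linear_decline)
    rec, gt = _generate_session(task_spec, n_blocks, block_length,
                                rest_length, ("OA", "OC"))

    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed, 911]))
    fs = spec.sampling_rate
    n_trials = max(3, int(round(trials_per_minute * block_length / 60.0)))
    blocks = []
    for b in range(n_blocks):
        t0 = 2 * rest_length + b * block_length
        i0, i1 = int(t0 * fs), int((t0 + block_length) * fs)
        vbar = float(gt.latent_vigilance[i0:i1].mean())
        median = rt_base + rt_drift * (1.0 - vbar)
        rts = median * np.exp(rt_sigma * rng.standard_normal(n_trials))
        blocks.append(rts)
    return rec, gt, RTSeries(reaction_times=blocks)


def generate_atm_session(
    spec: SimulationSpec,
    n_blocks: int = 3,
    block_length: float = 300.0,
    rest_length: float = 60.0,
) -> tuple[Recording, GroundTruth]:
    """One air-traffic-management supervision scenario.

    Same contract as :func:`generate_pvt_session` without reaction times;
    the default 3 x 5-minute layout reproduces a 15-minute calibration
    scenario whose first block is high vigilance and last block low
    vigilance.  Rest segments are labelled REF (eyes open) and OC.
    """
    task_spec = spec if spec.vigilance_profile is not constant_vigilance \
        else replace(spec, vigilance_profile=linear_decline)
    return _generate_session(task_spec, n_blocks, block_length,
                             rest_length, ("REF", "OC"))
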