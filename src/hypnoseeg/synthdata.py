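"""Labeled synthetic EEG with the statistical structure the pipeline assumes.

The generator emulates a frontal 8-channel driving-EEG recording (plus two
mastoid reference channels) at 500 Hz as a linear mixture X = A.S of eight
latent sources:

* five narrowband oscillatory sources, one per canonical band (delta,
  theta, alpha, beta, gamma). Each is a frequency-wandering sinusoidal
  carrier (sub-Gaussian, the standard model of a sustained EEG rhythm)
  plus band-filtered noise, with slow waxing-and-waning amplitude
  modulation. The sub-Gaussian carrier keeps the sources identifiable by
  FastICA, which cannot separate Gaussian sources.
* a blink artifact source: stereotyped biphasic ~300 ms pulses at Poisson
  times, projected mainly onto the frontal-pole (Fp) electrodes.
* a cardiac artifact source: a ~1.2 Hz train of sharp QRS-like wavelets
  with a diffuse scalp projection and strong mastoid pickup.
* a broadband heavy-tailed noise source with a diffuse projection.

Two latent driving states (RH = road hypnosis, ND = normal driving) differ
only through per-band amplitude multipliers applied to the oscillatory
sources; by default the RH state raises theta and alpha amplitude by 1.5x
(2.25x in power), echoing the reported frontal slow-rhythm increase in
hypofatigue/monotony states. Event annotations are emitted on a regular
grid and labeled with the active state; events too close to a state switch
are skipped so every downstream epoch is label-pure.

Everything is driven by one integer seed through a single
``numpy.random.Generator``; identical config + seed gives bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import fftconvolve, lfilter

from .bands import BAND_NAMES, band_edges
from .errors import ConfigError, ValidationError
from .preprocess import _windowed_sinc_lowpass
from .recording import (
    DEFAULT_EEG_CHANNELS,
    DEFAULT_MASTOIDS,
    EventList,
    RawRecording,
    StateTimeline,
)
from . import io as _io

SOURCE_ORDER = BAND_NAMES + ("blink", "cardiac", "noise")


def _default_class_band_power() -> dict:
    return {
        "RH": {"theta": 1.5, "alpha": 1.5},
        "ND": {},
    }


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic recording.

    ``class_band_power`` maps state -> band -> amplitude multiplier
    (unlisted bands default to 1.0). ``artifact_rate`` is blink events per
    minute; ``noise_sd`` the sensor-noise amplitude in microvolts.
    """

    channel_names: tuple[str, ...] = DEFAULT_EEG_CHANNELS + DEFAULT_MASTOIDS
    fs: float = 500.0
    duration: float = 60.0
    class_band_power: dict = field(default_factory=_default_class_band_power)
    artifact_rate: float = 12.0  # blinks / minute
    cardiac_rate_hz: float = 1.2
    noise_sd: float = 2.0  # microvolts, per-channel sensor noise
    seed: int = 0
    event_spacing: float = 2.0  # seconds between annotations
    state_block_s: float = 20.0  # alternating-state block length
    carrier_fraction: float = 0.92  # power fraction of the sinusoidal carrier
    am_depth: float = 0.10  # slow amplitude-modulation depth

    def __post_init__(self) -> None:
        if not self.fs > 0:
            raise ConfigError(f"fs must be positive, got {self.fs}")
        if not self.duration > 0:
            raise ConfigError(f"duration must be positive, got {self.duration}")
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ConfigError("channel names must be unique")
        if not 0 <= self.carrier_fraction <= 1:
            raise ConfigError("carrier_fraction must lie in [0, 1]")
        for state, bands in self.class_band_power.items():
            if state not in ("RH", "ND"):
                raise ConfigError(f"unknown state {state!r} in class_band_power")
            for band, mult in bands.items():
                band_edges(band)  # raises ConfigError on unknown band
                if not mult > 0:
                    raise ConfigError(
                        f"band multiplier must be positive, got {band}={mult}"
                    )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))

    def multiplier(self, state: str, band: str) -> float:
        return float(self.class_band_power.get(state, {}).get(band, 1.0))


@dataclass
class SourceSet:
    """Latent sources (n_sources x samples) with per-source kind tags."""

    sources: np.ndarray
    source_kinds: tuple[str, ...]  # band-oscillation | blink-artifact | ...
    bands: tuple[str | None, ...]  # band name for oscillatory sources
    fs: float

    @property
    def n_sources(self) -> int:
        return self.sources.shape[0]


@dataclass
class MixingSpec:
    """Forward model: channels x sources mixing matrix in microvolts."""

    A: np.ndarray
    channel_names: tuple[str, ...]
    source_kinds: tuple[str, ...]

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.shape != (len(self.channel_names), len(self.source_kinds)):
            raise ValidationError(
                f"mixing matrix shape {self.A.shape} does not match "
                f"{len(self.channel_names)} channels x "
                f"{len(self.source_kinds)} sources"
            )
        if np.linalg.matrix_rank(self.A) < self.A.shape[1]:
            raise ValidationError("mixing matrix must have full column rank")


# ---------------------------------------------------------------------------
# source synthesis helpers


def _ar1_smooth(white: np.ndarray, rho: float) -> np.ndarray:
    """AR(1) smoothing, x[t] = rho x[t-1] + white[t], unit-variance output."""
    out = lfilter([1.0], [1.0, -rho], white)
    sd = out.std()
    return out / sd if sd > 0 else out


def _slow_process(rng, n: int, fs: float, bandwidth_hz: float) -> np.ndarray:
    """Unit-variance slowly varying Gaussian process via coarse AR(1) + interp."""
    ctrl_fs = max(4.0 * bandwidth_hz, 1.0)
    n_ctrl = max(int(np.ceil(n / fs * ctrl_fs)) + 2, 4)
    rho = float(np.exp(-2.0 * np.pi * bandwidth_hz / ctrl_fs))
    coarse = _ar1_smooth(rng.standard_normal(n_ctrl), rho)
    t_ctrl = np.arange(n_ctrl) / ctrl_fs
    t = np.arange(n) / fs
    out = np.interp(t, t_ctrl, coarse)
    sd = out.std()
    return out / sd if sd > 0 else out


def _oscillatory_source(
    rng, band: str, n: int, fs: float, carrier_fraction: float, am_depth: float
) -> np.ndarray:
    """Unit-variance narrowband stochastic oscillation for one band."""
    lo, hi = band_edges(band)
    bw = hi - lo
    center = 0.5 * (lo + hi)
    # carrier frequency wanders inside the band interior (keeps >=80% of
    # power in-band while decorrelating the phase over ~0.5 s)
    wander = _slow_process(rng, n, fs, bandwidth_hz=0.8)
    freq = np.clip(center + 0.28 * bw * wander, lo + 0.08 * bw, hi - 0.08 * bw)
    phase = 2.0 * np.pi * np.cumsum(freq) / fs + rng.uniform(0, 2 * np.pi)
    carrier = np.sqrt(2.0) * np.sin(phase)

    order = 3300 if lo < 2.0 else 1500
    if n < 3 * (order + 1):  # short fixtures: cheaper kernel
        order = min(order, 2 * (n // 6))
        order += order % 2
    bp = _windowed_sinc_lowpass(hi, order, fs) - _windowed_sinc_lowpass(lo, order, fs)
    raw = rng.standard_normal(n + order)
    noise = fftconvolve(raw, bp, mode="same")[order // 2 : order // 2 + n]
    sd = noise.std()
    if sd > 0:
        noise = noise / sd

    envelope = 1.0 + am_depth * _slow_process(rng, n, fs, bandwidth_hz=0.2)
    envelope = np.clip(envelope, 0.2, None)
    s = (
        np.sqrt(carrier_fraction) * carrier
        + np.sqrt(1.0 - carrier_fraction) * noise
    ) * envelope
    return s / s.std()


def _blink_kernel(fs: float) -> np.ndarray:
    """Biphasic ~300 ms pulse (derivative-of-Gaussian), unit peak."""
    sigma = 0.06
    t = np.arange(int(round(0.3 * fs))) / fs - 0.15
    k = -t / sigma**2 * np.exp(-(t**2) / (2 * sigma**2))
    return k / np.abs(k).max()


def _blink_source(rng, n: int, fs: float, rate_per_min: float) -> np.ndarray:
    s = np.zeros(n)
    if rate_per_min <= 0:
        return s
    kernel = _blink_kernel(fs)
    t = 0.0
    duration = n / fs
    while True:
        t += rng.exponential(60.0 / rate_per_min) + 0.5  # 0.5 s refractory
        if t >= duration:
            break
        start = int(round(t * fs))
        stop = min(start + kernel.size, n)
        s[start:stop] += rng.uniform(0.8, 1.2) * kernel[: stop - start]
    sd = s.std()
    return s / sd if sd > 0 else s


def _cardiac_source(rng, n: int, fs: float, rate_hz: float) -> np.ndarray:
    """QRS-like Ricker wavelet train with slight beat-interval jitter."""
    width = int(round(0.04 * fs))
    t = np.arange(-3 * width, 3 * width + 1) / width
    ricker = (1 - t**2) * np.exp(-(t**2) / 2)
    s = np.zeros(n)
    if rate_hz <= 0:
        return s
    beat = 0.0
    duration = n / fs
    while True:
        beat += (1.0 / rate_hz) * rng.uniform(0.98, 1.02)
        if beat >= duration:
            break
        center = int(round(beat * fs))
        lo = max(center - 3 * width, 0)
        hi = min(center + 3 * width + 1, n)
        s[lo:hi] += ricker[lo - (center - 3 * width) : hi - (center - 3 * width)]
    sd = s.std()
    return s / sd if sd > 0 else s


def _broadband_noise_source(rng, n: int, fs: float) -> np.ndarray:
    """Heavy-tailed (Laplace) broadband source, lightly low-passed."""
    white = rng.laplace(size=n)
    order = min(100, 2 * (n // 6))
    order += order % 2
    if order >= 2:
        lp = _windowed_sinc_lowpass(min(100.0, 0.4 * fs), order, fs)
        white = fftconvolve(white, lp, mode="same")
    return white / white.std()


# ---------------------------------------------------------------------------
# public operations


def generate_sources(
    config: SyntheticConfig, timeline: StateTimeline
) -> SourceSet:
    """Synthesize the eight latent sources under a driving-state timeline.

    Oscillatory sources are scaled sample-by-sample by the active state's
    band multiplier; artifact and broadband sources are state-independent.
    """
    if timeline.duration < config.duration:
        raise ValidationError(
            f"timeline covers [0, {timeline.duration}] s but the recording "
            f"lasts {config.duration} s"
        )
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    t = np.arange(n) / config.fs
    states = timeline.state_at(t)
    is_rh = states == "RH"

    rows, kinds, bands = [], [], []
    for band in BAND_NAMES:
        s = _oscillatory_source(
            rng, band, n, config.fs, config.carrier_fraction, config.am_depth
        )
        amp = np.where(
            is_rh, config.multiplier("RH", band), config.multiplier("ND", band)
        )
        rows.append(s * amp)
        kinds.append("band-oscillation")
        bands.append(band)
    rows.append(_blink_source(rng, n, config.fs, config.artifact_rate))
    kinds.append("blink-artifact")
    bands.append(None)
    rows.append(_cardiac_source(rng, n, config.fs, config.cardiac_rate_hz))
    kinds.append("cardiac-artifact")
    bands.append(None)
    rows.append(_broadband_noise_source(rng, n, config.fs))
    kinds.append("noise")
    bands.append(None)

    return SourceSet(
        sources=np.vstack(rows),
        source_kinds=tuple(kinds),
        bands=tuple(bands),
        fs=config.fs,
    )


#: Base scalp projections (EEG channel order Fp2, Fpz, Fp1, F4, Fz, F3,
#: FC2, FC1) and microvolt scales for the default forward model.
_TOPOGRAPHIES = {
    # frontal-central delta, polarity flip toward FC (distinct from the
    # steeper frontal-pole blink gradient)
    "delta": ([0.55, 0.75, 0.65, 1.00, 0.90, 1.00, -0.45, -0.55], 6.0),
    # frontal-midline theta: midline positive, lateral sites weakly negative
    "theta": ([-0.35, 0.95, -0.35, 0.30, 1.00, 0.30, 0.65, 0.65], 7.0),
    # tangential (left-right) alpha dipole
    "alpha": ([0.85, 0.10, -0.85, 0.95, 0.05, -0.95, 0.75, -0.75], 8.0),
    # anterior-posterior beta gradient with a polarity flip at FC
    "beta": ([0.70, 0.80, 0.70, -0.25, -0.20, -0.25, -0.95, -0.95], 4.0),
    # focal left-frontal gamma patch
    "gamma": ([0.90, -0.50, 0.30, -0.80, 0.45, 0.90, -0.60, 0.40], 3.0),
    # blink (EOG): frontal-pole positive gradient
    "blink": ([1.00, 1.05, 0.95, 0.45, 0.50, 0.45, 0.25, 0.20], 30.0),
    # cardiac: near common-mode on the scalp, strong at the mastoids
    "cardiac": ([0.90, 1.00, 0.95, 1.00, 0.90, 0.95, 1.00, 0.90], 8.0),
    # broadband noise: diffuse with mixed polarity
    "noise": ([0.80, -0.90, 0.85, 0.95, -0.80, 0.90, -0.85, 0.95], 3.0),
}
#: Mastoid pickup relative to the column's microvolt scale.
_MASTOID_GAIN = {
    "delta": 0.12,
    "theta": 0.12,
    "alpha": 0.12,
    "beta": 0.12,
    "gamma": 0.12,
    "blink": 0.05,
    "cardiac": 1.30,
    "noise": 0.80,
}


def default_mixing(config: SyntheticConfig) -> MixingSpec:
    """Default 10-channel x 8-source forward model with seeded jitter.

    The blink column is frontal-pole weighted; cardiac and broadband noise
    project diffusely and dominate the mastoid rows (which is what makes
    mastoid re-referencing useful).
    """
    rng = np.random.default_rng(config.seed + 104729)
    n_eeg = len(DEFAULT_EEG_CHANNELS)
    cols = []
    for name in SOURCE_ORDER:
        topo, scale = _TOPOGRAPHIES[name]
        eeg = np.asarray(topo) * (1.0 + 0.08 * rng.standard_normal(n_eeg))
        mastoid_gain = _MASTOID_GAIN[name] * (
            1.0 + 0.05 * rng.standard_normal(2)
        )
        cols.append(np.concatenate([eeg, mastoid_gain]) * scale)
    A = np.column_stack(cols)
    kinds = tuple(
        "band-oscillation"
        if name in BAND_NAMES
        else f"{name}-artifact" if name in ("blink", "cardiac") else "noise"
        for name in SOURCE_ORDER
    )
    return MixingSpec(
        A=A,
        channel_names=DEFAULT_EEG_CHANNELS + DEFAULT_MASTOIDS,
        source_kinds=kinds,
    )


def mix_and_annotate(
    sources: SourceSet,
    mixing: MixingSpec,
    config: SyntheticConfig,
    timeline: StateTimeline,
) -> tuple[RawRecording, EventList]:
    """Project sources to the scalp, add sensor noise, and emit annotations.

    Annotations lie on a regular ``event_spacing`` grid; events within
    1.0 s of a state-block boundary are skipped so the 0.2-1.0 s epoch that
    follows each onset never straddles two states.
    """
    if mixing.A.shape[1] != sources.n_sources:
        raise ValidationError(
            f"mixing matrix {mixing.A.shape} incompatible with "
            f"{sources.n_sources} x {sources.sources.shape[1]} sources"
        )
    rng = np.random.default_rng(config.seed + 7919)
    data = mixing.A @ sources.sources
    if config.noise_sd > 0:
        data = data + config.noise_sd * rng.standard_normal(data.shape)
    rec = RawRecording(
        data=data,
        fs=config.fs,
        channel_names=mixing.channel_names,
        history=("simulate",),
    )

    onsets = np.arange(
        config.event_spacing / 2.0, config.duration, config.event_spacing
    )
    # keep only events whose 1 s post-onset window stays within one state
    interior = np.searchsorted(timeline.edges, onsets, side="right")
    same_state = np.searchsorted(timeline.edges, onsets + 1.0, side="right")
    keep = (interior == same_state) & (onsets + 1.0 <= timeline.duration)
    onsets = onsets[keep]
    labels = timeline.state_at(onsets)
    return rec, EventList(onsets=onsets, labels=labels)


def simulate(
    config: SyntheticConfig, timeline: StateTimeline | None = None
) -> tuple[RawRecording, EventList, SourceSet, MixingSpec]:
    """Full generation: timeline -> sources -> mixed recording + events."""
    if timeline is None:
        timeline = StateTimeline.alternating(
            config.duration, config.state_block_s
        )
    sources = generate_sources(config, timeline)
    mixing = default_mixing(config)
    rec, events = mix_and_annotate(sources, mixing, config, timeline)
    return rec, events, sources, mixing


def write_fixture(
    recording: RawRecording, events: EventList, out_dir: str | Path
) -> tuple[Path, Path]:
    """Write the recording (HDF5 container) and events (TSV) to *out_dir*."""
    out_dir = Path(out_dir)
    rec_path = _io.save_recording(recording, out_dir / "recording.h5")
    ev_path = _io.save_events(events, out_dir / "events.tsv")
    return rec_path, ev_path
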