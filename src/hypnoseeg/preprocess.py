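"""Montage re-referencing and linear-phase FIR filtering.

The preprocessing chain mirrors standard ERP practice: each EEG channel is
re-expressed against the bilateral mastoid average, then filtered with
linear-phase windowed-sinc FIR filters (30 Hz low-pass, 0.1 Hz high-pass and
a narrow 40 Hz notch by default). Filters are applied zero-phase: the
symmetric taps are convolved in 'same' alignment after reflect-padding, which
centres the group delay exactly and leaves the magnitude response equal to
the designed |H(f)| (not its square).

FIR design uses the classic windowed-sinc construction with a Hamming
window. High-pass and notch kernels are built by spectral inversion
(delta minus low-pass / band-pass), which makes the DC contracts exact:
low-pass taps sum to 1, high-pass and notch taps sum to 0 to machine
precision. Gain at the cutoff itself is 0.5 (half amplitude), the windowed-
sinc convention.

A continuous wavelet transform is exposed as an alternative time-frequency
comparison path; it is not part of the main pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.signal import fftconvolve

from .errors import ConfigError, StateError, ValidationError
from .recording import RawRecording, REF_AS_RECORDED, REF_MASTOID

LOW_PASS = "low-pass"
HIGH_PASS = "high-pass"
NOTCH = "notch"

#: Default filter order (taps - 1) at fs = 500 Hz: one-second kernels for the
#: low-pass/notch; the high-pass needs a wider kernel because its transition
#: band (~0.5 Hz) is narrow relative to the sampling rate.
DEFAULT_ORDER = {LOW_PASS: 500, NOTCH: 500, HIGH_PASS: 3300}


@dataclass(frozen=True)
class FilterSpec:
    """Parameters of one FIR filter.

    ``fc`` is the cutoff in Hz; for a notch it is the centre frequency and
    ``half_width`` the half-width of the stop band. ``order`` is the number
    of taps minus one and must be even (linear-phase type I).
    """

    kind: str
    fc: float
    order: int | None = None
    half_width: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in (LOW_PASS, HIGH_PASS, NOTCH):
            raise ConfigError(f"unknown filter kind {self.kind!r}")
        if self.order is not None and self.order % 2 != 0:
            raise ConfigError(f"filter order must be even, got {self.order}")
        if self.kind == NOTCH and not self.half_width > 0:
            raise ConfigError("notch half-width must be positive")

    def resolved_order(self) -> int:
        return DEFAULT_ORDER[self.kind] if self.order is None else self.order

    def validate_against(self, fs: float) -> None:
        nyq = fs / 2.0
        hi = self.fc + (self.half_width if self.kind == NOTCH else 0.0)
        if hi >= nyq or self.fc <= 0:
            raise ConfigError(
                f"{self.kind} cutoff {self.fc} Hz violates 0 < fc < "
                f"Nyquist ({nyq} Hz) at fs={fs} Hz"
            )


@dataclass(frozen=True)
class FIRCoefficients:
    """Designed taps plus the spec they came from."""

    b: np.ndarray
    spec: FilterSpec
    fs: float

    @property
    def n_taps(self) -> int:
        return self.b.size


def _windowed_sinc_lowpass(fc: float, order: int, fs: float) -> np.ndarray:
    """Hamming-windowed sinc low-pass, taps normalized to unit DC gain."""
    m = order
    n = np.arange(m + 1) - m / 2.0
    h = np.sinc(2.0 * fc / fs * n) * np.hamming(m + 1)
    return h / h.sum()


def design_fir(spec: FilterSpec, fs: float) -> FIRCoefficients:
    """Design linear-phase FIR taps for *spec* at sampling rate *fs*.

    Raises :class:`ConfigError` when the cutoff is at or above the Nyquist
    frequency fs/2.
    """
    if not fs > 0:
        raise ConfigError(f"sampling rate must be positive, got {fs}")
    spec.validate_against(fs)
    order = spec.resolved_order()
    if spec.kind == LOW_PASS:
        b = _windowed_sinc_lowpass(spec.fc, order, fs)
    elif spec.kind == HIGH_PASS:
        b = -_windowed_sinc_lowpass(spec.fc, order, fs)
        b[order // 2] += 1.0  # spectral inversion: delta - lowpass
    else:  # notch: delta - (lowpass(hi) - lowpass(lo)) band-pass
        lo = spec.fc - spec.half_width
        hi = spec.fc + spec.half_width
        bp = _windowed_sinc_lowpass(hi, order, fs) - _windowed_sinc_lowpass(
            lo, order, fs
        )
        b = -bp
        b[order // 2] += 1.0
    return FIRCoefficients(b=b, spec=spec, fs=fs)


def frequency_response(
    coef: FIRCoefficients, freqs, fs: float | None = None
) -> np.ndarray:
    """|H(f)| = |sum_r b_r exp(-i 2 pi f r / fs)| at each frequency in Hz."""
    fs = coef.fs if fs is None else fs
    freqs = np.atleast_1d(np.asarray(freqs, dtype=float))
    if np.any(freqs < 0) or np.any(freqs > fs / 2.0):
        raise ValidationError(
            f"frequencies must lie in [0, {fs / 2.0}] Hz (Nyquist)"
        )
    r = np.arange(coef.b.size)
    phases = np.exp(-2j * np.pi * np.outer(freqs, r) / fs)
    return np.abs(phases @ coef.b)


def apply_filter(raw: RawRecording, coef: FIRCoefficients) -> RawRecording:
    """Zero-phase application of symmetric FIR taps to every channel.

    The signal is reflect-padded by one kernel length on each side before
    convolution, suppressing onset/offset transients. Output length equals
    input length.
    """
    n_taps = coef.n_taps
    if raw.n_samples < 3 * n_taps and n_taps > 1:
        raise ValidationError(
            f"recording too short for filtering: {raw.n_samples} samples "
            f"< 3 x {n_taps} taps"
        )
    if n_taps == 1:
        out = raw.data * coef.b[0]
    else:
        pad = n_taps
        padded = np.pad(raw.data, ((0, 0), (pad, pad)), mode="reflect")
        out = fftconvolve(padded, coef.b[None, :], mode="same", axes=1)
        out = out[:, pad:-pad]
    step = f"filter:{coef.spec.kind}@{coef.spec.fc}Hz(order={coef.spec.resolved_order()})"
    return raw.with_data(out, step)


def rereference(
    raw: RawRecording, ref_names: tuple[str, str] = ("M1", "M2")
) -> RawRecording:
    """Bilateral mastoid average re-reference.

    Subtracts the mean of the two reference channels from every other
    channel and drops the reference channels from the output.
    """
    if raw.reference != REF_AS_RECORDED:
        raise StateError(
            f"recording already re-referenced (reference={raw.reference!r})"
        )
    idx = [raw.channel_index(name) for name in ref_names]
    ref = raw.data[idx].mean(axis=0)
    keep = [i for i in range(raw.n_channels) if i not in idx]
    out = raw.data[keep] - ref
    return raw.with_data(
        out,
        f"rereference:{'+'.join(ref_names)}",
        channel_names=tuple(raw.channel_names[i] for i in keep),
        reference=REF_MASTOID,
    )


@dataclass(frozen=True)
class WaveletSpec:
    """Mother wavelet plus CWT scales (samples) for the comparison path."""

    wavelet: str = "morl"
    scales: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if len(self.scales) == 0:
            raise ValidationError("scale list must be non-empty")
        s = np.asarray(self.scales, dtype=float)
        if np.any(s <= 0) or np.any(np.diff(s) <= 0):
            raise ValidationError("scales must be positive and increasing")


def wavelet_scale_frequencies(spec: WaveletSpec, fs: float) -> np.ndarray:
    """Pseudo-frequency in Hz of each scale for the chosen mother wavelet."""
    return np.array(
        [pywt.scale2frequency(spec.wavelet, s) * fs for s in spec.scales]
    )


def wavelet_transform(
    signal: np.ndarray, spec: WaveletSpec, fs: float
) -> np.ndarray:
    """Discretized CWT coefficients, shape (n_scales, n_samples)."""
    signal = np.asarray(signal, dtype=float)
    if signal.ndim != 1 or signal.size < 2:
        raise ValidationError("need a 1-D signal with at least 2 samples")
    coeffs, _ = pywt.cwt(
        signal, np.asarray(spec.scales), spec.wavelet, sampling_period=1.0 / fs
    )
    return coeffs
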