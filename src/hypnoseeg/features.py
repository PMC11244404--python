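"""Event-locked epoching and periodogram band-power features.

Epochs are extracted in the half-open window [onset + 0.2 s, onset + 1.0 s)
relative to each annotation: 400 samples at 500 Hz, starting 100 samples
after the onset. The power spectral density of an epoch is the raw
periodogram |DFT(x)|^2 / N on a one-sided frequency grid (non-DC, non-
Nyquist bins doubled), so that the one-sided PSD sums to the epoch's total
energy sum(x^2) — the Parseval identity tested in the suite. No detrending
or tapering is applied by default (boxcar); a Hann taper and Welch averaging
are available as options.

Band powers sum PSD bins with band_lo <= f < band_hi for the five canonical
bands (delta through gamma); because the bands are half-open and pairwise
disjoint, band powers plus out-of-band bins partition the total exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window, welch as _scipy_welch

from .bands import BAND_TABLE, band_edges
from .errors import ConfigError, ValidationError
from .recording import EventList, RawRecording


@dataclass
class EpochSet:
    """Epochs x channels x samples tensor with per-epoch RH/ND labels."""

    data: np.ndarray
    labels: np.ndarray
    window: tuple[float, float]
    fs: float
    channel_names: tuple[str, ...] = ()
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype="U2")
        if self.data.ndim != 3:
            raise ValidationError(f"epoch tensor must be 3-D, got {self.data.shape}")
        if self.labels.shape[0] != self.data.shape[0]:
            raise ValidationError("one label per epoch required")
        expected = int(round((self.window[1] - self.window[0]) * self.fs))
        if self.data.shape[2] != expected:
            raise ValidationError(
                f"epoch length {self.data.shape[2]} != round((t2-t1)*fs) = {expected}"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def epoch_len(self) -> int:
        return self.data.shape[2]


@dataclass
class PSDFeatures:
    """One-sided PSD per epoch/channel plus the five-band power summary."""

    values: np.ndarray  # epochs x channels x bins
    freqs: np.ndarray  # bin centres, Hz
    band_powers: np.ndarray  # epochs x channels x 5
    band_names: tuple[str, ...]
    labels: np.ndarray

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]


def extract_epochs(
    raw: RawRecording,
    events: EventList,
    window: tuple[float, float] = (0.2, 1.0),
) -> EpochSet:
    """Slice the recording into event-locked epochs.

    Events whose window would run past either end of the recording are
    dropped; the drop count is recorded on the returned :class:`EpochSet`.
    Raises :class:`ValidationError` when no event survives.
    """
    t1, t2 = window
    if not t2 > t1:
        raise ValidationError(f"window must satisfy t_end > t_start, got {window}")
    n_len = int(round((t2 - t1) * raw.fs))
    starts = np.round((events.onsets + t1) * raw.fs).astype(int)
    ok = (starts >= 0) & (starts + n_len <= raw.n_samples)
    n_dropped = int(np.sum(~ok))
    starts = starts[ok]
    if starts.size == 0:
        raise ValidationError(
            f"no events fit in the recording (all {n_dropped} dropped)"
        )
    idx = starts[:, None] + np.arange(n_len)[None, :]
    data = raw.data[:, idx].transpose(1, 0, 2)  # epochs x channels x samples
    return EpochSet(
        data=data,
        labels=events.labels[ok],
        window=(t1, t2),
        fs=raw.fs,
        channel_names=raw.channel_names,
        n_dropped=n_dropped,
    )


def periodogram_psd(x: np.ndarray, fs: float, window: str = "boxcar"):
    """One-sided periodogram PSD = |DFT|^2 / N along the last axis.

    Non-DC/non-Nyquist bins are doubled so the one-sided sum equals the
    signal energy sum(x^2) (for the default boxcar).
    """
    x = np.asarray(x, dtype=float)
    n = x.shape[-1]
    if window != "boxcar":
        x = x * get_window(window, n)
    spec = np.abs(np.fft.rfft(x, axis=-1)) ** 2 / n
    spec[..., 1:] *= 2.0
    if n % 2 == 0:  # Nyquist bin is not mirrored
        spec[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    return freqs, spec


def compute_psd(
    epochs: EpochSet, method: str = "periodogram", window: str = "boxcar"
) -> PSDFeatures:
    """PSD features for every epoch and channel.

    ``method`` is ``periodogram`` (default, raw |DFT|^2/N) or ``welch``
    (averaged modified periodograms via scipy, rescaled to the same
    energy-like normalization).
    """
    if epochs.epoch_len < 8:
        raise ValidationError("epochs too short for spectral estimation (<8 samples)")
    if method == "periodogram":
        freqs, values = periodogram_psd(epochs.data, epochs.fs, window=window)
    elif method == "welch":
        nper = min(epochs.epoch_len, 256)
        freqs, dens = _scipy_welch(
            epochs.data, fs=epochs.fs, nperseg=nper, axis=-1
        )
        # density (power/Hz) -> per-bin power on this grid
        values = dens * (freqs[1] - freqs[0]) * epochs.epoch_len / 1.0
    else:
        raise ConfigError(f"unknown PSD method {method!r}")
    band_names = tuple(BAND_TABLE)
    bp = np.stack(
        [
            values[..., (freqs >= lo) & (freqs < hi)].sum(axis=-1)
            for lo, hi in BAND_TABLE.values()
        ],
        axis=-1,
    )
    return PSDFeatures(
        values=values,
        freqs=freqs,
        band_powers=bp,
        band_names=band_names,
        labels=epochs.labels,
    )


def band_power(psd: PSDFeatures, band: str) -> np.ndarray:
    """Epochs x channels band power: sum of PSD bins with lo <= f < hi."""
    lo, hi = band_edges(band)
    mask = (psd.freqs >= lo) & (psd.freqs < hi)
    return psd.values[..., mask].sum(axis=-1)


def channel_means(epochs: EpochSet) -> np.ndarray:
    """Average waveform over epochs, shape channels x samples."""
    if epochs.n_epochs < 1:
        raise ValidationError("cannot average an empty epoch set")
    return epochs.data.mean(axis=0)


def signal_band_fraction(x: np.ndarray, fs: float, band: str) -> float:
    """Fraction of total periodogram power of a 1-D signal inside *band*."""
    freqs, spec = periodogram_psd(np.asarray(x, dtype=float), fs)
    lo, hi = band_edges(band)
    total = spec.sum()
    if total == 0:
        return 0.0
    return float(spec[(freqs >= lo) & (freqs < hi)].sum() / total)
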