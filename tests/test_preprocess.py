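"""FIR design/application, re-referencing, and CWT contracts."""

import numpy as np
import pytest
from scipy.signal import freqz

import hypnoseeg as hs
from hypnoseeg.errors import ConfigError, StateError, ValidationError
from hypnoseeg.preprocess import (
    FilterSpec,
    HIGH_PASS,
    LOW_PASS,
    NOTCH,
    WaveletSpec,
    apply_filter,
    design_fir,
    frequency_response,
    rereference,
    wavelet_scale_frequencies,
    wavelet_transform,
)
from hypnoseeg.recording import RawRecording

FS = 500.0


def _tone(freq, duration=12.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


@pytest.mark.parametrize(
    "spec,checks",
    [
        (FilterSpec(LOW_PASS, 30.0), [(20.0, "ge", 0.9), (45.0, "le", 0.1), (0.0, "ge", 1 - 1e-9)]),
        (FilterSpec(HIGH_PASS, 0.1), [(0.0, "le", 1e-6), (5.0, "ge", 0.95)]),
        (FilterSpec(NOTCH, 40.0), [(40.0, "le", 0.05), (30.0, "ge", 0.9), (50.0, "ge", 0.9)]),
    ],
)
def test_magnitude_response_contracts(spec, checks):
    coef = design_fir(spec, FS)
    for freq, op, bound in checks:
        mag = frequency_response(coef, [freq])[0]
        assert (mag >= bound) if op == "ge" else (mag <= bound), (spec.kind, freq, mag)


@pytest.mark.parametrize("kind,fc", [(LOW_PASS, 30.0), (HIGH_PASS, 0.1), (NOTCH, 40.0)])
def test_taps_symmetric_linear_phase(kind, fc):
    b = design_fir(FilterSpec(kind, fc), FS).b
    assert np.allclose(b, b[::-1], atol=1e-15)
    assert b.size % 2 == 1  # type-I (even order)


def test_dc_gains_by_kind():
    assert design_fir(FilterSpec(LOW_PASS, 30.0), FS).b.sum() == pytest.approx(1.0, abs=1e-12)
    assert abs(design_fir(FilterSpec(HIGH_PASS, 0.1), FS).b.sum()) <= 1e-6
    assert design_fir(FilterSpec(NOTCH, 40.0), FS).b.sum() == pytest.approx(1.0, abs=1e-9)


def test_notch_minimum_near_center():
    coef = design_fir(FilterSpec(NOTCH, 40.0), FS)
    freqs = np.linspace(35.0, 45.0, 501)
    mags = frequency_response(coef, freqs)
    assert abs(freqs[np.argmin(mags)] - 40.0) <= 1.0


def test_nyquist_violations_rejected():
    with pytest.raises(ConfigError, match="Nyquist"):
        design_fir(FilterSpec(LOW_PASS, 250.0), FS)
    with pytest.raises(ConfigError):
        design_fir(FilterSpec(NOTCH, 249.5), FS)
    coef = design_fir(FilterSpec(LOW_PASS, 30.0), FS)
    with pytest.raises(ValidationError):
        frequency_response(coef, [251.0])
    with pytest.raises(ConfigError, match="even"):
        FilterSpec(LOW_PASS, 30.0, order=11)


def test_frequency_response_matches_brute_force_dft(rng):
    """|H(f)| equals a direct evaluation of the tap DFT within 1e-10."""
    coef = design_fir(FilterSpec(LOW_PASS, 30.0, order=64), FS)
    freqs = rng.uniform(0, FS / 2, 20)
    mags = frequency_response(coef, freqs)
    for f, m in zip(freqs, mags):
        brute = sum(
            coef.b[r] * np.exp(-2j * np.pi * f * r / FS) for r in range(coef.b.size)
        )
        assert abs(m - abs(brute)) < 1e-10


def test_single_tap_is_identity(rng):
    raw = RawRecording(rng.standard_normal((2, 1000)), FS, ("a", "b"))
    coef = design_fir(FilterSpec(LOW_PASS, 30.0, order=0), FS)
    out = apply_filter(raw, coef)
    assert np.allclose(out.data, raw.data, atol=1e-12)
    assert out.history[-1].startswith("filter:")


def test_tone_amplitudes_through_lowpass():
    """30 Hz low-pass: 10 Hz tone within 5%, 60 Hz tone below 10%."""
    coef = design_fir(FilterSpec(LOW_PASS, 30.0), FS)
    for freq, lo, hi in ((10.0, 0.95, 1.05), (60.0, 0.0, 0.10)):
        raw = RawRecording(_tone(freq)[None, :], FS, ("x",))
        out = apply_filter(raw, coef)
        amp = np.abs(out.data[0][2000:-2000]).max()
        assert lo <= amp <= hi


def test_filtering_is_linear(rng):
    coef = design_fir(FilterSpec(LOW_PASS, 30.0), FS)
    x = rng.standard_normal((1, 4000))
    y = rng.standard_normal((1, 4000))
    fx = apply_filter(RawRecording(x, FS, ("a",)), coef).data
    fy = apply_filter(RawRecording(y, FS, ("a",)), coef).data
    fxy = apply_filter(RawRecording(x + y, FS, ("a",)), coef).data
    assert np.max(np.abs(fxy - fx - fy)) < 1e-9


def test_lowpass_highpass_commute(rng):
    lp = design_fir(FilterSpec(LOW_PASS, 30.0, order=200), FS)
    hp = design_fir(FilterSpec(HIGH_PASS, 1.0, order=200), FS)
    raw = RawRecording(rng.standard_normal((1, 3000)), FS, ("a",))
    a = apply_filter(apply_filter(raw, lp), hp).data
    b = apply_filter(apply_filter(raw, hp), lp).data
    assert np.max(np.abs(a - b)) < 1e-9


def test_zero_phase_no_lag():
    # band-limited input: 8 Hz tone; cross-correlation peak must sit at lag 0
    coef = design_fir(FilterSpec(LOW_PASS, 30.0), FS)
    x = _tone(8.0, duration=10.0)
    y = apply_filter(RawRecording(x[None, :], FS, ("a",)), coef).data[0]
    seg = slice(1000, 4000)
    lags = range(-10, 11)
    cc = [np.dot(x[seg], np.roll(y, lag)[seg]) for lag in lags]
    assert list(lags)[int(np.argmax(cc))] == 0


def test_too_short_recording_rejected(rng):
    coef = design_fir(FilterSpec(LOW_PASS, 30.0), FS)  # 501 taps
    raw = RawRecording(rng.standard_normal((1, 600)), FS, ("a",))
    with pytest.raises(ValidationError, match="short"):
        apply_filter(raw, coef)


def test_scipy_freqz_agreement():
    coef = design_fir(FilterSpec(LOW_PASS, 30.0), FS)
    w, h = freqz(coef.b, worN=[10.0, 20.0, 45.0], fs=FS)
    assert np.allclose(frequency_response(coef, [10.0, 20.0, 45.0]), np.abs(h), atol=1e-12)


# --- re-referencing ---------------------------------------------------------


def test_rereference_zero_and_constant_mastoids(rng):
    eeg = rng.standard_normal((2, 100))
    data = np.vstack([eeg, np.zeros((2, 100))])
    raw = RawRecording(data, FS, ("Fp1", "Fz", "M1", "M2"))
    out = rereference(raw)
    assert np.array_equal(out.data, eeg)
    assert out.channel_names == ("Fp1", "Fz")
    assert out.reference == "mastoid-average"

    data = np.vstack([eeg, np.full((2, 100), 3.5)])
    out = rereference(RawRecording(data, FS, ("Fp1", "Fz", "M1", "M2")))
    assert np.allclose(out.data, eeg - 3.5)


def test_rereference_default_fixture_keeps_eight_channels(default_sim):
    _, rec, *_ = default_sim
    out = rereference(rec)
    assert out.channel_names == ("Fp2", "Fpz", "Fp1", "F4", "Fz", "F3", "FC2", "FC1")


def test_rereference_errors(default_sim):
    _, rec, *_ = default_sim
    with pytest.raises(ValidationError, match="TP9"):
        rereference(rec, ("TP9", "M2"))
    once = rereference(rec)
    with pytest.raises(StateError):
        rereference(once)


# --- wavelet comparison path ------------------------------------------------


def test_wavelet_zero_signal_and_linearity(rng):
    spec = WaveletSpec(scales=tuple(np.arange(2.0, 30.0, 2.0)))
    zeros = wavelet_transform(np.zeros(500), spec, FS)
    assert np.allclose(zeros, 0.0)
    x = rng.standard_normal(500)
    c1 = wavelet_transform(x, spec, FS)
    c3 = wavelet_transform(3 * x, spec, FS)
    assert np.allclose(c3, 3 * c1, atol=1e-9)
    assert np.sum(np.abs(c3) ** 2) == pytest.approx(9 * np.sum(np.abs(c1) ** 2), rel=1e-9)


def test_wavelet_peak_scale_matches_tone():
    spec = WaveletSpec(scales=tuple(np.linspace(5, 60, 40)))
    pseudo = wavelet_scale_frequencies(spec, FS)
    x = _tone(10.0, duration=4.0)
    coeffs = wavelet_transform(x, spec, FS)
    power = (np.abs(coeffs) ** 2)[:, 500:-500].sum(axis=1)
    best = np.argmax(power)
    nearest = np.argmin(np.abs(pseudo - 10.0))
    assert abs(int(best) - int(nearest)) <= 1


def test_wavelet_validation():
    with pytest.raises(ValidationError):
        WaveletSpec(scales=())
    with pytest.raises(ValidationError):
        WaveletSpec(scales=(3.0, 2.0))
    with pytest.raises(ValidationError):
        wavelet_transform(np.array([1.0]), WaveletSpec(scales=(2.0,)), FS)
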