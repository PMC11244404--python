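"""FastICA: whitening, fixed-point recovery, artifact scoring, removal."""

import warnings

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import hypnoseeg as hs
from hypnoseeg.errors import ConfigError, NumericalError, ValidationError
from hypnoseeg.ica import (
    clean_recording,
    fastica_fit,
    fit_ica,
    identify_artifact_components,
    remove_components,
    whiten,
)
from hypnoseeg.synthdata import SOURCE_ORDER, SyntheticConfig, simulate


def matched_abs_corr(true_sources, recovered):
    """Permutation- and sign-invariant recovery score (Hungarian matching)."""
    k = true_sources.shape[0]
    C = np.abs(np.corrcoef(np.vstack([true_sources, recovered]))[:k, k:])
    rows, cols = linear_sum_assignment(-C)
    return C[rows, cols], cols


def test_whiten_identity_covariance(rng):
    X = rng.standard_normal((6, 5000)) * rng.uniform(0.5, 5, (6, 1)) + rng.uniform(-3, 3, (6, 1))
    Z, K, means = whiten(X)
    cov = Z @ Z.T / (Z.shape[1] - 1)
    assert np.max(np.abs(cov - np.eye(6))) < 1e-8
    assert np.allclose(Z, K @ (X - means[:, None]))


def test_whiten_component_count_matches_channels(default_sim):
    _, rec, *_ = default_sim
    Z, K, _ = whiten(rec.data[:8], 8)
    assert Z.shape[0] == 8 and K.shape == (8, 8)


def test_whiten_rank_deficient_error(rng):
    X = rng.standard_normal((3, 1000))
    X = np.vstack([X, X[0]])  # duplicated channel
    with pytest.raises(NumericalError, match="rank deficient"):
        whiten(X)


def test_already_unmixed_uniform_sources_recovered(rng):
    S = rng.uniform(-np.sqrt(3), np.sqrt(3), (8, 20000))
    Z, K, m = whiten(S)
    model = fastica_fit(Z, seed=0, K=K, means=m)
    corr, _ = matched_abs_corr(S, model.sources(S))
    assert np.all(corr >= 0.999)


def test_synthdata_recovery_under_random_mixing(rng):
    """Blind separation of the 8 generator sources: matched |corr| >= 0.95."""
    cfg = SyntheticConfig(duration=60.0, seed=21)
    _, _, sources, _ = simulate(cfg)
    A = rng.standard_normal((8, 8))
    X = A @ sources.sources
    Z, K, m = whiten(X)
    model = fastica_fit(Z, seed=3, K=K, means=m)
    corr, _ = matched_abs_corr(sources.sources, model.sources(X))
    assert corr.mean() >= 0.95
    # orthonormality after symmetric decorrelation
    assert np.max(np.abs(model.W @ model.W.T - np.eye(8))) <= 1e-6


def test_agrees_with_sklearn_fastica(rng):
    """Independent implementation cross-check on the same mixture."""
    sklearn_ica = pytest.importorskip("sklearn.decomposition")
    cfg = SyntheticConfig(duration=30.0, seed=22)
    _, _, sources, _ = simulate(cfg)
    A = rng.standard_normal((8, 8))
    X = A @ sources.sources
    Z, K, m = whiten(X)
    mine = fastica_fit(Z, seed=3, K=K, means=m)
    corr_mine, _ = matched_abs_corr(sources.sources, mine.sources(X))
    sk = sklearn_ica.FastICA(n_components=8, random_state=0, max_iter=500, tol=1e-4)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        S_sk = sk.fit_transform(X.T).T
    corr_sk, _ = matched_abs_corr(sources.sources, S_sk)
    assert corr_mine.mean() >= 0.95
    assert abs(corr_mine.mean() - corr_sk.mean()) < 0.05


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_reconstruction_identity(rng):
    X = rng.standard_normal((5, 8000)) * 3 + 1.0
    Z, K, m = whiten(X)
    model = fastica_fit(Z, seed=0, K=K, means=m)
    S = model.sources(X)
    recon = model.A @ S + model.means[:, None]
    assert np.max(np.abs(recon - X)) < 1e-8


def test_seed_determinism_and_log(default_sim):
    _, rec, *_ = default_sim
    m1 = fit_ica(rec, seed=4)
    m2 = fit_ica(rec, seed=4)
    assert np.array_equal(m1.W, m2.W)
    assert len(m1.iteration_log) == m1.n_iter
    assert m1.iteration_log[-1] < 1e-4  # converged below tol


def test_nonconvergence_warns_and_flags(default_sim):
    _, rec, *_ = default_sim
    with pytest.warns(RuntimeWarning, match="did not converge"):
        model = fit_ica(rec, max_iter=2, seed=0)
    assert not model.converged


def test_invalid_arguments(rng):
    Z = rng.standard_normal((4, 1000))
    with pytest.raises(ConfigError):
        fastica_fit(Z, g="cube")
    with pytest.raises(ConfigError):
        fastica_fit(Z, tol=0.0)
    with pytest.raises(ValidationError):
        fastica_fit(Z, n_components=6)


@pytest.mark.filterwarnings("ignore::RuntimeWarning")
def test_remove_components_empty_and_full(rng):
    X = rng.standard_normal((6, 6000))
    Z, K, m = whiten(X)
    model = fastica_fit(Z, seed=0, K=K, means=m)
    assert np.max(np.abs(remove_components(X, model, []) - X)) < 1e-9
    # excluding every component leaves only the channel means
    resid = remove_components(X, model, range(6))
    assert np.max(np.abs(resid - m[:, None])) < 1e-8
    with pytest.raises(ValidationError):
        remove_components(X, model, [7])


def test_blink_component_ranks_first_across_seeds():
    """The injected blink source tops the artifact ranking in >=95% of seeds."""
    hits = 0
    n_seeds = 20
    for seed in range(n_seeds):
        cfg = SyntheticConfig(duration=30.0, seed=seed)
        rec, _, sources, _ = simulate(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_ica(rec, seed=seed)
        S = model.sources(rec.data)
        _, cols = matched_abs_corr(sources.sources, S)
        blink_comp = cols[list(SOURCE_ORDER).index("blink")]
        scores = identify_artifact_components(model, S, rec.channel_names, fs=rec.fs)
        hits += scores[0].index == blink_comp
    assert hits >= int(0.95 * n_seeds)


def test_no_artifacts_no_flags():
    for seed in (0, 1, 2):
        cfg = SyntheticConfig(
            duration=30.0, seed=seed, artifact_rate=0.0, cardiac_rate_hz=0.0
        )
        rec, *_ = simulate(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = fit_ica(rec, seed=seed)
        scores = identify_artifact_components(
            model, model.sources(rec.data), rec.channel_names, fs=rec.fs
        )
        assert not any(s.flagged for s in scores)


def test_two_default_flags_on_standard_fixture(default_sim):
    """Blink + cardiac: two components excluded, as in visual ICA practice."""
    _, rec, *_ = default_sim
    cleaned, model, scores = clean_recording(rec, seed=0)
    assert len(model.excluded) == 2


def test_blink_removal_band_power(default_sim):
    """Removing the blink component cuts Fp delta-band power >= 90% while
    alpha power moves <= 10%."""
    cfg, rec, events, sources, mixing = default_sim
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = fit_ica(rec, seed=1)
    S = model.sources(rec.data)
    _, cols = matched_abs_corr(sources.sources, S)
    blink_comp = int(cols[list(SOURCE_ORDER).index("blink")])
    corrected = remove_components(rec.data, model, [blink_comp])

    from hypnoseeg.features import periodogram_psd

    fp = [rec.channel_index(n) for n in ("Fp2", "Fpz", "Fp1")]

    def band(data, lo, hi):
        freqs, spec = periodogram_psd(data[fp], rec.fs)
        return spec[:, (freqs >= lo) & (freqs < hi)].sum()

    delta_before = band(rec.data, 0.5, 4.0)
    delta_after = band(corrected, 0.5, 4.0)
    alpha_before = band(rec.data, 8.0, 13.0)
    alpha_after = band(corrected, 8.0, 13.0)
    assert delta_after <= 0.10 * delta_before
    assert abs(alpha_after - alpha_before) <= 0.10 * alpha_before
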