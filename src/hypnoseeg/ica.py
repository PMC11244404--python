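"""From-scratch FastICA with automated artifact-component scoring.

The decomposition follows the classic fixed-point scheme: PCA whitening,
the parallel (symmetric) one-unit update

    W_new = E{g(WZ) Z^T} - diag(E{g'(WZ)}) W

with ``g = tanh`` (``pow3`` available), followed by symmetric decorrelation
W <- (W W^T)^{-1/2} W after every sweep. Convergence is declared when every
row of the new unmixing matrix is colinear with its previous iterate
(max |1 - |<w_new, w_old>|| < tol).

Artifact components are scored automatically by combining (a) the
concentration of the component's scalp projection on the frontal-pole (Fp)
electrodes, (b) excess kurtosis of the component time series, and (c)
template evidence: cross-correlation with a stereotyped blink pulse and
autocorrelation periodicity in the cardiac beat range. Components above a
threshold are flagged; callers can always override the exclusion set.
Corrected signals are X - A_excluded S_excluded (back-projection of the
flagged components subtracted in sensor space).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigError, NumericalError, ValidationError
from .recording import RawRecording
from .synthdata import _blink_kernel

DEFAULT_N_COMPONENTS = 8


@dataclass
class UnmixingModel:
    """Fitted ICA decomposition.

    ``W`` unmixes *whitened* data; ``K`` is the whitening matrix and
    ``means`` the removed channel means, so sources are
    ``S = W @ K @ (X - means)``. ``A`` is the estimated mixing matrix
    (sensor-space scalp projections as columns).
    """

    W: np.ndarray  # n_components x n_components, whitened space
    K: np.ndarray  # n_components x n_channels whitening matrix
    A: np.ndarray  # n_channels x n_components mixing matrix
    means: np.ndarray  # per-channel means
    n_components: int
    converged: bool
    n_iter: int
    iteration_log: tuple[float, ...]  # per-sweep max row deviation
    channel_names: tuple[str, ...] = ()
    excluded: tuple[int, ...] = ()

    def unmixing_sensor(self) -> np.ndarray:
        """Sensor-space unmixing matrix W @ K."""
        return self.W @ self.K

    def sources(self, X: np.ndarray) -> np.ndarray:
        """Recovered source time series, n_components x samples."""
        return self.unmixing_sensor() @ (np.asarray(X, float) - self.means[:, None])


def whiten(
    X: np.ndarray, n_components: int | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA-whiten channels x samples data.

    Returns ``(Z, K, means)`` with ``Z = K (X - means)`` having identity
    covariance (sample covariance normalized by n-1).
    """
    X = np.asarray(X, dtype=float)
    n_ch, n_samp = X.shape
    k = n_ch if n_components is None else n_components
    if k > n_ch:
        raise ValidationError(
            f"cannot extract {k} components from {n_ch} channels"
        )
    means = X.mean(axis=1)
    Xc = X - means[:, None]
    cov = (Xc @ Xc.T) / (n_samp - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1][:k]
    evals, evecs = evals[order], evecs[:, order]
    if evals[-1] <= 1e-12 * max(evals[0], 1.0):
        raise NumericalError(
            f"covariance is rank deficient (eigenvalue {evals[-1]:.3e}); "
            f"reduce n_components below {k}"
        )
    K = (evecs / np.sqrt(evals)).T
    return K @ Xc, K, means


def _g_tanh(u: np.ndarray):
    gu = np.tanh(u)
    return gu, 1.0 - gu**2


def _g_pow3(u: np.ndarray):
    return u**3, 3.0 * u**2


_NONLINEARITIES = {"tanh": _g_tanh, "pow3": _g_pow3}


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^(-1/2) W (symmetric decorrelation)."""
    evals, evecs = np.linalg.eigh(W @ W.T)
    if np.any(evals <= 0):
        raise NumericalError("degenerate unmixing iterate")
    inv_sqrt = (evecs / np.sqrt(evals)) @ evecs.T
    return inv_sqrt @ W


def fastica_fit(
    Z: np.ndarray,
    n_components: int | None = None,
    g: str = "tanh",
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int = 0,
    K: np.ndarray | None = None,
    means: np.ndarray | None = None,
    channel_names: tuple[str, ...] = (),
) -> UnmixingModel:
    """Fixed-point FastICA on whitened data ``Z`` (components x samples).

    ``K``/``means`` are carried into the model when the caller whitened the
    data via :func:`whiten`; otherwise identity whitening is assumed.
    """
    Z = np.asarray(Z, dtype=float)
    k = Z.shape[0] if n_components is None else n_components
    if k != Z.shape[0]:
        raise ValidationError(
            f"whitened data has {Z.shape[0]} components, requested {k}"
        )
    if g not in _NONLINEARITIES:
        raise ConfigError(f"unknown nonlinearity {g!r}; use tanh or pow3")
    if not tol > 0:
        raise ConfigError("tol must be positive")
    nonlin = _NONLINEARITIES[g]
    n_samp = Z.shape[1]
    rng = np.random.default_rng(seed)
    W = _sym_decorrelate(rng.standard_normal((k, k)))

    log = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        U = W @ Z
        gu, gprime = nonlin(U)
        W_new = (gu @ Z.T) / n_samp - np.diag(gprime.mean(axis=1)) @ W
        if not np.all(np.isfinite(W_new)):
            raise NumericalError(f"NaN/Inf in FastICA update at sweep {it}")
        W_new = _sym_decorrelate(W_new)
        delta = float(np.max(np.abs(1.0 - np.abs(np.sum(W_new * W, axis=1)))))
        log.append(delta)
        W = W_new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"FastICA did not converge in {max_iter} sweeps "
            f"(last delta {log[-1]:.2e}); returning best iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    n_ch = Z.shape[0] if K is None else K.shape[1]
    K_full = np.eye(k) if K is None else K
    means_full = np.zeros(n_ch) if means is None else means
    A = np.linalg.pinv(W @ K_full)
    return UnmixingModel(
        W=W,
        K=K_full,
        A=A,
        means=means_full,
        n_components=k,
        converged=converged,
        n_iter=it,
        iteration_log=tuple(log),
        channel_names=tuple(channel_names),
    )


def fit_ica(
    raw: RawRecording,
    n_components: int = DEFAULT_N_COMPONENTS,
    g: str = "tanh",
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int = 0,
) -> UnmixingModel:
    """Whiten a recording and fit FastICA in one call."""
    Z, K, means = whiten(raw.data, n_components)
    return fastica_fit(
        Z,
        n_components,
        g=g,
        tol=tol,
        max_iter=max_iter,
        seed=seed,
        K=K,
        means=means,
        channel_names=raw.channel_names,
    )


# ---------------------------------------------------------------------------
# artifact identification


def _excess_kurtosis(x: np.ndarray) -> float:
    x = x - x.mean()
    var = np.mean(x**2)
    if var == 0:
        return 0.0
    return float(np.mean(x**4) / var**2 - 3.0)


def _template_correlation(source: np.ndarray, kernel: np.ndarray) -> float:
    """Max |normalized cross-correlation| between source and template."""
    s = source - source.mean()
    k = kernel - kernel.mean()
    num = np.abs(np.correlate(s, k, mode="valid"))
    # local normalization by the sliding signal energy under the template
    energy = np.convolve(s**2, np.ones(k.size), mode="valid")
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = num / (np.sqrt(energy) * np.linalg.norm(k))
    cc = cc[np.isfinite(cc)]
    return float(cc.max()) if cc.size else 0.0


def _periodicity(source: np.ndarray, fs: float, lo_s: float = 0.5, hi_s: float = 1.2) -> float:
    """Max normalized autocorrelation at lags in [lo_s, hi_s] seconds."""
    s = source - source.mean()
    n = s.size
    lo = int(lo_s * fs)
    hi = min(int(hi_s * fs), n - 1)
    if hi <= lo:
        return 0.0
    denom = float(np.dot(s, s))
    if denom == 0:
        return 0.0
    ac = np.array(
        [np.dot(s[: n - lag], s[lag:]) / denom for lag in range(lo, hi, max(1, int(fs // 50)))]
    )
    return float(np.abs(ac).max()) if ac.size else 0.0


@dataclass
class ComponentScore:
    index: int
    score: float
    frontal_fraction: float
    kurtosis: float
    blink_template: float
    periodicity: float
    flagged: bool


def identify_artifact_components(
    model: UnmixingModel,
    sources: np.ndarray,
    channel_names: tuple[str, ...] | None = None,
    threshold: float = 0.55,
    fs: float = 500.0,
) -> list[ComponentScore]:
    """Score each component for blink/cardiac artifact character.

    Returns scores sorted descending; ``flagged`` marks components whose
    score exceeds *threshold*. An empty flag set is a valid outcome.
    """
    names = tuple(channel_names or model.channel_names)
    if not names:
        names = tuple(f"ch{i}" for i in range(model.A.shape[0]))
    fp_idx = [i for i, nm in enumerate(names) if nm.startswith("Fp")]
    kernel = _blink_kernel(fs)

    scores = []
    col_abs = np.abs(model.A)
    for j in range(model.n_components):
        col = col_abs[:, j]
        frontal = float(col[fp_idx].sum() / col.sum()) if col.sum() > 0 else 0.0
        kurt = _excess_kurtosis(sources[j])
        kurt_norm = min(max(kurt, 0.0) / 10.0, 1.0)
        blink_cc = _template_correlation(sources[j], kernel)
        period = _periodicity(sources[j], fs)
        blink_score = 0.45 * frontal + 0.30 * kurt_norm + 0.25 * blink_cc
        cardiac_score = 0.55 * kurt_norm + 0.45 * period
        score = max(blink_score, cardiac_score)
        scores.append(
            ComponentScore(
                index=j,
                score=score,
                frontal_fraction=frontal,
                kurtosis=kurt,
                blink_template=blink_cc,
                periodicity=period,
                flagged=score > threshold,
            )
        )
    scores.sort(key=lambda s: s.score, reverse=True)
    return scores


def remove_components(
    X: np.ndarray, model: UnmixingModel, excluded
) -> np.ndarray:
    """X_corrected = X - A_excluded S_excluded (sensor space).

    With an empty exclusion set the input is returned unchanged (up to
    floating point); excluding everything removes the full retained
    subspace.
    """
    excluded = sorted(set(int(i) for i in excluded))
    if any(i < 0 or i >= model.n_components for i in excluded):
        raise ValidationError(
            f"excluded indices {excluded} outside 0..{model.n_components - 1}"
        )
    X = np.asarray(X, dtype=float)
    if not excluded:
        return X.copy()
    S = model.sources(X)
    return X - model.A[:, excluded] @ S[excluded]


def clean_recording(
    raw: RawRecording,
    n_components: int = DEFAULT_N_COMPONENTS,
    exclude: str | list = "auto",
    threshold: float = 0.55,
    seed: int = 0,
) -> tuple[RawRecording, UnmixingModel, list[ComponentScore]]:
    """Fit ICA, flag artifact components, and return the corrected recording.

    ``exclude`` is either ``"auto"`` (use the scorer) or an explicit list of
    component indices (manual override).
    """
    model = fit_ica(raw, n_components=n_components, seed=seed)
    S = model.sources(raw.data)
    scores = identify_artifact_components(
        model, S, raw.channel_names, threshold=threshold, fs=raw.fs
    )
    if exclude == "auto":
        excluded = tuple(s.index for s in scores if s.flagged)
    else:
        excluded = tuple(int(i) for i in exclude)
    model.excluded = excluded
    corrected = remove_components(raw.data, model, excluded)
    cleaned = raw.with_data(
        corrected, f"ica:excluded={list(excluded)}"
    )
    return cleaned, model, scores
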