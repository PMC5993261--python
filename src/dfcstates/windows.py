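"""Sliding-window (dynamic) connectivity estimation.

Each subject-run's prepared time series is cut into temporally
overlapping windows (default: 15 volumes = 30 s at TR 2 s, step 1
volume) and a node x node connectivity matrix is estimated per window —
either the Pearson correlation of the windowed rows (optionally under a
Gaussian taper) or an L1-regularized sparse precision matrix (graphical
lasso) reported as partial correlations. The stack of per-window
matrices, vectorized to upper-triangle edge vectors, is the feature
space in which recurring connectivity states are clustered.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.covariance import graphical_lasso

from .containers import ComponentTimeSeries

__all__ = [
    "WindowParams", "WindowedConnectivity", "make_windows",
    "window_correlation", "sparse_precision", "partial_correlation",
    "dfc_stack", "vectorize_upper", "unvectorize_upper",
    "SlidingWindowConnectivity",
]


@dataclass
class WindowParams:
    """Sliding-window and estimator settings.

    ``taper`` is ``"rectangular"`` or ``"gaussian"`` (with
    ``gaussian_sigma`` in volumes); ``estimator`` is ``"correlation"``
    or ``"sparse_precision"`` (graphical lasso with ``l1_penalty``,
    features are then partial correlations).
    """
    window_length: int = 15
    step: int = 1
    taper: str = "rectangular"
    gaussian_sigma: float = 3.0
    estimator: str = "correlation"
    l1_penalty: float = 0.1

    def __post_init__(self):
        if self.window_length < 3:
            raise ValueError("window_length must be >= 3")
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.taper not in ("rectangular", "gaussian"):
            raise ValueError(f"unknown taper {self.taper!r}")
        if self.estimator not in ("correlation", "sparse_precision"):
            raise ValueError(f"unknown estimator {self.estimator!r}")
        if self.l1_penalty < 0:
            raise ValueError("l1_penalty must be >= 0")

    def weights(self) -> np.ndarray:
        """Window weight profile, normalized to sum 1."""
        if self.taper == "rectangular":
            w = np.ones(self.window_length)
        else:
            t = np.arange(self.window_length) - (self.window_length - 1) / 2.0
            w = np.exp(-0.5 * (t / self.gaussian_sigma) ** 2)
        return w / w.sum()


@dataclass
class WindowedConnectivity:
    """Ordered stack of per-window symmetric connectivity matrices."""
    windows: list
    window_starts: np.ndarray
    params: WindowParams
    subject_id: str = ""
    run_id: str = ""
    flags: list = field(default_factory=list)  # per-window QC notes

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def n_nodes(self) -> int:
        return self.windows[0].shape[0]

    def to_features(self) -> np.ndarray:
        """(n_windows, n_edges) matrix of vectorized upper triangles."""
        return np.array([vectorize_upper(W) for W in self.windows])


def make_windows(n_volumes: int, window_length: int = 15, step: int = 1):
    """Half-open ``[start, start + window_length)`` index pairs, 0-based."""
    if window_length < 3:
        raise ValueError("window_length must be >= 3")
    if step < 1:
        raise ValueError("step must be >= 1")
    if n_volumes < window_length:
        raise ValueError(
            f"{n_volumes} volumes is shorter than window length "
            f"{window_length}")
    starts = range(0, n_volumes - window_length + 1, step)
    return [(s, s + window_length) for s in starts]


def vectorize_upper(M: np.ndarray) -> np.ndarray:
    """Strict upper triangle of a symmetric matrix, row-major order."""
    iu = np.triu_indices(M.shape[0], k=1)
    return M[iu]


def unvectorize_upper(v: np.ndarray, n_nodes: int | None = None) -> np.ndarray:
    """Inverse of :func:`vectorize_upper` (zero diagonal)."""
    v = np.asarray(v, dtype=float)
    if n_nodes is None:
        n_nodes = int(round((1 + np.sqrt(1 + 8 * v.size)) / 2))
    if n_nodes * (n_nodes - 1) // 2 != v.size:
        raise ValueError(
            f"edge vector of length {v.size} does not match any node count "
            f"(tried {n_nodes})")
    M = np.zeros((n_nodes, n_nodes))
    iu = np.triu_indices(n_nodes, k=1)
    M[iu] = v
    return M + M.T


def window_correlation(X: np.ndarray, weights: np.ndarray | None = None):
    """(Weighted) Pearson correlation of a windowed segment.

    Nodes that are constant within the window get zeroed correlations
    (diagonal stays 1) and the affected node indices are returned as a
    QC flag list.

    Returns ``(R, flagged_nodes)``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n < 3:
        raise ValueError("window must contain at least 3 volumes")
    if weights is None:
        weights = np.full(n, 1.0 / n)
    weights = np.asarray(weights, dtype=float)
    weights = weights / weights.sum()
    mu = weights @ X
    Xc = X - mu
    cov = (Xc * weights[:, None]).T @ Xc
    sd = np.sqrt(np.diag(cov))
    flagged = np.where(sd <= 1e-14 * max(1.0, np.abs(X).max()))[0]
    sd_safe = sd.copy()
    sd_safe[flagged] = 1.0
    R = cov / np.outer(sd_safe, sd_safe)
    if flagged.size:
        warnings.warn(
            f"constant node(s) {flagged.tolist()} within window; "
            "their correlations set to 0", RuntimeWarning, stacklevel=2)
        R[flagged, :] = 0.0
        R[:, flagged] = 0.0
    np.fill_diagonal(R, 1.0)
    np.clip(R, -1.0, 1.0, out=R)
    return 0.5 * (R + R.T), flagged.tolist()


def sparse_precision(sample_cov: np.ndarray, l1_penalty: float,
                     max_iter: int = 200):
    """L1-penalized sparse inverse covariance (graphical lasso).

    Minimizes ``-log det(P) + tr(S P) + l1_penalty * ||P_offdiag||_1``
    over symmetric positive-definite P. At ``l1_penalty = 0`` the
    solution is the plain matrix inverse of a well-conditioned input.

    Returns ``(precision, partial_corr)``.
    """
    S = np.asarray(sample_cov, dtype=float)
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("sample covariance must be symmetric")
    eigs = np.linalg.eigvalsh(S)
    if eigs.min() < -1e-8:
        raise ValueError("sample covariance must be positive semi-definite")
    if l1_penalty < 0:
        raise ValueError("l1_penalty must be >= 0")
    if l1_penalty == 0:
        if eigs.min() <= 1e-12:
            raise ValueError(
                "unpenalized precision requires a positive-definite input")
        P = np.linalg.inv(S)
    else:
        try:
            _, P = graphical_lasso(S, alpha=l1_penalty, max_iter=max_iter)
        except FloatingPointError as err:  # pragma: no cover
            raise RuntimeError(
                f"graphical lasso failed to converge within {max_iter} "
                f"iterations: {err}") from err
    P = 0.5 * (P + P.T)
    return P, partial_correlation(P)


def partial_correlation(precision: np.ndarray) -> np.ndarray:
    """Partial correlations from a precision matrix: -P_ij/sqrt(P_ii P_jj)."""
    d = np.sqrt(np.diag(precision))
    R = -precision / np.outer(d, d)
    np.fill_diagonal(R, 1.0)
    return R


def dfc_stack(ts: ComponentTimeSeries, params: WindowParams | None = None,
              require_prepared: bool = True) -> WindowedConnectivity:
    """Per-window connectivity stack for one subject-run.

    By default refuses unprepared input (missing detrend/filter flags)
    so the pipeline order cannot be violated silently.
    """
    params = params or WindowParams()
    if require_prepared and "detrended" not in ts.prep_flags:
        raise ValueError(
            "time series is not prepared (run the preprocessor first, or "
            "pass require_prepared=False)")
    pairs = make_windows(ts.n_volumes, params.window_length, params.step)
    w = params.weights()
    mats, flags = [], []
    for start, end in pairs:
        R, flagged = window_correlation(ts.data[start:end], weights=w)
        if params.estimator == "sparse_precision":
            _, R = sparse_precision(_shrink_to_pd(R), params.l1_penalty)
        mats.append(R)
        flags.append(flagged)
    return WindowedConnectivity(
        windows=mats, window_starts=np.array([p[0] for p in pairs]),
        params=params, subject_id=ts.subject_id, run_id=ts.run_id,
        flags=flags)


def _shrink_to_pd(R: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Minimal ridge shrinkage making a correlation matrix PD (short
    windows give rank-deficient sample correlations)."""
    lo = np.linalg.eigvalsh(R).min()
    if lo > eps:
        return R
    lam = (eps - lo) / (1.0 + eps - lo)
    return (1 - lam) * R + lam * np.eye(R.shape[0])


class SlidingWindowConnectivity(BaseEstimator, TransformerMixin):
    """Transformer: (n_volumes, n_nodes) -> (n_windows, n_edges) features.

    Each output row is the vectorized upper triangle of one window's
    connectivity matrix (correlations, or partial correlations when
    ``estimator="sparse_precision"``). Stateless; ``fit`` only records
    the input dimension.
    """

    def __init__(self, window_length: int = 15, step: int = 1,
                 taper: str = "rectangular", gaussian_sigma: float = 3.0,
                 estimator: str = "correlation", l1_penalty: float = 0.1):
        self.window_length = window_length
        self.step = step
        self.taper = taper
        self.gaussian_sigma = gaussian_sigma
        self.estimator = estimator
        self.l1_penalty = l1_penalty

    def _params(self) -> WindowParams:
        return WindowParams(window_length=self.window_length, step=self.step,
                            taper=self.taper,
                            gaussian_sigma=self.gaussian_sigma,
                            estimator=self.estimator,
                            l1_penalty=self.l1_penalty)

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (volumes x nodes)")
        self._params()  # validate
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        ts = ComponentTimeSeries(data=X, tr_seconds=1.0)
        stack = dfc_stack(ts, self._params(), require_prepared=False)
        return stack.to_features()
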