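"""Group-level multivariate Gaussian hidden Markov model of brain states.

A single HMM is fit to the concatenated, per-subject standardized component
timecourses of a cohort.  Emissions are multivariate Gaussian with
state-specific means and one covariance matrix shared across states, so the
latent states are activation patterns and the dynamic structure is driven by
mean shifts rather than by connectivity changes.  Fitting is maximum-
likelihood EM (Baum–Welch) with k-means initialization and multiple
restarts; the forward–backward recursion uses per-frame scaling, which is
numerically equivalent to log-space and never underflows on finite input.

Per-subject temporal metrics derived from the fit:

* fractional occupancy — the proportion of scan time each state is active
  (posterior-probability mean by default), compositional across states;
* switching rate — the fraction of volume pairs at which the Viterbi path
  changes state;
* mean state lifetimes — average dwell time per state in volumes.

Each subject's chain is restarted at its boundary with the model's initial
distribution; subjects share transition matrix and emission parameters
(a group-level model).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import cholesky, solve_triangular
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianHMM",
    "PosteriorStates",
    "StateTemporalMetrics",
    "standardize_and_concatenate",
    "forward_backward",
    "fit_hmm",
    "viterbi",
    "fractional_occupancy",
    "switching_rate",
    "mean_lifetimes",
    "state_metrics",
    "match_states",
    "dice_coefficient",
    "dual_regression_stage1",
]


@dataclass
class GaussianHMM:
    """K-state Gaussian HMM with a covariance matrix common to all states."""

    means: np.ndarray  # (K, C)
    covariance: np.ndarray  # (C, C)
    transition: np.ndarray  # (K, K) row-stochastic
    initial: np.ndarray  # (K,)
    log_likelihood_trace: list = field(default_factory=list)

    @property
    def n_states(self) -> int:
        return self.means.shape[0]

    @property
    def n_channels(self) -> int:
        return self.means.shape[1]

    def validate(self, atol: float = 1e-10) -> None:
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=atol):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=atol):
            raise ValueError("initial distribution must sum to 1")
        if not np.allclose(self.covariance, self.covariance.T, atol=1e-8):
            raise ValueError("covariance must be symmetric")


@dataclass
class PosteriorStates:
    gamma: np.ndarray  # (T, K) posterior state probabilities
    xi: np.ndarray  # (T-1, K, K) pairwise posteriors, each slice sums to 1
    viterbi_path: np.ndarray  # (T,)
    loglik: float


@dataclass
class StateTemporalMetrics:
    fractional_occupancy: np.ndarray  # (K,)
    switching_rate: float
    mean_lifetime: np.ndarray  # (K,) in volumes; NaN for unvisited states


def standardize_and_concatenate(series_list) -> tuple[np.ndarray, list]:
    """Z-score every channel within subject and stack subjects in time.

    Returns ``(X, boundaries)`` where ``boundaries`` is a list of
    ``(start, stop)`` row ranges, one per subject, partitioning ``X``.
    Raises on any zero-variance channel (degenerate input).
    """
    mats = []
    boundaries = []
    start = 0
    C = None
    for i, s in enumerate(series_list):
        data = np.asarray(s, dtype=float) if isinstance(s, (np.ndarray, list)) else s.data
        if C is None:
            C = data.shape[1]
        elif data.shape[1] != C:
            raise ValueError("all subjects must share the channel count")
        sd = data.std(axis=0, ddof=0)
        if np.any(sd < 1e-12):
            bad = int(np.argmin(sd))
            raise ValueError(f"zero-variance channel {bad} in subject {i}")
        mats.append((data - data.mean(axis=0)) / sd)
        boundaries.append((start, start + data.shape[0]))
        start += data.shape[0]
    return np.vstack(mats), boundaries


def _emission_logpdf(model: GaussianHMM, X: np.ndarray) -> np.ndarray:
    """Per-frame per-state Gaussian log-densities, (T, K)."""
    C = model.n_channels
    L = cholesky(model.covariance, lower=True)
    logdet = 2.0 * np.log(np.diag(L)).sum()
    Xw = solve_triangular(L, X.T, lower=True).T  # (T, C)
    Mw = solve_triangular(L, model.means.T, lower=True).T  # (K, C)
    quad = (
        (Xw**2).sum(axis=1)[:, None]
        - 2.0 * Xw @ Mw.T
        + (Mw**2).sum(axis=1)[None, :]
    )
    return -0.5 * (quad + logdet + C * np.log(2.0 * np.pi))


def _scaled_passes(model: GaussianHMM, logB: np.ndarray):
    """Scaled forward and backward passes for one subject.

    Returns (alpha_hat, beta_hat, B, loglik) where alpha_hat rows are
    normalized filtering distributions and loglik is exact (scale factors
    and the per-frame log-shift are accumulated in log space).
    """
    T, K = logB.shape
    shift = logB.max(axis=1)
    B = np.exp(logB - shift[:, None])
    A = model.transition
    alpha = np.empty((T, K))
    c = np.empty(T)
    a = model.initial * B[0]
    c[0] = a.sum()
    if c[0] <= 0:
        raise FloatingPointError("forward pass underflow at t=0")
    alpha[0] = a / c[0]
    for t in range(1, T):
        a = (alpha[t - 1] @ A) * B[t]
        c[t] = a.sum()
        if c[t] <= 0:
            raise FloatingPointError(f"forward pass underflow at t={t}")
        alpha[t] = a / c[t]
    beta = np.empty((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    loglik = float(np.log(c).sum() + shift.sum())
    return alpha, beta, B, c, loglik


def forward_backward(model: GaussianHMM, series: np.ndarray) -> PosteriorStates:
    """Exact posteriors for one subject's series (T, C).

    ``loglik`` equals the log of the path-summed likelihood; ``gamma`` rows
    and ``xi`` slices are normalized.  The Viterbi path is included for
    convenience.
    """
    X = np.asarray(series, dtype=float)
    if X.shape[1] != model.n_channels:
        raise ValueError("series channel count does not match the model")
    logB = _emission_logpdf(model, X)
    alpha, beta, B, c, loglik = _scaled_passes(model, logB)
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True)
    A = model.transition
    xi = alpha[:-1, :, None] * A[None, :, :] * (B[1:] * beta[1:])[:, None, :]
    xi /= xi.sum(axis=(1, 2), keepdims=True)
    return PosteriorStates(gamma, xi, _viterbi_from_logB(model, logB), loglik)


def _viterbi_from_logB(model: GaussianHMM, logB: np.ndarray) -> np.ndarray:
    T, K = logB.shape
    logA = np.log(np.maximum(model.transition, 1e-300))
    delta = np.log(np.maximum(model.initial, 1e-300)) + logB[0]
    psi = np.zeros((T, K), dtype=np.intp)
    for t in range(1, T):
        cand = delta[:, None] + logA
        psi[t] = np.argmax(cand, axis=0)
        delta = cand[psi[t], np.arange(K)] + logB[t]
    path = np.empty(T, dtype=np.intp)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 2, -1, -1):
        path[t] = psi[t + 1][path[t + 1]]
    return path


def viterbi(model: GaussianHMM, series: np.ndarray) -> np.ndarray:
    """Most probable joint state path for one series."""
    X = np.asarray(series, dtype=float)
    if X.shape[1] != model.n_channels:
        raise ValueError("series channel count does not match the model")
    return _viterbi_from_logB(model, _emission_logpdf(model, X))


# ---------------------------------------------------------------------------
# EM fitting


def _batch_e_step(model: GaussianHMM, Xs: np.ndarray):
    """E-step vectorized across subjects with equal series length.

    Xs: (N, T, C).  Returns (gamma (N,T,K), xi_sum (K,K), gamma0 (K,),
    total loglik).  The time recursion loops over T only; each step operates
    on all subjects at once.
    """
    N, T, C = Xs.shape
    K = model.n_states
    logB = _emission_logpdf(model, Xs.reshape(N * T, C)).reshape(N, T, K)
    shift = logB.max(axis=2)
    B = np.exp(logB - shift[:, :, None])
    A = model.transition
    alpha = np.empty((N, T, K))
    c = np.empty((N, T))
    a = model.initial[None, :] * B[:, 0]
    c[:, 0] = a.sum(axis=1)
    alpha[:, 0] = a / c[:, 0, None]
    for t in range(1, T):
        a = (alpha[:, t - 1] @ A) * B[:, t]
        c[:, t] = a.sum(axis=1)
        if np.any(c[:, t] <= 0):
            raise FloatingPointError(f"forward pass underflow at t={t}")
        alpha[:, t] = a / c[:, t, None]
    beta = np.ones((N, K))
    gamma = np.empty((N, T, K))
    gamma[:, -1] = alpha[:, -1]
    xi_sum = np.zeros((K, K))
    for t in range(T - 2, -1, -1):
        Bb = B[:, t + 1] * beta  # (N, K)
        xi_sum += A * (alpha[:, t].T @ (Bb / c[:, t + 1, None]))
        beta = (Bb @ A.T) / c[:, t + 1, None]
        g = alpha[:, t] * beta
        gamma[:, t] = g / g.sum(axis=1, keepdims=True)
    loglik = float(np.log(c).sum() + shift.sum())
    return gamma, xi_sum, gamma[:, 0].sum(axis=0), loglik


def _subject_list(X: np.ndarray, boundaries) -> list:
    return [X[a:b] for a, b in boundaries]


def _m_step(
    X_all: np.ndarray,
    gamma_all: np.ndarray,
    xi_sum: np.ndarray,
    gamma0: np.ndarray,
    n_subjects: int,
    rng: np.random.Generator,
) -> GaussianHMM:
    Ttot, C = X_all.shape
    K = gamma_all.shape[1]
    Nk = gamma_all.sum(axis=0)  # (K,)
    # empty-state guard: re-seed starved states at random frames
    starved = Nk < 1.0
    if np.any(starved):
        for k in np.where(starved)[0]:
            logger.warning("state %d starved (mass %.3g); re-initializing", k, Nk[k])
            j = int(rng.integers(0, Ttot))
            gamma_all[j] = 0.0
            gamma_all[j, k] = 1.0
        Nk = gamma_all.sum(axis=0)
    means = (gamma_all.T @ X_all) / Nk[:, None]
    # responsibility-pooled covariance shared across states
    S = X_all.T @ X_all - (means.T * Nk) @ means
    cov = S / Ttot
    cov = 0.5 * (cov + cov.T)
    cov += (1e-6 * np.trace(cov) / C) * np.eye(C)
    trans = xi_sum / np.maximum(xi_sum.sum(axis=1, keepdims=True), 1e-300)
    initial = gamma0 / n_subjects
    initial = np.maximum(initial, 1e-12)
    initial /= initial.sum()
    return GaussianHMM(means, cov, trans, initial)


def fit_hmm(
    X: np.ndarray,
    boundaries,
    K: int = 8,
    n_restarts: int = 3,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
    stay_prob: float = 0.9,
) -> tuple[GaussianHMM, list]:
    """Fit the group-level Gaussian HMM by EM with multiple restarts.

    ``X`` is the standardized concatenated series; ``boundaries`` the
    per-subject row ranges from :func:`standardize_and_concatenate`.  State
    means initialize from k-means on pooled volumes; the transition matrix
    from a ``stay_prob`` diagonal.  The log-likelihood is checked to be
    non-decreasing every iteration.  Returns the best-likelihood model and
    per-subject posteriors.
    """
    X = np.asarray(X, dtype=float)
    Ttot = X.shape[0]
    if Ttot < 10 * K:
        raise ValueError("need at least 10*K total volumes")
    lengths = {b - a for a, b in boundaries}
    batched = len(lengths) == 1
    if batched:
        T = lengths.pop()
        Xs = X.reshape(len(boundaries), T, X.shape[1])

    best: GaussianHMM | None = None
    best_ll = -np.inf
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + 7919 * r)
        km = KMeans(n_clusters=K, n_init=3, random_state=int(rng.integers(0, 2**31 - 1)))
        labels = km.fit_predict(X)
        means = km.cluster_centers_.copy()
        cov = np.cov(X, rowvar=False, ddof=0)
        cov += (1e-6 * np.trace(cov) / X.shape[1]) * np.eye(X.shape[1])
        if K == 1:
            trans = np.ones((1, 1))
        else:
            trans = stay_prob * np.eye(K) + (1 - stay_prob) / (K - 1) * (1 - np.eye(K))
        model = GaussianHMM(means, cov, trans, np.full(K, 1.0 / K))

        trace: list[float] = []
        prev = -np.inf
        for it in range(max_iter):
            if batched:
                gamma, xi_sum, gamma0, ll = _batch_e_step(model, Xs)
                gamma_all = gamma.reshape(Ttot, K)
            else:
                gamma_parts, xi_sum, gamma0 = [], np.zeros((K, K)), np.zeros(K)
                ll = 0.0
                for a, b in boundaries:
                    post = forward_backward(model, X[a:b])
                    gamma_parts.append(post.gamma)
                    xi_sum += post.xi.sum(axis=0)
                    gamma0 += post.gamma[0]
                    ll += post.loglik
                gamma_all = np.vstack(gamma_parts)
            trace.append(ll)
            if ll < prev - 1e-8 * max(1.0, abs(prev)):
                warnings.warn(f"EM log-likelihood decreased at iter {it}: {prev} -> {ll}")
            model = _m_step(X, gamma_all, xi_sum, gamma0, len(boundaries), rng)
            model.log_likelihood_trace = trace
            if np.isfinite(prev) and abs(ll - prev) < tol * max(1.0, abs(prev)):
                break
            prev = ll
        if trace[-1] > best_ll:
            best_ll = trace[-1]
            best = model
    assert best is not None
    posteriors = [forward_backward(best, X[a:b]) for a, b in boundaries]
    return best, posteriors


# ---------------------------------------------------------------------------
# Temporal metrics


def fractional_occupancy(gamma: np.ndarray) -> np.ndarray:
    """Mean posterior probability per state; sums to 1."""
    gamma = np.asarray(gamma, dtype=float)
    return gamma.mean(axis=0)


def switching_rate(path: np.ndarray) -> float:
    """Fraction of adjacent volume pairs at which the state changes."""
    path = np.asarray(path)
    if path.size < 2:
        raise ValueError("need at least 2 volumes")
    return float(np.mean(path[1:] != path[:-1]))


def mean_lifetimes(path: np.ndarray, K: int) -> np.ndarray:
    """Average dwell time per state in volumes (NaN for unvisited states)."""
    path = np.asarray(path)
    change = np.flatnonzero(np.diff(path)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [path.size]))
    out = np.full(K, np.nan)
    states = path[starts]
    lengths = ends - starts
    for k in range(K):
        sel = states == k
        if sel.any():
            out[k] = lengths[sel].mean()
    return out


def state_metrics(post: PosteriorStates, occupancy_from: str = "gamma") -> StateTemporalMetrics:
    """Per-subject temporal metrics from one subject's posteriors.

    ``occupancy_from`` selects soft ("gamma", default) or hard ("viterbi")
    fractional occupancy.
    """
    K = post.gamma.shape[1]
    if occupancy_from == "gamma":
        fo = fractional_occupancy(post.gamma)
    elif occupancy_from == "viterbi":
        fo = np.bincount(post.viterbi_path, minlength=K) / post.viterbi_path.size
    else:
        raise ValueError("occupancy_from must be 'gamma' or 'viterbi'")
    return StateTemporalMetrics(fo, switching_rate(post.viterbi_path), mean_lifetimes(post.viterbi_path, K))


# ---------------------------------------------------------------------------
# State matching across fits


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|) of two binary maps; 0 if both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("maps must have the same length")
    denom = a.sum() + b.sum()
    if denom == 0:
        logger.warning("both maps empty; Dice defined as 0")
        return 0.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def _binarize_map(m: np.ndarray, threshold_sd: float) -> np.ndarray:
    return np.abs(m) > threshold_sd * m.std(ddof=0)


def match_states(
    model_a: GaussianHMM,
    model_b: GaussianHMM,
    threshold_sd: float = 0.5,
    method: str = "dice",
) -> tuple[np.ndarray, np.ndarray]:
    """One-to-one state assignment between two fits (Hungarian algorithm).

    With ``method="dice"`` (default), mean activation maps are binarized at
    ``|activation| > threshold_sd`` standard deviations of each map and the
    summed Dice coefficient is maximized.  With ``method="correlation"``,
    the signed Pearson correlation between mean maps is maximized instead —
    preferable when anticorrelated activation patterns must not be
    confused, e.g. in parameter-recovery checks.  Returns ``(perm, sim)``
    where state ``k`` of ``model_a`` matches state ``perm[k]`` of
    ``model_b`` with similarity ``sim[k]``.
    """
    if model_a.n_states != model_b.n_states:
        raise ValueError("models must have the same number of states")
    K = model_a.n_states
    if method == "dice":
        Ba = [_binarize_map(m, threshold_sd) for m in model_a.means]
        Bb = [_binarize_map(m, threshold_sd) for m in model_b.means]
        sim = np.array([[dice_coefficient(Ba[i], Bb[j]) for j in range(K)] for i in range(K)])
    elif method == "correlation":
        sim = np.array(
            [[np.corrcoef(model_a.means[i], model_b.means[j])[0, 1] for j in range(K)] for i in range(K)]
        )
    else:
        raise ValueError("method must be 'dice' or 'correlation'")
    rows, cols = linear_sum_assignment(-sim)
    perm = np.empty(K, dtype=np.intp)
    perm[rows] = cols
    return perm, sim[rows, cols]


def dual_regression_stage1(group_maps: np.ndarray, data: np.ndarray) -> np.ndarray:
    """Stage-1 dual regression: per-volume least squares of data on maps.

    ``group_maps`` is (C, V) spatial maps, ``data`` (T, V); returns (T, C)
    subject-specific component timecourses.
    """
    maps = np.asarray(group_maps, dtype=float)
    data = np.asarray(data, dtype=float)
    C, V = maps.shape
    if C >= V:
        raise ValueError("need more voxels than components")
    if np.linalg.matrix_rank(maps) < C:
        raise ValueError("group maps are rank deficient")
    coef, *_ = np.linalg.lstsq(maps.T, data.T, rcond=None)
    return coef.T
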