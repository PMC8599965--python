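"""Group statistics: permutation GLM with max-statistic FWE correction,
PCA of fractional occupancy with the Kaiser rule, partial correlations,
moderation (interaction) tests, Steiger's Z, and the demographic-table
tests.

The permutation GLM uses the Freedman–Lane scheme: residuals of the reduced
(nuisance-only) model are permuted, the full model is refit to each permuted
dataset, and family-wise error corrected p-values come from the permutation
distribution of the maximum |t| across all outcomes and contrasts in the
call.  The observed data count as one permutation, so the smallest
attainable p is 1/(n_perm + 1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "GLMPermResult",
    "PCAResult",
    "permutation_glm",
    "pca_kaiser",
    "partial_correlation",
    "moderation_test",
    "steiger_z",
    "two_sample_t",
    "chi_squared_2x2",
    "discriminating_component",
]


@dataclass
class GLMPermResult:
    outcome: int
    contrast: int
    t: float
    p_unc: float
    p_fwe: float
    n_perm: int
    seed: int


@dataclass
class PCAResult:
    loadings: np.ndarray  # (K, n_retained), orthonormal columns
    scores: np.ndarray  # (n, n_retained), centered
    eigenvalues: np.ndarray  # all K eigenvalues of the correlation matrix
    variance_explained: np.ndarray  # fraction per retained component
    n_retained: int


def permutation_glm(
    Y: np.ndarray,
    X: np.ndarray,
    contrasts,
    n_perm: int = 10000,
    seed: int = 0,
) -> list[GLMPermResult]:
    """Freedman–Lane permutation GLM over a family of outcomes/contrasts.

    ``Y`` (n, q) outcomes, ``X`` (n, p) full design, ``contrasts`` a list of
    length-p vectors (columns with zero contrast weight act as nuisance for
    that contrast).  Degenerate outcomes (zero variance) are flagged with
    NaN statistics and excluded from the max-|t| family.
    """
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and Y.shape[1] > 1 and np.asarray(X).shape[0] != 1:
        Y = Y.T
    X = np.asarray(X, dtype=float)
    n, q = Y.shape
    p = X.shape[1]
    if n <= p:
        raise ValueError("need more observations than design columns")
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("design matrix is rank deficient")
    contrasts = [np.asarray(c, dtype=float) for c in np.atleast_2d(contrasts)]

    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    pinvX = np.linalg.pinv(X)
    XtX_inv = np.linalg.inv(X.T @ X)
    Mfull = np.eye(n) - X @ pinvX
    dof = n - p

    valid = Y.std(axis=0) > 1e-12
    if not valid.all():
        logger.warning("%d degenerate outcome(s) excluded from the family", int((~valid).sum()))

    t_obs = np.full((len(contrasts), q), np.nan)
    t_perm_all = []  # per contrast: (n_perm-1, q)
    for ci, c in enumerate(contrasts):
        w = c @ pinvX  # (n,)
        g = float(c @ XtX_inv @ c)
        nuis = np.flatnonzero(c == 0)
        Z = X[:, nuis]
        if Z.size:
            Rz = np.eye(n) - Z @ np.linalg.pinv(Z)
        else:
            Rz = np.eye(n)
        E = Rz @ Y  # reduced-model residuals

        def tstat(Ymat: np.ndarray) -> np.ndarray:
            num = w @ Ymat
            rss = ((Mfull @ Ymat) ** 2).sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                return num / np.sqrt(g * rss / dof)

        t_obs[ci] = tstat(Y)
        # permuted datasets, vectorized over permutations in chunks
        tp = np.empty((n_perm, q))
        chunk = max(1, int(5e6 / (n * q)))
        for s in range(0, n_perm, chunk):
            P = perms[s : s + chunk]
            Ep = E[P]  # (b, n, q)
            num = np.einsum("i,bij->bj", w, Ep)
            res = np.einsum("ki,bij->bkj", Mfull, Ep)
            rss = (res**2).sum(axis=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                tp[s : s + chunk] = num / np.sqrt(g * rss / dof)
        t_perm_all.append(tp)

    # FWE from the max |t| across valid outcomes and all contrasts
    abs_perm = np.stack([np.abs(tp[:, valid]) for tp in t_perm_all])  # (nc, n_perm, nv)
    max_perm = abs_perm.max(axis=(0, 2)) if valid.any() else np.zeros(n_perm)

    results = []
    for ci in range(len(contrasts)):
        for j in range(q):
            if not valid[j]:
                results.append(GLMPermResult(j, ci, np.nan, np.nan, np.nan, n_perm, seed))
                continue
            t = float(t_obs[ci, j])
            exceed = np.abs(t_perm_all[ci][:, j]) >= abs(t) - 1e-12
            p_unc = (1 + int(exceed.sum())) / (n_perm + 1)
            p_fwe = (1 + int((max_perm >= abs(t) - 1e-12).sum())) / (n_perm + 1)
            results.append(GLMPermResult(j, ci, t, p_unc, max(p_fwe, p_unc), n_perm, seed))
    return results


def pca_kaiser(F: np.ndarray) -> PCAResult:
    """PCA of the column correlation matrix, retaining eigenvalues > 1.

    Loadings are orthonormal eigenvectors, each oriented so its largest-
    magnitude entry is positive; scores are the standardized data projected
    on the loadings (centered by construction).
    """
    F = np.asarray(F, dtype=float)
    n, K = F.shape
    if n <= K:
        raise ValueError("need more rows than columns")
    sd = F.std(axis=0, ddof=1)
    if np.any(sd < 1e-12):
        raise ValueError(f"constant column {int(np.argmin(sd))}")
    Z = (F - F.mean(axis=0)) / sd
    corr = np.corrcoef(F, rowvar=False)
    evals, evecs = np.linalg.eigh(corr)
    order = np.argsort(evals)[::-1]
    evals = np.maximum(evals[order], 0.0)
    evecs = evecs[:, order]
    flip = np.sign(evecs[np.abs(evecs).argmax(axis=0), np.arange(K)])
    flip[flip == 0] = 1.0
    evecs = evecs * flip[None, :]
    n_keep = int((evals > 1.0).sum())
    loadings = evecs[:, :n_keep]
    return PCAResult(
        loadings=loadings,
        scores=Z @ loadings,
        eigenvalues=evals,
        variance_explained=evals[:n_keep] / K,
        n_retained=n_keep,
    )


def _residualize(v: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    n = v.shape[0]
    Z = np.ones((n, 1)) if covariates is None else np.column_stack([np.ones(n), covariates])
    beta, *_ = np.linalg.lstsq(Z, v, rcond=None)
    return v - Z @ beta


def partial_correlation(x, y, covariates=None) -> tuple[float, float, float]:
    """Correlation of x and y after removing covariates (plus intercept).

    Returns (r, t, p) with t = r·sqrt((n − k − 2)/(1 − r²)) on n − k − 2
    degrees of freedom, k the number of covariates.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    cov = None if covariates is None else np.column_stack([np.asarray(covariates, dtype=float)])
    k = 0 if cov is None else cov.shape[1]
    if n <= k + 2:
        raise ValueError("too few observations for the covariate count")
    rx = _residualize(x, cov)
    ry = _residualize(y, cov)
    if rx.std() < 1e-14 or ry.std() < 1e-14:
        raise ValueError("degenerate residuals")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - k - 2
    if abs(r) >= 1.0:
        return r, np.inf * np.sign(r), 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * sps.t.sf(abs(t), df)
    return r, float(t), float(p)


def moderation_test(y, x, group, covariates=None) -> tuple[float, float, float]:
    """Does the x→y slope differ by group?  F-test on the x×group term.

    Returns (delta_r2, F, p): the R² gain of the model with the interaction
    over the model without it, always >= 0.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    g = np.asarray(group, dtype=float)
    for lab in np.unique(g):
        if (g == lab).sum() < 3:
            raise ValueError("both groups need n >= 3")
    n = y.size
    base = [np.ones(n)]
    if covariates is not None:
        base.append(np.column_stack([np.asarray(covariates, dtype=float)]).reshape(n, -1))
    Xred = np.column_stack(base + [x, g])
    Xfull = np.column_stack([Xred, x * g])
    if np.linalg.matrix_rank(Xfull) < Xfull.shape[1]:
        raise ValueError("singular moderation design")

    def rss(X: np.ndarray) -> float:
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        return float(((y - X @ beta) ** 2).sum())

    tss = float(((y - y.mean()) ** 2).sum())
    rss_red, rss_full = rss(Xred), rss(Xfull)
    delta_r2 = max(0.0, (rss_red - rss_full) / tss)
    df2 = n - Xfull.shape[1]
    F = (rss_red - rss_full) / (rss_full / df2)
    p = float(sps.f.sf(F, 1, df2))
    return delta_r2, float(F), p


def steiger_z(r12: float, r13: float, r23: float, n: int) -> tuple[float, float]:
    """Steiger's (1980) Z for two dependent correlations sharing variable 1.

    Tests r12 against r13 given their mutual correlation r23; two-sided p.
    The sign of Z matches the sign of r12 − r13.
    """
    if n <= 3:
        raise ValueError("need n > 3")
    for r in (r12, r13, r23):
        if not -1.0 < r < 1.0:
            raise ValueError("correlations must lie strictly inside (-1, 1)")
    R = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1.0]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("correlation matrix is not positive semidefinite")
    psi = r23 * (1 - r12**2 - r13**2) - 0.5 * r12 * r13 * (1 - r12**2 - r13**2 - r23**2)
    s = psi / ((1 - r12**2) * (1 - r13**2))
    z12, z13 = np.arctanh(r12), np.arctanh(r13)
    Z = (z12 - z13) * np.sqrt((n - 3) / (2.0 - 2.0 * s))
    p = 2.0 * sps.norm.sf(abs(Z))
    return float(Z), float(p)


def two_sample_t(mean1, sd1, n1, mean2, sd2, n2, welch: bool = False) -> tuple[float, float]:
    """Two-sample t from summary statistics (pooled variance by default)."""
    res = sps.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def chi_squared_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, df=1, no continuity correction."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero table margin")
    chi2, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def discriminating_component(
    results: list[GLMPermResult],
    scores: np.ndarray,
    groups: np.ndarray,
    contrast_index: int = 0,
) -> tuple[int, float, np.ndarray]:
    """Select and orient the component that best separates the groups.

    Picks the outcome with the largest |t| for the given contrast, and flips
    its sign so the case group scores below controls (the convention in
    which a more abnormal profile is more negative).  Returns
    (component index, FWE p, oriented scores).
    """
    rel = [r for r in results if r.contrast == contrast_index and np.isfinite(r.t)]
    if not rel:
        raise ValueError("no valid outcome for this contrast")
    best = max(rel, key=lambda r: abs(r.t))
    sc = scores[:, best.outcome].copy()
    case = np.asarray(groups) == "case"
    if sc[case].mean() > sc[~case].mean():
        sc = -sc
    return best.outcome, best.p_fwe, sc
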