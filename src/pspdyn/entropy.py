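"""Sample entropy and multiscale entropy (MSE) of component timecourses.

Sample entropy is −ln(A/B), where B counts pairs of length-m templates whose
Chebyshev distance is within tolerance r and A counts the same for length
m+1; self-matches are excluded and both template sets are drawn from the
first T−m positions so the two counts are comparable (Richman–Moorman
convention).  Multiscale entropy coarse-grains the series by non-overlapping
window averaging and sums sample entropy over scales; the tolerance r is
fixed in units of the standardized original series and is NOT recomputed per
scale (Costa convention), so the decline of white-noise entropy across
scales is preserved.  A per-scale renormalization flag is available.

Subject-level MSE is the channel average of per-channel across-scale sums;
channels whose entropy is undefined at any scale (zero template matches) are
excluded from the average with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "EntropyParams",
    "coarse_grain",
    "sample_entropy",
    "multiscale_entropy",
    "subject_mse",
    "default_n_scales",
]


def default_n_scales(T: int) -> int:
    """4 scales for longer series (T >= 300), 3 otherwise."""
    return 4 if T >= 300 else 3


@dataclass
class EntropyParams:
    """m: template length; r: tolerance in standardized units; n_scales."""

    m: int = 1
    r: float = 0.35
    n_scales: int = 4
    renormalize_per_scale: bool = False

    def validate_for(self, T: int) -> None:
        if self.m < 1 or self.r <= 0 or self.n_scales < 1:
            raise ValueError("need m >= 1, r > 0, n_scales >= 1")
        if T // self.n_scales - self.m < 10:
            raise ValueError(
                f"series of length {T} too short for {self.n_scales} scales with m={self.m}"
            )


def coarse_grain(series: np.ndarray, tau: int) -> np.ndarray:
    """Non-overlapping window means of width tau; tau=1 is the identity."""
    x = np.asarray(series, dtype=float)
    if tau < 1:
        raise ValueError("tau must be >= 1")
    n = x.size // tau
    if n == 0:
        raise ValueError(f"series of length {x.size} too short for scale {tau}")
    return x[: n * tau].reshape(n, tau).mean(axis=1)


def sample_entropy(series: np.ndarray, m: int = 1, r: float = 0.35) -> float:
    """SampEn(m, r) = −ln(A/B); NaN (logged) when no template pair matches.

    Template pairs are counted over i < j with both indices restricted to
    the first T−m starting positions for both template lengths.
    """
    x = np.asarray(series, dtype=float)
    T = x.size
    if T < m + 2:
        raise ValueError(f"series of length {T} too short for m={m}")
    n = T - m  # number of templates at both lengths
    # Chebyshev distances between length-(m+1) templates starting at 0..n-1;
    # the length-m distance is the max over the first m coordinates.
    idx = np.arange(n)[:, None] + np.arange(m + 1)[None, :]
    templ = x[idx]  # (n, m+1)
    d = np.abs(templ[:, None, :] - templ[None, :, :])  # (n, n, m+1)
    dm = d[:, :, :m].max(axis=2)
    dm1 = d.max(axis=2)
    iu = np.triu_indices(n, k=1)
    B = int(np.count_nonzero(dm[iu] <= r))
    A = int(np.count_nonzero(dm1[iu] <= r))
    if A == 0 or B == 0:
        logger.warning("sample entropy undefined (A=%d, B=%d); returning NaN", A, B)
        return float("nan")
    return float(-np.log(A / B))


def multiscale_entropy(series: np.ndarray, params: EntropyParams) -> tuple[np.ndarray, float]:
    """Per-scale sample entropies and their sum over scales 1..n_scales."""
    x = np.asarray(series, dtype=float)
    params.validate_for(x.size)
    vals = np.empty(params.n_scales)
    for s in range(1, params.n_scales + 1):
        cg = coarse_grain(x, s)
        if params.renormalize_per_scale:
            sd = cg.std(ddof=0)
            if sd < 1e-12:
                vals[s - 1] = np.nan
                continue
            cg = cg / sd
        vals[s - 1] = sample_entropy(cg, params.m, params.r)
    return vals, float(vals.sum())


def subject_mse(channels: np.ndarray, params: EntropyParams) -> float:
    """Channel-averaged MSE for one subject.

    ``channels`` is (T, C) standardized timecourses.  Channels with an
    undefined entropy at any scale are skipped (count logged); if every
    channel is undefined this is an error.
    """
    X = np.asarray(channels, dtype=float)
    sums = np.array([multiscale_entropy(X[:, c], params)[1] for c in range(X.shape[1])])
    ok = np.isfinite(sums)
    if not ok.any():
        raise ValueError("MSE undefined for every channel")
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("MSE undefined for %d of %d channels; averaging the rest", n_bad, ok.size)
    return float(sums[ok].mean())
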