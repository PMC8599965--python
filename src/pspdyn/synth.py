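"""Synthetic two-group cohort generator with planted dynamic-network effects.

Generates component timecourses from a ground-truth multivariate Gaussian
hidden Markov model, together with clinical severity scores, structural
covariates and motion/QC metrics whose statistical structure is known by
construction.  Every downstream stage of the pipeline (state inference,
entropy, graphs, group statistics) therefore has an answer it can be checked
against.

The generative model mirrors the family assumed by the analysis model:
K latent states with Markov dynamics, Gaussian emissions with state-specific
means and one covariance shared across states.  Patients ("case" group)
receive transition matrices exponentially tilted so that stationary mass
moves from designated subcortical/posterior states toward designated
executive/frontoparietal states — the direction of the occupancy shift seen
in progressive supranuclear palsy.  Severity (a PSPRS-like score) is a noisy
linear function of each case's true executive-minus-subcortical occupancy
contrast, so greater severity accompanies a more abnormal occupancy profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

logger = logging.getLogger(__name__)

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "SubjectTimeseries",
    "SyntheticCohort",
    "make_state_basis",
    "stationary_distribution",
    "sample_transition_matrix",
    "simulate_subject",
    "simulate_covariates",
    "simulate_qc_metrics",
    "simulate_motion_trace",
    "simulate_cohort",
    "colored_noise",
    "default_state_sets",
]

QC_METRIC_NAMES = ["max_spike_pct", "median_spike_pct", "max_fd", "max_dvars"]


@dataclass
class CohortSpec:
    """Parameters of a simulated two-group cohort.

    Defaults emulate the larger of the two cohorts the pipeline targets:
    22 controls vs 24 patients, 30 component channels, 305 volumes at
    TR = 2 s, 8 latent states.  ``occupancy_shift`` is the total stationary
    mass moved from the subcortical state set to the executive state set in
    patients; ``severity_loading`` the correlation linking true occupancy to
    the severity score among patients.
    """

    n_control: int = 22
    n_case: int = 24
    n_channels: int = 30
    n_timepoints: int = 305
    tr: float = 2.0
    n_states: int = 8
    occupancy_shift: float = 0.1
    severity_loading: float = 0.6
    structural_loading: float = 0.3
    noise_sd: float = 0.5
    stay_prob: float = 0.8
    # Dirichlet concentration for mild between-subject transition variability
    subject_jitter_kappa: float = 600.0
    outlier_fraction: float = 0.0
    mismatch: str | None = None  # None | "ar1" | "per_state_cov"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 2 or self.n_case < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_channels < self.n_states:
            raise ValueError("n_channels must be >= n_states")
        if self.n_timepoints < 50:
            raise ValueError("n_timepoints must be >= 50")
        if not 0.0 <= self.occupancy_shift:
            raise ValueError("occupancy_shift must be >= 0")
        if self.mismatch not in (None, "ar1", "per_state_cov"):
            raise ValueError(f"unknown mismatch mode {self.mismatch!r}")


@dataclass
class SubjectTimeseries:
    """One subject's component timecourses, time along axis 0."""

    data: np.ndarray  # (T, C)
    tr: float
    subject_id: str
    group: str  # "control" | "case"

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]


@dataclass
class GroundTruth:
    state_means: np.ndarray  # (K, C)
    shared_covariance: np.ndarray  # (C, C)
    per_subject_transition: list  # of (K, K)
    per_subject_hidden_path: list  # of (T,)
    true_occupancy: np.ndarray  # (n, K) empirical occupancy of hidden paths
    executive_states: tuple
    subcortical_states: tuple


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    timeseries: list  # of SubjectTimeseries
    covariates: pd.DataFrame
    qc: pd.DataFrame
    motion: list = field(default_factory=list)  # per-subject (T, 6) traces
    ground_truth: GroundTruth | None = None

    @property
    def groups(self) -> np.ndarray:
        return self.covariates["group"].to_numpy()


def default_state_sets(K: int) -> tuple[tuple, tuple]:
    """Designate executive (first quarter) and subcortical (last quarter)
    state index sets; disjoint for any K >= 2."""
    q = max(1, K // 4)
    return tuple(range(q)), tuple(range(K - q, K))


def make_state_basis(K: int, C: int, seed: int, max_abs_corr: float = 0.3) -> np.ndarray:
    """Random unit-norm state mean maps with low pairwise correlation.

    Rows play the role of mean activation patterns over C channels.  Built
    from the Q factor of a random Gaussian matrix (rows orthonormal, hence
    near-zero centered correlations); resampled until every pairwise row
    correlation is below ``max_abs_corr`` in absolute value.
    """
    if K > C:
        raise ValueError(f"need K <= C, got K={K} > C={C}")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        q, _ = np.linalg.qr(rng.standard_normal((C, K)))
        basis = q.T  # (K, C), orthonormal rows
        if K == 1 or C < 4:
            # with so few channels any two centered maps correlate near +-1;
            # only unit norm is enforceable
            return basis
        corr = np.corrcoef(basis)
        off = np.abs(corr[~np.eye(K, dtype=bool)])
        if off.max() <= max_abs_corr:
            return basis
    raise RuntimeError("could not draw a basis satisfying the correlation bound")


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (left eigenvector)."""
    vals, vecs = np.linalg.eig(P.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    pi = np.real(vecs[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def _tilt(base: np.ndarray, eta: float, sign: np.ndarray) -> np.ndarray:
    W = base * np.exp(eta * sign)[None, :]
    return W / W.sum(axis=1, keepdims=True)


def sample_transition_matrix(
    base: np.ndarray,
    group: str,
    delta: float,
    seed: int,
    executive_states: tuple | None = None,
    subcortical_states: tuple | None = None,
    jitter_kappa: float | None = None,
) -> np.ndarray:
    """Group-specific transition matrix with a planted occupancy shift.

    Controls receive ``base`` (optionally jittered).  Cases receive ``base``
    exponentially tilted toward the executive states and away from the
    subcortical states, with the tilt strength solved so the stationary mass
    on the executive set exceeds that of ``base`` by ``delta`` (the mass on
    the subcortical set drops by approximately the same amount).  A Dirichlet
    row perturbation with concentration ``jitter_kappa`` adds mild
    between-subject variability.
    """
    base = np.asarray(base, dtype=float)
    K = base.shape[0]
    if not np.allclose(base.sum(axis=1), 1.0, atol=1e-10):
        raise ValueError("base transition matrix must be row-stochastic")
    if executive_states is None or subcortical_states is None:
        executive_states, subcortical_states = default_state_sets(K)
    if set(executive_states) & set(subcortical_states):
        raise ValueError("executive and subcortical state sets must be disjoint")
    rng = np.random.default_rng(seed)

    if group == "case" and delta > 0:
        sign = np.zeros(K)
        sign[list(executive_states)] = 1.0
        sign[list(subcortical_states)] = -1.0
        exec_idx = list(executive_states)
        base_mass = stationary_distribution(base)[exec_idx].sum()

        def gap(eta: float) -> float:
            return stationary_distribution(_tilt(base, eta, sign))[exec_idx].sum() - base_mass - delta

        eta_hi = 50.0
        if gap(eta_hi) < 0:
            raise ValueError(f"occupancy shift delta={delta} not attainable for this base matrix")
        eta = brentq(gap, 0.0, eta_hi, xtol=1e-12)
        P = _tilt(base, eta, sign)
    else:
        P = base.copy()

    if jitter_kappa is not None and np.isfinite(jitter_kappa):
        P = np.vstack([rng.dirichlet(jitter_kappa * row) for row in P])
        P = P / P.sum(axis=1, keepdims=True)
    return P


def simulate_subject(
    transition: np.ndarray,
    state_means: np.ndarray,
    covariance: np.ndarray,
    T: int,
    seed: int,
    initial: np.ndarray | None = None,
    mismatch: str | None = None,
    ar_coef: float = 0.4,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a hidden state path and Gaussian emissions.

    Returns ``(X, path)`` with ``X`` of shape (T, C).  ``mismatch`` enables
    deliberate departures from the analysis model for robustness checks:
    ``"ar1"`` applies AR(1) filtering to the noise, ``"per_state_cov"``
    rescales the covariance per state.
    """
    transition = np.asarray(transition, dtype=float)
    K, C = state_means.shape
    rng = np.random.default_rng(seed)
    try:
        L = np.linalg.cholesky(covariance)
    except np.linalg.LinAlgError as e:
        raise ValueError("covariance must be positive definite") from e
    if initial is None:
        initial = stationary_distribution(transition)

    path = np.empty(T, dtype=np.intp)
    path[0] = rng.choice(K, p=initial)
    # draw the whole chain with one uniform per step against transition CDFs
    cdf = np.cumsum(transition, axis=1)
    u = rng.random(T)
    for t in range(1, T):
        path[t] = np.searchsorted(cdf[path[t - 1]], u[t])

    eps = rng.standard_normal((T, C))
    if mismatch == "ar1":
        for t in range(1, T):
            eps[t] = ar_coef * eps[t - 1] + np.sqrt(1 - ar_coef**2) * eps[t]
    noise = eps @ L.T
    if mismatch == "per_state_cov":
        scale = 1.0 + 0.5 * (np.arange(K) / max(K - 1, 1) - 0.5)
        noise = noise * scale[path][:, None]
    X = state_means[path] + noise
    return X, path


def _planted_score(z: np.ndarray, loading: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance score correlated ``loading`` with standardized ``z``."""
    eps = rng.standard_normal(z.shape[0])
    return loading * z + np.sqrt(max(0.0, 1.0 - loading**2)) * eps


def simulate_covariates(
    true_occupancy: np.ndarray,
    groups: np.ndarray,
    severity_loading: float,
    structural_loading: float,
    seed: int,
    executive_states: tuple | None = None,
    subcortical_states: tuple | None = None,
) -> pd.DataFrame:
    """Clinical and structural covariates with planted associations.

    Severity (PSPRS-like, cases only) loads positively on the case's true
    executive-minus-subcortical occupancy contrast: patients spending more
    time in executive states and less in subcortical states score as more
    severe.  The subcortical volume proxy loads positively on subcortical
    occupancy across all subjects; the frontal thickness proxy carries no
    planted loading.  Age ~ N(68, 8), sex ~ Bernoulli(0.5).
    """
    if not -1.0 <= severity_loading <= 1.0 or not -1.0 <= structural_loading <= 1.0:
        raise ValueError("loadings must lie in [-1, 1]")
    occ = np.asarray(true_occupancy, dtype=float)
    n, K = occ.shape
    groups = np.asarray(groups)
    if executive_states is None or subcortical_states is None:
        executive_states, subcortical_states = default_state_sets(K)
    rng = np.random.default_rng(seed)

    case = groups == "case"
    contrast = occ[:, list(executive_states)].sum(1) - occ[:, list(subcortical_states)].sum(1)
    sub_occ = occ[:, list(subcortical_states)].sum(1)

    severity = np.full(n, np.nan)
    if case.sum() >= 2:
        z = (contrast[case] - contrast[case].mean()) / max(contrast[case].std(ddof=0), 1e-12)
        severity[case] = 34.9 + 14.0 * _planted_score(z, severity_loading, rng)

    zs = (sub_occ - sub_occ.mean()) / max(sub_occ.std(ddof=0), 1e-12)
    subcortical_vol = 55.0 + 6.0 * _planted_score(zs, structural_loading, rng)
    frontal_thickness = 2.5 + 0.15 * rng.standard_normal(n)

    return pd.DataFrame(
        {
            "subject_id": [f"sub-{i:03d}" for i in range(n)],
            "group": groups,
            "age": 68.0 + 8.0 * rng.standard_normal(n),
            "sex": rng.integers(0, 2, size=n),
            "severity": severity,
            "subcortical_vol": subcortical_vol,
            "frontal_thickness": frontal_thickness,
        }
    )


def simulate_qc_metrics(n: int, outlier_fraction: float, seed: int) -> pd.DataFrame:
    """Four per-subject quality indices with optional planted outliers.

    Non-outlier values are drawn tightly around typical magnitudes; planted
    outliers are inflated by four reference standard deviations on every
    metric, so they exceed mean + 1 SD of the clean distribution.
    """
    if not 0.0 <= outlier_fraction < 0.5:
        raise ValueError("outlier_fraction must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    centers = np.array([3.0, 1.0, 0.3, 1.2])
    scales = np.array([0.6, 0.25, 0.08, 0.2])
    vals = np.abs(centers[None, :] + scales[None, :] * rng.standard_normal((n, 4)))
    n_out = int(np.floor(outlier_fraction * n))
    if n_out:
        idx = rng.choice(n, size=n_out, replace=False)
        vals[idx] += 4.0 * scales[None, :]
    df = pd.DataFrame(vals, columns=QC_METRIC_NAMES)
    df.insert(0, "subject_id", [f"sub-{i:03d}" for i in range(n)])
    return df


def simulate_motion_trace(T: int, seed: int, scale: float = 0.02, spike_rate: float = 0.02) -> np.ndarray:
    """Six rigid-body motion parameters (3 translations mm, 3 rotations rad)
    as a slow random walk with occasional spikes."""
    rng = np.random.default_rng(seed)
    steps = scale * rng.standard_normal((T, 6))
    steps[:, 3:] *= 0.01  # rotations in radians are much smaller
    spikes = rng.random(T) < spike_rate
    steps[spikes] *= 15.0
    trace = np.cumsum(steps, axis=0)
    trace[0] = 0.0
    return trace


def colored_noise(T: int, exponent: float, seed: int) -> np.ndarray:
    """Standardized 1/f^exponent noise (exponent 0 = white, 1 = pink)."""
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(T)
    f = np.fft.rfftfreq(T)
    amp = np.ones_like(f)
    amp[1:] = f[1:] ** (-exponent / 2.0)
    amp[0] = 0.0
    x = np.fft.irfft(np.fft.rfft(white) * amp, n=T)
    return (x - x.mean()) / x.std()


def simulate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a complete two-group cohort from a :class:`CohortSpec`.

    Deterministic given ``spec.seed``: all subordinate random streams are
    spawned from one root generator.
    """
    rng = np.random.default_rng(spec.seed)
    K, C, T = spec.n_states, spec.n_channels, spec.n_timepoints
    n = spec.n_control + spec.n_case
    exec_set, sub_set = default_state_sets(K)

    def sub_seed() -> int:
        return int(rng.integers(0, 2**31 - 1))

    means = make_state_basis(K, C, sub_seed())
    cov = spec.noise_sd**2 * np.eye(C)
    base = spec.stay_prob * np.eye(K) + (1 - spec.stay_prob) / (K - 1) * (1 - np.eye(K))

    groups = np.array(["control"] * spec.n_control + ["case"] * spec.n_case)
    timeseries, transitions, paths, motion = [], [], [], []
    occ = np.zeros((n, K))
    for i, g in enumerate(groups):
        P = sample_transition_matrix(
            base, g, spec.occupancy_shift, sub_seed(), exec_set, sub_set,
            jitter_kappa=spec.subject_jitter_kappa,
        )
        X, path = simulate_subject(P, means, cov, T, sub_seed(), mismatch=spec.mismatch)
        occ[i] = np.bincount(path, minlength=K) / T
        # one latent per-subject motion level drives trace amplitude and
        # FD-coupled signal artifacts, so the four QC indices co-vary
        art_rng = np.random.default_rng(sub_seed())
        scale = 0.02 * np.exp(0.5 * art_rng.standard_normal())
        trace = simulate_motion_trace(T, sub_seed(), scale=scale)
        d = np.abs(np.diff(trace, axis=0))
        fd = np.concatenate(([0.0], d[:, :3].sum(1) + 50.0 * d[:, 3:].sum(1)))
        X = X + 2.0 * fd[:, None] * art_rng.standard_normal(C)[None, :]
        timeseries.append(SubjectTimeseries(X, spec.tr, f"sub-{i:03d}", g))
        transitions.append(P)
        paths.append(path)
        motion.append(trace)

    covariates = simulate_covariates(
        occ, groups, spec.severity_loading, spec.structural_loading, sub_seed(),
        exec_set, sub_set,
    )
    qc = simulate_qc_metrics(n, spec.outlier_fraction, sub_seed())
    gt = GroundTruth(means, cov, transitions, paths, occ, exec_set, sub_set)
    return SyntheticCohort(spec, timeseries, covariates, qc, motion, gt)
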