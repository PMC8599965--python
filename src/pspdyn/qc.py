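"""Motion and data-quality metrics, the 1-SD exclusion rule, and the
composite motion covariate.

Four worse-when-larger indices summarize each subject's scan quality:
maximum and median spike percentage (fraction of volumes exceeding motion or
signal-change thresholds), maximum framewise displacement (FD, mm) and
maximum DVARS (RMS volume-to-volume signal change).  A subject is excluded
when any index exceeds the reference sample mean + 1 SD; the composite
motion covariate is the within-subject average of the four z-scored indices.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "framewise_displacement",
    "dvars",
    "spike_percentage",
    "qc_metrics_from_traces",
    "exclusion_rule",
    "motion_covariate",
    "QC_METRIC_NAMES",
]

QC_METRIC_NAMES = ["max_spike_pct", "median_spike_pct", "max_fd", "max_dvars"]


def framewise_displacement(trace: np.ndarray, head_radius: float = 50.0) -> np.ndarray:
    """Per-volume FD: sum of |Δtranslation| plus head_radius·|Δrotation|.

    ``trace`` is (T, 6): three translations in mm then three rotations in
    radians.  FD at the first volume is 0.
    """
    tr = np.asarray(trace, dtype=float)
    if tr.ndim != 2 or tr.shape[1] != 6 or not np.all(np.isfinite(tr)):
        raise ValueError("trace must be a finite (T, 6) array")
    d = np.abs(np.diff(tr, axis=0))
    fd = d[:, :3].sum(axis=1) + head_radius * d[:, 3:].sum(axis=1)
    return np.concatenate(([0.0], fd))


def dvars(series: np.ndarray) -> np.ndarray:
    """RMS across channels of the volume-to-volume difference; first volume 0.

    ``series`` is (T, C), time along axis 0.
    """
    X = np.asarray(series, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least 2 volumes")
    d = np.diff(X, axis=0)
    return np.concatenate(([0.0], np.sqrt((d**2).mean(axis=1))))


def spike_percentage(fd: np.ndarray, dv: np.ndarray, fd_thresh: float = 0.5, dvars_thresh: float | None = None) -> float:
    """Percentage of volumes with FD or DVARS above threshold.

    The DVARS threshold defaults to 1.5x the series median DVARS.
    """
    if fd_thresh <= 0:
        raise ValueError("thresholds must be positive")
    fd = np.asarray(fd, dtype=float)
    dv = np.asarray(dv, dtype=float)
    if dvars_thresh is None:
        dvars_thresh = 1.5 * np.median(dv[1:]) if dv.size > 1 else np.inf
    if dvars_thresh <= 0:
        raise ValueError("thresholds must be positive")
    spike = (fd > fd_thresh) | (dv > dvars_thresh)
    return float(100.0 * spike.mean())


def qc_metrics_from_traces(motion_traces, series_list, fd_thresh: float = 0.5) -> pd.DataFrame:
    """Compute the four QC indices for each subject from motion traces and
    timecourses.

    Spike percentage is evaluated per channel (FD spikes are shared, the
    signal-change series is channel-specific), and summarized as the
    maximum and the median over channels — channels standing in for the
    voxelwise units of the original spike indices.
    """
    rows = []
    for i, (trace, s) in enumerate(zip(motion_traces, series_list)):
        data = np.asarray(s, dtype=float) if isinstance(s, (np.ndarray, list)) else s.data
        fd = framewise_displacement(trace)
        dv = dvars(data)
        per_channel = []
        for c in range(data.shape[1]):
            dvc = np.concatenate(([0.0], np.abs(np.diff(data[:, c]))))
            per_channel.append(spike_percentage(fd, dvc, fd_thresh, 3.0 * np.median(dvc[1:])))
        rows.append(
            {
                "subject_id": getattr(s, "subject_id", f"sub-{i:03d}"),
                "max_spike_pct": float(np.max(per_channel)),
                "median_spike_pct": float(np.median(per_channel)),
                "max_fd": float(fd.max()),
                "max_dvars": float(dv.max()),
            }
        )
    return pd.DataFrame(rows)


def exclusion_rule(metrics: pd.DataFrame, reference: pd.DataFrame | None = None) -> pd.DataFrame:
    """Flag subjects exceeding mean + 1 SD on any QC index.

    Thresholds come from ``reference`` when given (an external reference
    sample's metric table), otherwise from the supplied table itself.
    Returns the table with an ``excluded`` flag and a ``reason`` column
    naming the offending metrics.  Sample SD uses the n−1 denominator.
    """
    if len(metrics) < 3 and reference is None:
        raise ValueError("need at least 3 subjects to set thresholds")
    ref = metrics if reference is None else reference
    out = metrics.copy()
    reasons = [[] for _ in range(len(metrics))]
    flagged = np.zeros(len(metrics), dtype=bool)
    for m in QC_METRIC_NAMES:
        thresh = ref[m].mean() + ref[m].std(ddof=1)
        over = metrics[m].to_numpy() > thresh
        flagged |= over
        for i in np.flatnonzero(over):
            reasons[i].append(f"{m}>{thresh:.3g}")
    out["excluded"] = flagged
    out["reason"] = [";".join(r) for r in reasons]
    if flagged.any():
        logger.info("excluded %d of %d subjects", int(flagged.sum()), len(metrics))
    return out


def motion_covariate(metrics: pd.DataFrame) -> pd.Series:
    """Composite motion covariate: mean of the four z-scored indices.

    Zero-variance metrics are dropped (logged).  The covariate has sample
    mean 0 by construction.
    """
    if len(metrics) < 2:
        raise ValueError("need at least 2 subjects")
    cols = []
    for m in QC_METRIC_NAMES:
        sd = metrics[m].std(ddof=1)
        if sd < 1e-12:
            logger.warning("metric %s has zero variance; dropped from covariate", m)
            continue
        cols.append((metrics[m] - metrics[m].mean()) / sd)
    if not cols:
        # identical subjects: every metric constant, covariate is all zero
        logger.warning("all QC metrics constant; motion covariate is zero")
        return pd.Series(np.zeros(len(metrics)), name="motion")
    cov = pd.concat(cols, axis=1).mean(axis=1)
    cov.name = "motion"
    return cov
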