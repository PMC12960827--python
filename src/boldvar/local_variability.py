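"""Local BOLD signal variability.

Local variability of a regional timeseries is the root mean squared successive
difference (rMSSD),

    rMSSD = sqrt( sum_{i=1}^{n-1} (x_{i+1} - x_i)^2 / (n - 1) ),

the square-root of the mean squared first difference (MSSD is on the scale of a
variance, rMSSD of a standard deviation). Runs are first mean-centered to a
whole-brain mean of zero -- a single scalar shift that leaves rMSSD untouched
but puts samples on a common baseline. Lag-1/lag-2 autocorrelation maps and
group-map utilities (averaging, z-scoring) live here too.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .containers import ParcellatedRun, RegionalMap

__all__ = [
    "center_whole_brain",
    "rmssd",
    "rmssd_map",
    "lag_autocorrelation",
    "group_map",
    "zscore_map",
]


def center_whole_brain(run: ParcellatedRun) -> ParcellatedRun:
    """Subtract the grand mean over all regions and timepoints."""
    if run.data.size == 0:
        raise ValueError("empty run")
    return run.with_data(run.data - run.data.mean())


def rmssd(series: np.ndarray) -> float:
    """Root mean squared successive difference of a 1-D series."""
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("rMSSD needs at least 2 timepoints")
    d = np.diff(x)
    return float(np.sqrt(np.mean(d * d)))


def rmssd_map(run: ParcellatedRun, parcellation_ref: str = "synthetic") -> RegionalMap:
    """Per-region rMSSD of a (typically whole-brain-centered) run."""
    d = np.diff(run.data, axis=1)
    vals = np.sqrt(np.mean(d * d, axis=1))
    return RegionalMap(
        values=vals,
        parcellation_ref=parcellation_ref,
        label=f"rmssd:{run.subject_id}:{run.run_label}",
    )


def lag_autocorrelation(series: np.ndarray, lag: int = 1) -> float:
    """Product-moment correlation between the series and its ``lag``-shifted copy."""
    x = np.asarray(series, dtype=float).ravel()
    if lag < 1:
        raise ValueError("lag must be a positive integer")
    if x.size <= lag + 2:
        raise ValueError("series too short for this lag")
    a, b = x[:-lag], x[lag:]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("autocorrelation undefined for a zero-variance series")
    return float(stats.pearsonr(a, b).statistic)


def lag_autocorrelation_map(run: ParcellatedRun, lag: int = 1,
                            parcellation_ref: str = "synthetic") -> RegionalMap:
    vals = [lag_autocorrelation(row, lag) for row in run.data]
    return RegionalMap(
        values=np.asarray(vals),
        parcellation_ref=parcellation_ref,
        label=f"lag{lag}-autocorr:{run.subject_id}",
    )


def group_map(per_subject_maps: list[RegionalMap]) -> RegionalMap:
    """Element-wise mean across subjects' regional maps."""
    if not per_subject_maps:
        raise ValueError("need at least one map")
    ref = per_subject_maps[0].parcellation_ref
    n = len(per_subject_maps[0])
    rows = []
    for m in per_subject_maps:
        if len(m) != n or m.parcellation_ref != ref:
            raise ValueError("maps must share a parcellation")
        rows.append(m.values)
    return RegionalMap(
        values=np.mean(rows, axis=0),
        parcellation_ref=ref,
        label="group:" + per_subject_maps[0].label,
    )


def zscore_map(m: RegionalMap) -> RegionalMap:
    """Z-score across regions using the population SD (divide by R)."""
    sd = m.values.std()  # ddof=0 by design; documented choice
    if sd == 0:
        raise ValueError("cannot z-score a constant map")
    return RegionalMap(
        values=(m.values - m.values.mean()) / sd,
        parcellation_ref=m.parcellation_ref,
        label="z:" + m.label,
        standardized=True,
    )
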