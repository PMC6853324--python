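"""Cumulative log viral load (cVL2).

cVL2 measures a patient's cumulative exposure to detectable viremia while on
antiretroviral therapy: the trapezoidal time-integral, in log10 copy-year/mL,
of log10(VL / detection limit) over visits where the viral load exceeds the
detection threshold.  The default threshold is 400 copies/mL, above the 50
copies/mL assay limit, so that transient "blips" (50-400 copies/mL) do not
contribute.

Visits with a missing viral load contribute no node to the trapezoid: the
integral bridges the adjacent observed-VL visits with a correspondingly longer
inter-visit duration.  Every visit -- including missing-VL visits -- still
receives a running cumulative value (the cumulative at the most recent
observed node at or before that visit), because downstream regression models
need a per-visit covariate.  cVL2 is 0 at baseline by definition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_DETECTION_LIMIT = 400.0

__all__ = [
    "DEFAULT_DETECTION_LIMIT",
    "log_excess",
    "cvl2_increment",
    "compute_cvl2_series",
    "compute_cvl2",
]


def log_excess(viral_load, detection_limit: float = DEFAULT_DETECTION_LIMIT):
    """log10(viral_load / detection_limit), floored at 0.

    Values at or below the detection limit contribute nothing: the metric is
    the area *above* the limit of detection, and negative contributions would
    make the cumulative non-monotone.

    Parameters
    ----------
    viral_load : float or array-like
        Raw viral load in copies/mL; must be strictly positive.
    detection_limit : float
        Threshold in copies/mL (default 400).

    Returns
    -------
    float or ndarray
        log10 decades above the detection limit, >= 0.
    """
    vl = np.asarray(viral_load, dtype=float)
    if np.any(vl <= 0) or not np.all(np.isfinite(vl)):
        raise ValueError("viral load must be strictly positive and finite")
    out = np.maximum(np.log10(vl / detection_limit), 0.0)
    return float(out) if np.isscalar(viral_load) else out


def cvl2_increment(
    t_prev: float,
    t_curr: float,
    v_prev: float,
    v_curr: float,
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
) -> float:
    """Trapezoid increment between two observed-VL visits.

    (t_curr - t_prev) * (log_excess(v_curr) + log_excess(v_prev)) / 2, in
    log10 copy-year/mL.  When intermediate visits have missing VL, the pair
    passed here simply spans a longer inter-visit duration.
    """
    if not t_curr > t_prev:
        raise ValueError(f"visit times must increase: {t_prev!r} -> {t_curr!r}")
    lo = log_excess(v_prev, detection_limit)
    hi = log_excess(v_curr, detection_limit)
    return (t_curr - t_prev) * (lo + hi) / 2.0


def compute_cvl2_series(
    times,
    viral_loads,
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
) -> np.ndarray:
    """Running cVL2 at every visit of one patient.

    Parameters
    ----------
    times : array-like
        Visit times in years, strictly increasing; the first entry is the
        baseline visit.
    viral_loads : array-like
        Raw viral loads in copies/mL; NaN marks a missing measurement.
        Missing visits are excluded as trapezoid nodes but still receive the
        running cumulative value at or before their time.

    Returns
    -------
    ndarray
        cvl2 per visit, same length as ``times``; 0 at baseline,
        non-decreasing.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(viral_loads, dtype=float)
    if t.size == 0:
        raise ValueError("patient has no visits (baseline visit required)")
    if t.shape != v.shape:
        raise ValueError("times and viral_loads must have equal length")
    if np.any(np.diff(t) <= 0):
        raise ValueError("visit times must be strictly increasing")

    observed = ~np.isnan(v)
    cvl2 = np.zeros_like(t)
    if observed.sum() >= 2:
        t_obs = t[observed]
        ex = log_excess(v[observed], detection_limit)
        incr = np.diff(t_obs) * (ex[1:] + ex[:-1]) / 2.0
        cum_obs = np.concatenate([[0.0], np.cumsum(incr)])
        # each visit takes the cumulative at the latest observed node <= its time
        idx = np.searchsorted(t_obs, t, side="right") - 1
        cvl2 = np.where(idx >= 0, cum_obs[np.clip(idx, 0, None)], 0.0)
    return cvl2


def compute_cvl2(
    visits: pd.DataFrame,
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
) -> pd.DataFrame:
    """Per-visit cVL2 for a long-format visit table.

    ``visits`` needs columns patient_id, time_on_art, viral_load (NaN =
    missing).  Returns a DataFrame (patient_id, time_on_art, cvl2) aligned
    with the input row order within each patient.
    """
    required = {"patient_id", "time_on_art", "viral_load"}
    missing_cols = required - set(visits.columns)
    if missing_cols:
        raise ValueError(f"visit table lacks columns: {sorted(missing_cols)}")
    parts = []
    for pid, grp in visits.groupby("patient_id", sort=False):
        grp = grp.sort_values("time_on_art")
        cvl2 = compute_cvl2_series(
            grp["time_on_art"].to_numpy(),
            grp["viral_load"].to_numpy(),
            detection_limit,
        )
        parts.append(
            pd.DataFrame(
                {
                    "patient_id": pid,
                    "time_on_art": grp["time_on_art"].to_numpy(),
                    "cvl2": cvl2,
                }
            )
        )
    return pd.concat(parts, ignore_index=True)
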