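"""Stratified posterior-predictive summaries and model-comparison tables.

Predicted trajectories (slope family) or threshold probabilities (asymptote
family) are computed per posterior draw and patient over a time grid, then
summarized per covariate stratum as the median with a 95% prediction
interval taken across patients x draws.  For slope models the draw-level
predictions include fresh residual noise, so the intervals are genuine
prediction intervals, not credible intervals of the mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import CohortTable
from .diagnostics import compare_cdic
from .inference import FitResult
from .models import time_basis, time_basis_names


@dataclass
class StrataSpec:
    """Patient strata on a raw-scale baseline variable.

    ``cutpoints`` are the ordered internal boundaries; ``upper_inclusive``
    makes intervals (lo, hi] (the convention for CD4 bands like <=100,
    101-200, >200).
    """

    variable: str  # baseline_cd4 | sex | age | baseline_log_vl
    cutpoints: tuple = ()
    labels: tuple | None = None
    upper_inclusive: bool = True

    def assign(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        if self.variable == "sex":
            labels = self.labels or ("male", "female")
            return np.where(v > 0.5, labels[1], labels[0])
        cuts = list(self.cutpoints)
        idx = np.searchsorted(cuts, v, side="left" if self.upper_inclusive else "right")
        labels = self.labels or self._default_labels(cuts)
        return np.asarray(labels)[idx]

    def _default_labels(self, cuts):
        if not cuts:
            return ("all",)
        labels = [f"<={cuts[0]:g}"]
        for lo, hi in zip(cuts[:-1], cuts[1:]):
            labels.append(f"{lo:g}-{hi:g}")
        labels.append(f">{cuts[-1]:g}")
        return labels


DEFAULT_STRATA = {
    "baseline_cd4": StrataSpec("baseline_cd4", (100.0, 200.0),
                               ("<=100", "101-200", ">200")),
    "sex": StrataSpec("sex"),
    "age": StrataSpec("age", (50.0,), ("<=50", ">50")),
    "baseline_log_vl": StrataSpec("baseline_log_vl", (5.0,), ("<=5", ">5")),
}


def _carry_forward_cvl(cohort: CohortTable, grid: np.ndarray, detection_limit):
    """Per-patient cVL2 at grid times (step function from the visit series)."""
    from .cvl import compute_cvl2

    cvl = compute_cvl2(cohort.visits, detection_limit)
    out = {}
    for pid, grp in cvl.groupby("patient_id", sort=False):
        t = grp["time_on_art"].to_numpy()
        c = grp["cvl2"].to_numpy()
        idx = np.clip(np.searchsorted(t, grid, side="right") - 1, 0, len(t) - 1)
        vals = c[idx]
        vals[grid < t[0]] = 0.0
        out[pid] = vals
    return out


def predict_trajectories(
    fit: FitResult,
    cohort: CohortTable,
    strata: StrataSpec,
    grid=None,
    n_draws: int = 200,
    include_noise: bool = True,
    rng=None,
    detection_limit: float = 400.0,
) -> pd.DataFrame:
    """Per-stratum posterior-predictive median and 95% prediction interval.

    ``cohort`` must be the *raw-scale* cohort (pre-standardization) so strata
    cutpoints apply in natural units; the design inside ``fit`` supplies the
    standardized covariates actually used for prediction.  Returns a table
    (stratum, time, median, lower, upper, n_patients).
    """
    spec = fit.spec
    design = fit.design
    grid = np.asarray(
        grid if grid is not None else np.arange(0.0, 5.0 + 1e-9, 0.5), dtype=float
    )
    rng = np.random.default_rng(rng)

    raw = cohort.baselines.set_index("patient_id")
    labels = strata.assign(raw.loc[design.patient_ids, strata.variable].to_numpy())
    if pd.isna(raw.loc[design.patient_ids, strata.variable]).all():
        raise ValueError(f"stratum variable '{strata.variable}' entirely missing")

    # per-patient fixed covariate part (everything except the time basis/cvl)
    cov_cols = [design.column(c) for c in ("intercept", *spec.covariates)]
    first_row = np.searchsorted(design.group, np.arange(design.n_patients))
    Xcov = np.nan_to_num(design.X[first_row][:, cov_cols])

    TB = time_basis(grid, spec.time_basis)  # (g, k)
    cvl_grid = None
    if spec.cvl_adjusted:
        series = _carry_forward_cvl(cohort, grid, detection_limit)
        in_care = design.baseline["in_care"].to_numpy(dtype=float)
        cvl_grid = (
            np.stack([series[pid] for pid in design.patient_ids]) * in_care[:, None]
        )  # (n, g)

    chains, kept = fit.b_draws.shape[:2]
    total = chains * kept
    take = rng.choice(total, size=min(n_draws, total), replace=False)
    beta_names = ["intercept", *spec.covariates, *time_basis_names(spec.time_basis)]
    if spec.cvl_adjusted:
        beta_names.append("cvl2")
    beta_draws = np.stack(
        [np.asarray(fit.draws[f"beta_{nm}"]).reshape(total)[take] for nm in beta_names],
        axis=1,
    )  # (d, p)
    b_flat = fit.b_draws.reshape(total, design.n_patients, 2)[take]  # (d, n, 2)
    sig_draws = (
        np.asarray(fit.draws["sigma_eps"]).reshape(total)[take]
        if "sigma_eps" in fit.draws
        else None
    )
    del_draws = (
        np.asarray(fit.draws["delta_eps"]).reshape(total)[take]
        if "delta_eps" in fit.draws
        else None
    )

    n_cov = len(cov_cols)
    k_tb = TB.shape[1]
    # (d, n) covariate part + (d, g) time part + random effects
    part_cov = beta_draws[:, :n_cov] @ Xcov.T  # (d, n)
    part_time = beta_draws[:, n_cov : n_cov + k_tb] @ TB.T  # (d, g)
    pred = part_cov[:, :, None] + part_time[:, None, :]  # (d, n, g)
    if spec.cvl_adjusted:
        pred = pred + beta_draws[:, -1][:, None, None] * cvl_grid[None, :, :]
    pred = pred + b_flat[:, :, 0][:, :, None] + b_flat[:, :, 1][:, :, None] * grid

    if spec.outcome == "slope":
        if include_noise and sig_draws is not None:
            noise = sig_draws[:, None, None] * rng.standard_normal(pred.shape)
            if del_draws is not None:
                noise = noise + del_draws[:, None, None] * np.abs(
                    rng.standard_normal(pred.shape)
                )
            pred = pred + noise
    else:
        pred = expit(pred)

    records = []
    for lab in pd.unique(labels):
        sel = labels == lab
        if not sel.any():
            raise ValueError(f"empty stratum '{lab}'")
        block = pred[:, sel, :]  # (d, n_s, g)
        med = np.median(block, axis=(0, 1))
        lo = np.percentile(block, 2.5, axis=(0, 1))
        hi = np.percentile(block, 97.5, axis=(0, 1))
        for gi, tt in enumerate(grid):
            records.append(
                {
                    "stratum": lab,
                    "time": tt,
                    "median": med[gi],
                    "lower": lo[gi],
                    "upper": hi[gi],
                    "n_patients": int(sel.sum()),
                }
            )
    return pd.DataFrame.from_records(records)


def model_comparison_table(fits) -> pd.DataFrame:
    """cDIC comparison table sorted best-first.

    ``fits`` is a sequence of (label, FitResult) pairs or FitResults.  The
    difference to the best model is annotated with the <5 / ~10 decision
    rules: a clear choice needs a gap of about 10.
    """
    items = []
    for i, f in enumerate(fits):
        if isinstance(f, tuple):
            label, fr = f
        else:
            label, fr = f"model_{i}", f
        items.append((label, fr))
    if len(items) < 2:
        raise ValueError("need at least two fits to compare")
    df = pd.DataFrame(
        {
            "model": [lab for lab, _ in items],
            "cvl_adjusted": [fr.spec.cvl_adjusted for _, fr in items],
            "cdic": [fr.cdic for _, fr in items],
            "pD": [fr.pD for _, fr in items],
        }
    ).sort_values("cdic", ignore_index=True)
    best = df["cdic"].iloc[0]
    df["delta_cdic"] = df["cdic"] - best
    df["choice"] = [
        "best" if d == 0 else compare_cdic(best, best + d) for d in df["delta_cdic"]
    ]
    return df


def plot_trajectories(table: pd.DataFrame, ax=None, title: str | None = None):
    """Optional matplotlib rendering of a predict_trajectories table."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for lab, grp in table.groupby("stratum"):
        ax.plot(grp["time"], grp["median"], marker="o", label=str(lab))
        ax.fill_between(grp["time"], grp["lower"], grp["upper"], alpha=0.15)
    ax.set_xlabel("years on ART")
    ax.set_ylabel("predicted outcome")
    if title:
        ax.set_title(title)
    ax.legend()
    return ax
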