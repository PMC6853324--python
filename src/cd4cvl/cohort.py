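"""Longitudinal cohort I/O, exclusion filters and covariate standardization.

The single input currency of the pipeline is the :class:`CohortTable`:
one row per patient-visit (time on ART in years, CD4 count, viral load) plus
one row per patient of baseline covariates (sex, age, baseline CD4, baseline
log10 VL, in-care indicator).  Missing cells are carried as NaN and are never
silently dropped -- downstream models impute them within the MCMC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

VISIT_COLUMNS = ["patient_id", "time_on_art", "cd4", "viral_load", "first_line"]
BASELINE_COLUMNS = [
    "patient_id",
    "sex",
    "age",
    "baseline_cd4",
    "baseline_log_vl",
    "in_care",
]
#: continuous covariates standardized before modelling (time on ART is not)
STANDARDIZED_COVARIATES = ("age", "baseline_cd4", "baseline_log_vl")


class CohortError(ValueError):
    """Malformed or empty cohort input."""


@dataclass
class StandardizationInfo:
    """Per-covariate (mean, sd) used for z-scoring, for back-transformation."""

    params: dict  # name -> (mean, sd)
    ddof: int = 1  # sample-sd convention

    def transform(self, name: str, values):
        mean, sd = self.params[name]
        return (np.asarray(values, dtype=float) - mean) / sd

    def inverse(self, name: str, values):
        mean, sd = self.params[name]
        return np.asarray(values, dtype=float) * sd + mean


@dataclass
class CohortTable:
    """Visits (long format) + per-patient baseline covariates."""

    visits: pd.DataFrame
    baselines: pd.DataFrame
    standardization: StandardizationInfo | None = None

    @property
    def n_patients(self) -> int:
        return self.baselines["patient_id"].nunique()

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def copy(self) -> "CohortTable":
        return CohortTable(
            self.visits.copy(), self.baselines.copy(), self.standardization
        )

    def validate(self) -> None:
        dup = self.visits.duplicated(subset=["patient_id", "time_on_art"])
        if dup.any():
            pair = self.visits.loc[dup.idxmax(), ["patient_id", "time_on_art"]]
            raise CohortError(
                f"duplicate (patient, time) pair: {tuple(pair)}"
            )
        orphans = set(self.visits["patient_id"]) - set(self.baselines["patient_id"])
        if orphans:
            raise CohortError(f"visits without baseline rows: {sorted(orphans)[:5]}")
        if self.baselines["in_care"].isna().any():
            raise CohortError("in_care indicator may not be missing")


@dataclass
class ExclusionReport:
    """Patient/visit counts for each exclusion reason; partitions the input."""

    n_input_patients: int
    n_retained_patients: int
    excluded: dict = field(default_factory=dict)  # reason -> patient count
    n_second_line_visits_removed: int = 0

    def __post_init__(self):
        total = self.n_retained_patients + sum(self.excluded.values())
        if total != self.n_input_patients:
            raise CohortError("exclusion counts do not partition the cohort")


def _resolve_columns(df: pd.DataFrame, wanted: Sequence[str], dialect, optional=()):
    dialect = dict(dialect or {})
    out = {}
    for name in wanted:
        src = dialect.get(name, name)
        if src in df.columns:
            out[name] = src
        elif name in optional:
            out[name] = None
        else:
            raise CohortError(f"required column '{name}' not found (looked for '{src}')")
    return out


def read_cohort(
    path,
    dialect: Mapping[str, str] | None = None,
    baseline_path=None,
    sep: str = ",",
    missing_tokens: Sequence[str] = ("", "NA", "."),
) -> CohortTable:
    """Read a delimited long-format cohort file.

    One row per visit.  Baseline covariates may be repeated on every visit row
    (single-file layout) or supplied separately via ``baseline_path``.
    ``dialect`` maps canonical column names to the file's column names.
    Unparseable patient_id/time rows are rejected and reported; missing
    CD4/VL/covariate cells become NaN.
    """
    na = list(missing_tokens)
    raw = pd.read_csv(path, sep=sep, na_values=na, keep_default_na=False, dtype=str)
    cols = _resolve_columns(
        raw, VISIT_COLUMNS, dialect, optional=("first_line",)
    )

    visits = pd.DataFrame({"patient_id": raw[cols["patient_id"]]})
    visits["time_on_art"] = pd.to_numeric(raw[cols["time_on_art"]], errors="coerce")
    visits["cd4"] = pd.to_numeric(raw[cols["cd4"]], errors="coerce")
    visits["viral_load"] = pd.to_numeric(raw[cols["viral_load"]], errors="coerce")
    if cols["first_line"] is None:
        visits["first_line"] = True
    else:
        visits["first_line"] = (
            pd.to_numeric(raw[cols["first_line"]], errors="coerce").fillna(1).astype(int)
            != 0
        )

    bad = visits["patient_id"].isna() | visits["time_on_art"].isna()
    rejected = visits.index[bad].tolist()
    visits = visits.loc[~bad].reset_index(drop=True)
    if visits.empty:
        raise CohortError(f"no parseable visit rows in {path}")

    if baseline_path is not None:
        braw = pd.read_csv(
            baseline_path, sep=sep, na_values=na, keep_default_na=False, dtype=str
        )
    else:
        braw = raw.loc[~bad]
    bcols = _resolve_columns(braw, BASELINE_COLUMNS, dialect, optional=("in_care",))
    baselines = pd.DataFrame({"patient_id": braw[bcols["patient_id"]]})
    for name in ("sex", "age", "baseline_cd4", "baseline_log_vl"):
        baselines[name] = pd.to_numeric(braw[bcols[name]], errors="coerce")
    if bcols["in_care"] is None:
        baselines["in_care"] = 1
    else:
        baselines["in_care"] = pd.to_numeric(
            braw[bcols["in_care"]], errors="coerce"
        ).astype("Int64")
    baselines = (
        baselines.dropna(subset=["patient_id"])
        .drop_duplicates(subset="patient_id", keep="first")
        .reset_index(drop=True)
    )
    baselines["in_care"] = baselines["in_care"].astype(int)

    cohort = CohortTable(visits, baselines)
    cohort.validate()
    if rejected:
        cohort.rejected_rows = rejected  # per-row report, 0-based data rows
    return cohort


def write_cohort(cohort: CohortTable, path, sep: str = ",") -> None:
    """Write a single-file long-format cohort (baselines merged onto visits).

    Missing cells are written as empty strings; round-trips through
    :func:`read_cohort`.
    """
    merged = cohort.visits.merge(cohort.baselines, on="patient_id", how="left")
    merged["first_line"] = merged["first_line"].astype(int)
    merged.to_csv(path, sep=sep, index=False, na_rep="")


def apply_exclusions(
    cohort: CohortTable, outcome: str = "slope"
) -> tuple[CohortTable, ExclusionReport]:
    """Apply the analysis exclusion filters.

    (a) visits on second-line ART are removed; (b) patients left with only a
    baseline visit are removed (a trajectory cannot be estimated from one
    point); (c) for the asymptote outcome, patients with baseline CD4 >= 500
    cells/uL are removed (they already sit at the threshold).
    """
    if outcome not in ("slope", "asymptote"):
        raise ValueError(f"unknown outcome '{outcome}'")
    cohort.validate()
    n_input = cohort.n_patients

    visits = cohort.visits[cohort.visits["first_line"]].copy()
    n_second_line = cohort.n_visits - len(visits)

    post = visits[visits["time_on_art"] > 0].groupby("patient_id").size()
    keep = set(post.index)
    baseline_only = set(cohort.baselines["patient_id"]) - keep
    excluded = {"baseline-only": len(baseline_only)}

    baselines = cohort.baselines[cohort.baselines["patient_id"].isin(keep)].copy()
    if outcome == "asymptote":
        high = baselines["baseline_cd4"] >= 500  # NaN baseline CD4 -> retained
        excluded["baseline-cd4>=500"] = int(high.sum())
        baselines = baselines[~high.fillna(False)]
        keep = set(baselines["patient_id"])

    visits = visits[visits["patient_id"].isin(keep)].reset_index(drop=True)
    baselines = baselines.reset_index(drop=True)
    if visits.empty or baselines.empty:
        raise CohortError("cohort empty after exclusions")

    report = ExclusionReport(
        n_input_patients=n_input,
        n_retained_patients=len(baselines),
        excluded=excluded,
        n_second_line_visits_removed=n_second_line,
    )
    return CohortTable(visits, baselines, cohort.standardization), report


def standardize_covariates(
    cohort: CohortTable,
    covariates: Sequence[str] = STANDARDIZED_COVARIATES,
    ddof: int = 1,
) -> tuple[CohortTable, StandardizationInfo]:
    """z-score the continuous baseline covariates on the analysis sample.

    Means/sds are computed over non-missing entries of the post-exclusion
    sample; time on ART is deliberately untouched so that slope coefficients
    stay in cells/uL per year.  The returned info allows back-transformation
    and puts imputed draws on the standardized scale.
    """
    baselines = cohort.baselines.copy()
    params = {}
    for name in covariates:
        vals = baselines[name].astype(float)
        mean = float(vals.mean())
        sd = float(vals.std(ddof=ddof))
        if not np.isfinite(sd) or sd <= 0:
            raise CohortError(f"covariate '{name}' has zero variance")
        params[name] = (mean, sd)
        baselines[name] = (vals - mean) / sd
    info = StandardizationInfo(params=params, ddof=ddof)
    return CohortTable(cohort.visits.copy(), baselines, info), info
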