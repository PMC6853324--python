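"""Model specifications, design matrices and conditional log-likelihoods.

Two outcome families share one fixed-effects structure (intercept, sex,
baseline age, baseline CD4, baseline log10 VL, a time basis, and optionally
the in-care x cVL2 exposure) and a bivariate random intercept + slope:

* the **slope** family -- a linear mixed model for the CD4 count trajectory,
  y_ij = x_ij'β + z_ij'b_i + ε_ij, with Gaussian or skew-normal random
  effects and Gaussian or skew-normal measurement error;
* the **asymptote** family -- a logistic mixed model for the odds of reaching
  the normal-range threshold CD4 >= 500 cells/uL at any post-baseline visit,
  logit(π_ij) = x_ij'β + z_ij'b_i, Gaussian or skew-normal random effects.

The time basis is either a second-degree polynomial (t, t²) or a cubic
B-spline with 3 or 5 inner knots on the 5-year follow-up window; only the
fixed-effects basis changes -- the random slope always multiplies raw time.

Skew-normal variates use the stochastic representation ξ + δ·|w| + u with
w ~ N(0,1) truncated to the positives and u the Gaussian kernel, which makes
every skew-normal block samplable with conjugate or generic MCMC updates and
reduces exactly to the Gaussian at δ = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import log_ndtr

from .cohort import CohortTable

FOLLOW_UP_HORIZON = 5.0  # years
CD4_THRESHOLD = 500.0  # cells/uL, "normal range" lower bound

INNER_KNOTS = {
    "bspline3": (1.250, 2.5, 3.751),
    "bspline5": (0.833, 1.666, 2.5, 3.334, 4.167),
}

BASELINE_COVARIATES = ("sex", "age", "baseline_cd4", "baseline_log_vl")
#: covariates the MCMC imputes when missing (age must be complete)
IMPUTABLE_COVARIATES = ("baseline_cd4", "baseline_log_vl", "sex")


@dataclass(frozen=True)
class ModelSpec:
    """One of the nine model variants, adjusted or unadjusted for cVL2.

    model 1: slope, poly2, gaussian RE + gaussian error
    model 2/3: slope, bspline3/bspline5, gaussian
    model 4: slope, poly2, skew-normal RE
    model 5: slope, poly2, skew-normal RE + skew-normal error
    model 6: asymptote, poly2, gaussian RE
    model 7: asymptote, poly2, skew-normal RE
    model 8/9: asymptote, bspline3/bspline5, gaussian RE
    """

    outcome: str = "slope"  # slope | asymptote
    time_basis: str = "poly2"  # poly2 | bspline3 | bspline5
    re_dist: str = "gaussian"  # gaussian | skew_normal
    error_dist: str = "gaussian"  # gaussian | skew_normal (slope only)
    cvl_adjusted: bool = False
    covariates: tuple = BASELINE_COVARIATES

    def __post_init__(self):
        if self.outcome not in ("slope", "asymptote"):
            raise ValueError(f"unknown outcome '{self.outcome}'")
        if self.time_basis not in ("poly2", "bspline3", "bspline5"):
            raise ValueError(f"unknown time basis '{self.time_basis}'")
        if self.re_dist not in ("gaussian", "skew_normal"):
            raise ValueError(f"unknown random-effects distribution '{self.re_dist}'")
        if self.outcome == "asymptote" and self.error_dist != "gaussian":
            raise ValueError(
                "asymptote models have no error term; skew-normal error invalid"
            )
        if self.error_dist not in ("gaussian", "skew_normal"):
            raise ValueError(f"unknown error distribution '{self.error_dist}'")

    @classmethod
    def from_model_number(cls, k: int, cvl_adjusted: bool = True) -> "ModelSpec":
        table = {
            1: dict(outcome="slope", time_basis="poly2"),
            2: dict(outcome="slope", time_basis="bspline3"),
            3: dict(outcome="slope", time_basis="bspline5"),
            4: dict(outcome="slope", time_basis="poly2", re_dist="skew_normal"),
            5: dict(
                outcome="slope",
                time_basis="poly2",
                re_dist="skew_normal",
                error_dist="skew_normal",
            ),
            6: dict(outcome="asymptote", time_basis="poly2"),
            7: dict(outcome="asymptote", time_basis="poly2", re_dist="skew_normal"),
            8: dict(outcome="asymptote", time_basis="bspline3"),
            9: dict(outcome="asymptote", time_basis="bspline5"),
        }
        if k not in table:
            raise ValueError("model number must be 1..9")
        return cls(cvl_adjusted=cvl_adjusted, **table[k])

    @property
    def time_basis_size(self) -> int:
        if self.time_basis == "poly2":
            return 2
        # cubic B-spline, intercept column dropped: n_inner + 4 - 1
        return len(INNER_KNOTS[self.time_basis]) + 3


def time_basis(
    t,
    basis: str = "poly2",
    horizon: float = FOLLOW_UP_HORIZON,
    include_intercept: bool = False,
) -> np.ndarray:
    """Fixed-effects time-basis rows for times ``t`` (years in [0, horizon]).

    poly2 returns (t, t²).  B-spline bases are cubic with the fixed inner
    knots and boundary knots (0, horizon); the first column (the one absorbed
    by the model intercept) is dropped unless ``include_intercept``.
    """
    t = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t < 0) or np.any(t > horizon + 1e-9):
        raise ValueError(f"time outside [0, {horizon}]")
    if basis == "poly2":
        return np.column_stack([t, t**2])
    if basis not in INNER_KNOTS:
        raise ValueError(f"unknown time basis '{basis}'")
    inner = INNER_KNOTS[basis]
    knots = np.concatenate([[0.0] * 4, inner, [horizon] * 4])
    B = BSpline.design_matrix(np.clip(t, 0, horizon), knots, 3, extrapolate=False)
    B = np.asarray(B.todense())
    return B if include_intercept else B[:, 1:]


def time_basis_names(basis: str) -> list[str]:
    if basis == "poly2":
        return ["time", "time_sq"]
    return [f"{basis}_{i}" for i in range(1, len(INNER_KNOTS[basis]) + 4)]


@dataclass
class DesignMatrices:
    """Assembled fixed/random design with missingness bookkeeping.

    Rows are sorted by (patient, time).  ``X`` holds NaN where a baseline
    covariate is missing; the sampler's imputation layer fills those cells at
    every iteration.  ``Z`` is always (1, t): random intercept + slope.
    """

    X: np.ndarray
    Z: np.ndarray
    y: np.ndarray  # CD4 (slope) or 0/1 threshold indicator (asymptote); NaN missing
    columns: list[str]
    patient_ids: np.ndarray  # unique ids, length n
    group: np.ndarray  # row -> patient index in [0, n)
    time: np.ndarray  # raw time per row
    baseline: pd.DataFrame  # per-patient standardized covariates (NaN = missing)
    spec: ModelSpec = None
    missing_cov: dict = field(default_factory=dict)  # name -> (col idx, patient mask)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def column(self, name: str) -> int:
        return self.columns.index(name)


def build_design(
    cohort: CohortTable,
    spec: ModelSpec,
    cvl: pd.DataFrame | None = None,
) -> DesignMatrices:
    """Assemble X, Z and the outcome vector for a model specification.

    Expects exclusions and standardization already applied.  ``cvl`` is the
    per-visit cVL2 table (patient_id, time_on_art, cvl2) and is required when
    ``spec.cvl_adjusted``; the exposure column is in_care x cvl2, so patients
    lost to follow-up contribute zero exposure.  For the asymptote outcome,
    only post-baseline visits enter and y_ij = 1{CD4 >= 500} (NaN when the
    CD4 count is missing).
    """
    if spec.cvl_adjusted and cvl is None:
        raise ValueError("cvl_adjusted spec requires a cVL2 series")

    visits = cohort.visits
    if spec.outcome == "asymptote":
        visits = visits[visits["time_on_art"] > 0]
        if visits.empty:
            raise ValueError("no post-baseline visits for the asymptote outcome")
    visits = visits.sort_values(["patient_id", "time_on_art"]).reset_index(drop=True)

    if spec.cvl_adjusted:
        visits = visits.merge(
            cvl.rename(columns={"cvl2": "_cvl2"}),
            on=["patient_id", "time_on_art"],
            how="left",
        )
        if visits["_cvl2"].isna().any():
            raise ValueError("cVL2 series does not cover every analysed visit")

    baselines = (
        cohort.baselines.set_index("patient_id")
        .loc[visits["patient_id"].unique()]
        .reset_index()
    )
    patient_ids = baselines["patient_id"].to_numpy()
    code = {pid: i for i, pid in enumerate(patient_ids)}
    group = visits["patient_id"].map(code).to_numpy()

    t = visits["time_on_art"].to_numpy(dtype=float)
    basis = time_basis(t, spec.time_basis)
    columns = ["intercept", *spec.covariates, *time_basis_names(spec.time_basis)]
    blocks = [np.ones((len(visits), 1))]
    for name in spec.covariates:
        blocks.append(baselines[name].to_numpy(dtype=float)[group][:, None])
    blocks.append(basis)
    if spec.cvl_adjusted:
        in_care = baselines["in_care"].to_numpy(dtype=float)[group]
        blocks.append((in_care * visits["_cvl2"].to_numpy(dtype=float))[:, None])
        columns.append("cvl2")
    X = np.hstack(blocks)

    Z = np.column_stack([np.ones_like(t), t])
    cd4 = visits["cd4"].to_numpy(dtype=float)
    if spec.outcome == "slope":
        y = cd4
    else:
        y = np.where(np.isnan(cd4), np.nan, (cd4 >= CD4_THRESHOLD).astype(float))

    missing_cov = {}
    for name in IMPUTABLE_COVARIATES:
        if name in spec.covariates:
            mask = baselines[name].isna().to_numpy()
            if mask.any():
                missing_cov[name] = (columns.index(name), mask)

    return DesignMatrices(
        X=X,
        Z=Z,
        y=y,
        columns=columns,
        patient_ids=patient_ids,
        group=group,
        time=t,
        baseline=baselines,
        spec=spec,
        missing_cov=missing_cov,
    )


@dataclass
class ModelParameters:
    """A single parameter state (or posterior-mean state) of a model."""

    beta: np.ndarray
    b: np.ndarray  # (n_patients, 2) realized random effects
    Sigma_b: np.ndarray = None
    sigma_eps: float = 1.0
    delta_b: float = 0.0  # random-effects skewness (0 = gaussian)
    delta_eps: float = 0.0  # error skewness (0 = gaussian)


def sn_logpdf(x, loc, sigma, delta):
    """Log density of the ξ + δ|w| + u skew-normal.

    With w ~ N(0,1) truncated positive and u ~ N(0, σ²) the marginal is the
    classic skew-normal with scale ω² = σ² + δ² and shape α = δ/σ:
    f(x) = 2·φ(x; loc, ω²)·Φ(α (x−loc)/ω).  δ = 0 recovers N(loc, σ²).
    """
    x = np.asarray(x, dtype=float)
    omega2 = sigma**2 + delta**2
    omega = np.sqrt(omega2)
    zed = (x - loc) / omega
    base = -0.5 * np.log(2 * np.pi * omega2) - 0.5 * zed**2
    if delta == 0:
        return base
    alpha = delta / sigma
    return np.log(2.0) + base + log_ndtr(alpha * zed)


def log_likelihood(
    params: ModelParameters,
    design: DesignMatrices,
    y: np.ndarray | None = None,
    spec: ModelSpec | None = None,
) -> float:
    """Conditional log-likelihood of the outcomes given random effects.

    This is the deviance kernel used by the conditional DIC: random effects
    are conditioned on, so skew-normal *random effects* leave the likelihood
    Gaussian, while a skew-normal *error* term changes the observation
    density itself.  Rows with missing outcome are skipped.
    """
    spec = spec or design.spec
    y = design.y if y is None else np.asarray(y, dtype=float)
    eta = design.X @ params.beta + np.einsum(
        "ij,ij->i", design.Z, params.b[design.group]
    )
    obs = ~np.isnan(y)
    if not np.all(np.isfinite(eta[obs])):
        raise ValueError("non-finite linear predictor")
    if spec.outcome == "slope":
        ll = sn_logpdf(y[obs], eta[obs], params.sigma_eps, params.delta_eps)
        return float(np.sum(ll))
    # Bernoulli with logit link, numerically stable via log Φ-style softplus
    eta_o = eta[obs]
    y_o = y[obs]
    return float(np.sum(y_o * eta_o - np.logaddexp(0.0, eta_o)))


def sn_mean_offset(delta: float) -> float:
    """Mean of δ|w| for w ~ N(0,1) truncated positive: δ·sqrt(2/π).

    Under the location-zero convention SN(0, Σ, Δ) has this nonzero mean; a
    configuration switch in the simulator/sampler can subtract it to center
    the distribution at zero instead.
    """
    return delta * np.sqrt(2.0 / np.pi)
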