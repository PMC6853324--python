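"""Synthetic ART cohort generator.

Emulates the statistical structure the analysis assumes: ~750 patients seen
6-monthly for 5 years, ~70% female, low baseline CD4 (median ~89 cells/uL,
gamma-matched IQR 43-143), high baseline viremia (median log10 VL ~5.1), a
two-state (suppressed / rebounding) viral-load process that yields nonzero
and variable cumulative log viral load, CD4 trajectories from the linear
mixed model y = Xβ + Zb + ε with Gaussian or skew-normal random effects, and
MCAR missingness in viral loads, CD4 outcomes and baseline covariates.

Every generated cohort comes with a truth record (β, all b_i, noiseless
linear predictors, pre-missingness values) sufficient to verify recovery at
every pipeline stage.  The generator does *not* model mechanistic viral
dynamics or the real cohort's joint covariate dependence beyond marginals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import gamma as gamma_dist

from .cohort import CohortTable
from .cvl import DEFAULT_DETECTION_LIMIT, compute_cvl2_series
from .models import time_basis, time_basis_names

#: fixed-effect truth: the adjusted quadratic slope model's point estimates,
#: covariates on the standardized scale (sex is the raw 0/1 indicator)
DEFAULT_SLOPE_BETA = {
    "intercept": 105.0,
    "sex": 23.8,
    "age": -6.3,
    "baseline_cd4": 82.9,
    "baseline_log_vl": 7.5,
    "time": 55.7,
    "time_sq": -22.7,
    "cvl2": -19.6,
}

#: log-odds truth for the threshold model (posterior mean ORs, logged)
DEFAULT_ASYMPTOTE_BETA = {
    "intercept": -4.6,
    "sex": float(np.log(6.35)),
    "age": float(np.log(0.54)),
    "baseline_cd4": float(np.log(3.00)),
    "baseline_log_vl": float(np.log(1.26)),
    "time": float(np.log(4.08)),
    "time_sq": float(np.log(0.65)),
    "cvl2": float(np.log(0.42)),
}


def _lognormal_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    mu = np.log(median)
    sigma = (np.log(q3) - np.log(q1)) / (2 * 0.6744897501960817)
    return mu, sigma


def _gamma_params(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Shape/scale of a gamma matched to a median and IQR."""
    target = q3 / q1

    def ratio(k):
        return gamma_dist.ppf(0.75, k) / gamma_dist.ppf(0.25, k) - target

    k = brentq(ratio, 0.05, 50.0)
    theta = median / gamma_dist.ppf(0.5, k)
    return k, theta


@dataclass
class SyntheticConfig:
    """Cohort size, covariate marginals, viral dynamics, truth and noise."""

    n_patients: int = 750
    visit_interval: float = 0.5  # years
    horizon: float = 5.0  # years
    p_female: float = 0.696
    age_median: float = 36.0
    age_iqr: tuple = (31.0, 42.0)
    cd4_median: float = 89.0
    cd4_iqr: tuple = (43.0, 143.0)
    log_vl_median: float = 5.1
    log_vl_iqr: tuple = (4.64, 5.48)
    # two-state viral-load process
    p_suppress: float = 0.85  # unsuppressed -> suppressed, per visit
    p_rebound: float = 0.08  # suppressed -> rebound, per visit
    rebound_log_vl_mean: float = 4.0
    rebound_log_vl_sd: float = 0.6
    suppressed_vl: float = 50.0  # assay-limit value while suppressed
    # missingness (MCAR by default; MAR mode keys missing CD4 on the
    # previous visit's CD4)
    missing_vl: float = 0.49
    missing_cd4: float = 0.05
    missing_baseline: float = 0.03  # per covariate: sex, baseline CD4, log VL
    mar_cd4: bool = False
    dropout: float = 0.02  # per-visit hazard of loss to follow-up
    # truth
    beta: dict = field(default_factory=lambda: dict(DEFAULT_SLOPE_BETA))
    sigma0: float = 90.0
    sigma1: float = 35.0
    rho: float = -0.2
    delta: float = 0.0  # random-effects skewness (0 = gaussian)
    delta_eps: float = 0.0  # error skewness (slope only)
    sigma_eps: float = 80.0
    sn_mean_correction: bool = False  # subtract delta*sqrt(2/pi) to center b
    # The published quadratic time trend turns strongly negative late in
    # follow-up, so clamping negative CD4 at 0 would distort ~1/3 of visits
    # and break the generative model; clamping is therefore opt-in and the
    # count of affected visits is always reported in the truth record.
    truncate_cd4: bool = False
    # exclusion-filter exercise
    n_baseline_only: int = 0
    n_second_line: int = 0  # patients whose final 2 visits are second-line
    detection_limit: float = DEFAULT_DETECTION_LIMIT
    seed: int = 0

    def __post_init__(self):
        for p in (self.p_female, self.p_suppress, self.p_rebound,
                  self.missing_vl, self.missing_cd4, self.missing_baseline):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout hazard must be in [0, 1)")
        n_intervals = self.horizon / self.visit_interval
        if abs(n_intervals - round(n_intervals)) > 1e-9:
            raise ValueError("horizon must be a multiple of visit_interval")

    @property
    def visit_times(self) -> np.ndarray:
        k = int(round(self.horizon / self.visit_interval))
        return np.arange(k + 1) * self.visit_interval

    @classmethod
    def for_asymptote(cls, **overrides) -> "SyntheticConfig":
        """Defaults on the log-odds scale for the threshold outcome."""
        base = dict(
            beta=dict(DEFAULT_ASYMPTOTE_BETA),
            sigma0=2.0,
            sigma1=0.6,
            rho=-0.2,
        )
        base.update(overrides)
        return cls(**base)


def _draw_covariates(cfg: SyntheticConfig, rng, n: int, cap_cd4: float | None = None):
    sex = (rng.uniform(size=n) < cfg.p_female).astype(float)
    mu_a, sd_a = _lognormal_params(cfg.age_median, *cfg.age_iqr)
    age = np.exp(mu_a + sd_a * rng.standard_normal(n))
    k, theta = _gamma_params(cfg.cd4_median, *cfg.cd4_iqr)
    bcd4 = rng.gamma(k, theta, size=n)
    if cap_cd4 is not None:
        while True:  # regenerate the few draws at/above the threshold
            high = bcd4 >= cap_cd4
            if not high.any():
                break
            bcd4[high] = rng.gamma(k, theta, size=int(high.sum()))
    mu_v = cfg.log_vl_median
    sd_v = (cfg.log_vl_iqr[1] - cfg.log_vl_iqr[0]) / (2 * 0.6744897501960817)
    blvl = mu_v + sd_v * rng.standard_normal(n)
    return sex, age, bcd4, blvl


def _simulate_vl(cfg: SyntheticConfig, rng, blvl: float, n_visits: int) -> np.ndarray:
    """Two-state per-visit Markov viral-load series, copies/mL."""
    vl = np.empty(n_visits)
    vl[0] = 10.0**blvl
    suppressed = False
    for k in range(1, n_visits):
        if not suppressed:
            if rng.uniform() < cfg.p_suppress:
                suppressed = True
        else:
            if rng.uniform() < cfg.p_rebound:
                suppressed = False
        if suppressed:
            vl[k] = cfg.suppressed_vl
        else:
            if k == 1 and vl[0] > cfg.detection_limit and not suppressed:
                # still on the initial decay from baseline viremia
                vl[k] = 10.0 ** (blvl - rng.uniform(0.5, 1.5))
            else:
                vl[k] = 10.0 ** (
                    cfg.rebound_log_vl_mean
                    + cfg.rebound_log_vl_sd * rng.standard_normal()
                )
    return np.maximum(vl, 1.0)


def _random_effects(cfg: SyntheticConfig, rng, n: int):
    # closed-form 2x2 cholesky; tolerates zero sds (degenerate noise-free runs)
    L = np.array(
        [
            [cfg.sigma0, 0.0],
            [cfg.rho * cfg.sigma1, cfg.sigma1 * np.sqrt(1.0 - cfg.rho**2)],
        ]
    )
    eta = rng.standard_normal((n, 2)) @ L.T
    w = np.abs(rng.standard_normal((n, 2)))
    b = cfg.delta * w + eta
    if cfg.sn_mean_correction:
        b = b - cfg.delta * np.sqrt(2.0 / np.pi)
    return b, eta, w


def _zscore(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    return (x - mean) / sd, mean, sd


def generate_cohort(cfg: SyntheticConfig) -> tuple[CohortTable, dict]:
    """Generate a slope-outcome cohort and its ground-truth record."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    times = cfg.visit_times
    sex, age, bcd4, blvl = _draw_covariates(cfg, rng, n)

    sex_z = sex  # binary, not standardized
    age_z, age_m, age_s = _zscore(age)
    cd4_z, cd4_m, cd4_s = _zscore(bcd4)
    lvl_z, lvl_m, lvl_s = _zscore(blvl)

    # follow-up length via per-visit dropout
    n_visits = np.full(n, len(times), dtype=int)
    if cfg.dropout > 0:
        u = rng.uniform(size=(n, len(times) - 1))
        dropped = u < cfg.dropout
        for i in range(n):
            hit = np.nonzero(dropped[i])[0]
            if hit.size:
                n_visits[i] = hit[0] + 1
    n_visits = np.maximum(n_visits, 2)  # keep at least one post-baseline visit
    in_care = (n_visits == len(times)).astype(int)

    b, eta_re, w_re = _random_effects(cfg, rng, n)

    beta = dict(cfg.beta)
    basis_names = time_basis_names("poly2")
    acc = {k: [] for k in ("pid", "t", "lp", "mu", "cvl2", "cd4", "vl")}
    for i in range(n):
        t = times[: n_visits[i]]
        vl = _simulate_vl(cfg, rng, blvl[i], n_visits[i])
        cvl2 = compute_cvl2_series(t, vl, cfg.detection_limit)
        tb = time_basis(t, "poly2")
        lp = (
            beta["intercept"]
            + beta["sex"] * sex_z[i]
            + beta["age"] * age_z[i]
            + beta["baseline_cd4"] * cd4_z[i]
            + beta["baseline_log_vl"] * lvl_z[i]
            + tb @ np.array([beta[nm] for nm in basis_names])
            + beta.get("cvl2", 0.0) * in_care[i] * cvl2
        )
        mu = lp + b[i, 0] + b[i, 1] * t
        eps = cfg.sigma_eps * rng.standard_normal(len(t))
        if cfg.delta_eps != 0.0:
            eps = eps + cfg.delta_eps * np.abs(rng.standard_normal(len(t)))
        cd4 = mu + eps
        acc["pid"].append(np.full(len(t), i))
        acc["t"].append(t)
        acc["lp"].append(lp)
        acc["mu"].append(mu)
        acc["cvl2"].append(cvl2)
        acc["cd4"].append(cd4)
        acc["vl"].append(vl)

    cat = {k: np.concatenate(v) for k, v in acc.items()}
    visits = pd.DataFrame(
        {
            "patient_id": cat["pid"],
            "time_on_art": cat["t"],
            "cd4": np.maximum(cat["cd4"], 0.0) if cfg.truncate_cd4 else cat["cd4"],
            "viral_load": cat["vl"],
            "first_line": True,
        }
    )
    truth_visits = pd.DataFrame(
        {
            "patient_id": cat["pid"],
            "time_on_art": cat["t"],
            "lp": cat["lp"],
            "mu": cat["mu"],
            "cvl2_true": cat["cvl2"],
            "cd4_true": cat["cd4"],
            "vl_true": cat["vl"],
        }
    )
    n_truncated = int((truth_visits["cd4_true"] < 0).sum())

    # missingness, MCAR unless MAR mode is on
    vl_miss = rng.uniform(size=len(visits)) < cfg.missing_vl
    visits.loc[vl_miss, "viral_load"] = np.nan
    if cfg.mar_cd4 and cfg.missing_cd4 > 0:
        prev = visits.groupby("patient_id")["cd4"].shift(1)
        # lower previous CD4 -> more likely to miss the next measurement
        logit = np.log(cfg.missing_cd4 / (1 - cfg.missing_cd4)) - 0.004 * (
            prev.fillna(prev.mean()) - prev.mean()
        )
        cd4_miss = rng.uniform(size=len(visits)) < expit(logit.to_numpy())
    else:
        cd4_miss = rng.uniform(size=len(visits)) < cfg.missing_cd4
    visits.loc[cd4_miss, "cd4"] = np.nan

    baselines = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "sex": sex,
            "age": age,
            "baseline_cd4": bcd4,
            "baseline_log_vl": blvl,
            "in_care": in_care,
        }
    )
    for name in ("sex", "baseline_cd4", "baseline_log_vl"):
        m = rng.uniform(size=n) < cfg.missing_baseline
        baselines.loc[m, name] = np.nan

    # optional patients exercising the exclusion filters
    next_id = n
    if cfg.n_baseline_only:
        extra_sex, extra_age, extra_cd4, extra_lvl = _draw_covariates(
            cfg, rng, cfg.n_baseline_only
        )
        ids = np.arange(next_id, next_id + cfg.n_baseline_only)
        visits = pd.concat(
            [
                visits,
                pd.DataFrame(
                    {
                        "patient_id": ids,
                        "time_on_art": 0.0,
                        "cd4": extra_cd4,
                        "viral_load": 10.0**extra_lvl,
                        "first_line": True,
                    }
                ),
            ],
            ignore_index=True,
        )
        baselines = pd.concat(
            [
                baselines,
                pd.DataFrame(
                    {
                        "patient_id": ids,
                        "sex": extra_sex,
                        "age": extra_age,
                        "baseline_cd4": extra_cd4,
                        "baseline_log_vl": extra_lvl,
                        "in_care": 0,
                    }
                ),
            ],
            ignore_index=True,
        )
        next_id += cfg.n_baseline_only
    if cfg.n_second_line:
        targets = rng.choice(np.arange(n), size=min(cfg.n_second_line, n), replace=False)
        for pid in targets:
            rows_i = visits.index[visits["patient_id"] == pid]
            visits.loc[rows_i[-2:], "first_line"] = False

    cohort = CohortTable(visits, baselines)
    truth = {
        "beta": beta,
        "columns": ["intercept", "sex", "age", "baseline_cd4",
                    "baseline_log_vl", *basis_names]
        + (["cvl2"] if "cvl2" in beta else []),
        "b": b,
        "eta": eta_re,
        "w": w_re,
        "sigma0": cfg.sigma0,
        "sigma1": cfg.sigma1,
        "rho": cfg.rho,
        "sigma_eps": cfg.sigma_eps,
        "delta": cfg.delta,
        "delta_eps": cfg.delta_eps,
        "visits": truth_visits,
        "baselines_complete": pd.DataFrame(
            {
                "patient_id": np.arange(n),
                "sex": sex,
                "age": age,
                "baseline_cd4": bcd4,
                "baseline_log_vl": blvl,
                "in_care": in_care,
            }
        ),
        "standardization": {
            "age": (age_m, age_s),
            "baseline_cd4": (cd4_m, cd4_s),
            "baseline_log_vl": (lvl_m, lvl_s),
        },
        "n_cd4_truncated": n_truncated,
        "config": asdict(cfg),
    }
    return cohort, truth


def make_asymptote_cohort(cfg: SyntheticConfig) -> tuple[CohortTable, dict]:
    """Generate a threshold-outcome cohort: binary y_ij ~ Bern(logit⁻¹(Xβ+Zb)).

    ``cfg.beta`` must be on the log-odds scale (see DEFAULT_ASYMPTOTE_BETA).
    Baseline CD4 draws at or above 500 cells/uL are regenerated so the
    analysis precondition (no patient starts at the threshold) holds.  The
    binary outcome is encoded through the CD4 column: 650 cells/uL where
    y = 1 and 350 where y = 0, so thresholding at 500 recovers y exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_patients
    times = cfg.visit_times
    sex, age, bcd4, blvl = _draw_covariates(cfg, rng, n, cap_cd4=500.0)

    age_z, age_m, age_s = _zscore(age)
    cd4_z, cd4_m, cd4_s = _zscore(bcd4)
    lvl_z, lvl_m, lvl_s = _zscore(blvl)

    n_visits = np.full(n, len(times), dtype=int)
    if cfg.dropout > 0:
        u = rng.uniform(size=(n, len(times) - 1))
        for i in range(n):
            hit = np.nonzero(u[i] < cfg.dropout)[0]
            if hit.size:
                n_visits[i] = hit[0] + 1
    n_visits = np.maximum(n_visits, 2)
    in_care = (n_visits == len(times)).astype(int)

    b, eta_re, w_re = _random_effects(cfg, rng, n)
    beta = dict(cfg.beta)
    basis_names = time_basis_names("poly2")

    acc = {k: [] for k in ("pid", "t", "lp", "eta", "pi", "y", "cvl2", "cd4", "vl")}
    for i in range(n):
        t = times[: n_visits[i]]
        vl = _simulate_vl(cfg, rng, blvl[i], n_visits[i])
        cvl2 = compute_cvl2_series(t, vl, cfg.detection_limit)
        tb = time_basis(t, "poly2")
        lp = (
            beta["intercept"]
            + beta["sex"] * sex[i]
            + beta["age"] * age_z[i]
            + beta["baseline_cd4"] * cd4_z[i]
            + beta["baseline_log_vl"] * lvl_z[i]
            + tb @ np.array([beta[nm] for nm in basis_names])
            + beta.get("cvl2", 0.0) * in_care[i] * cvl2
        )
        eta_lin = lp + b[i, 0] + b[i, 1] * t
        pij = expit(eta_lin)
        y = (rng.uniform(size=len(t)) < pij).astype(float)
        y[0] = 0.0  # baseline CD4 < 500 by construction
        cd4 = np.where(y == 1.0, 650.0, 350.0)
        cd4[0] = bcd4[i]
        acc["pid"].append(np.full(len(t), i))
        acc["t"].append(t)
        acc["lp"].append(lp)
        acc["eta"].append(eta_lin)
        acc["pi"].append(pij)
        acc["y"].append(y)
        acc["cvl2"].append(cvl2)
        acc["cd4"].append(cd4)
        acc["vl"].append(vl)

    cat = {k: np.concatenate(v) for k, v in acc.items()}
    visits = pd.DataFrame(
        {
            "patient_id": cat["pid"],
            "time_on_art": cat["t"],
            "cd4": cat["cd4"],
            "viral_load": cat["vl"],
            "first_line": True,
        }
    )
    truth_visits = pd.DataFrame(
        {
            "patient_id": cat["pid"],
            "time_on_art": cat["t"],
            "lp": cat["lp"],
            "eta": cat["eta"],
            "pi": cat["pi"],
            "y": cat["y"],
            "cvl2_true": cat["cvl2"],
            "vl_true": cat["vl"],
        }
    )

    vl_miss = rng.uniform(size=len(visits)) < cfg.missing_vl
    visits.loc[vl_miss, "viral_load"] = np.nan
    cd4_miss = (rng.uniform(size=len(visits)) < cfg.missing_cd4) & (
        visits["time_on_art"] > 0
    )
    visits.loc[cd4_miss, "cd4"] = np.nan

    baselines = pd.DataFrame(
        {
            "patient_id": np.arange(n),
            "sex": sex,
            "age": age,
            "baseline_cd4": bcd4,
            "baseline_log_vl": blvl,
            "in_care": in_care,
        }
    )
    for name in ("sex", "baseline_cd4", "baseline_log_vl"):
        m = rng.uniform(size=n) < cfg.missing_baseline
        baselines.loc[m, name] = np.nan

    cohort = CohortTable(visits, baselines)
    truth = {
        "beta": beta,
        "b": b,
        "eta": eta_re,
        "w": w_re,
        "visits": truth_visits,
        "baselines_complete": pd.DataFrame(
            {
                "patient_id": np.arange(n),
                "sex": sex,
                "age": age,
                "baseline_cd4": bcd4,
                "baseline_log_vl": blvl,
                "in_care": in_care,
            }
        ),
        "standardization": {
            "age": (age_m, age_s),
            "baseline_cd4": (cd4_m, cd4_s),
            "baseline_log_vl": (lvl_m, lvl_s),
        },
        "config": asdict(cfg),
    }
    return cohort, truth
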