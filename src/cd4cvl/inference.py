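"""MCMC fitting with within-chain missing-data imputation.

The sampler is component-wise: conjugate Gibbs updates wherever the full
conditional is available in closed form (all Gaussian linear blocks, the
inverse-Wishart random-effects covariance, the truncated-normal latents of
the skew-normal representation, the error variance under a uniform prior on
the sd) and adaptive random-walk Metropolis steps for the blocks a logistic
likelihood makes non-conjugate (fixed effects and random effects of the
asymptote models, the logistic imputation model for sex, skewness blocks of
the asymptote family).  Adaptation runs only during burn-in, so the retained
chain is a valid Markov chain.

Missing data are handled by data augmentation inside every iteration:
missing baseline CD4 and baseline log VL are drawn from per-patient linear
imputation models (intercept + sex + age), missing sex from a logistic
imputation model (intercept + age + baseline CD4 + baseline log VL) using
the just-imputed covariates, and missing CD4 outcomes from the outcome
model's predictive distribution.  Observed cells are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri
from scipy.stats import invwishart

from . import diagnostics
from .cohort import CohortTable, apply_exclusions, standardize_covariates
from .cvl import DEFAULT_DETECTION_LIMIT, compute_cvl2
from .models import (
    DesignMatrices,
    ModelParameters,
    ModelSpec,
    build_design,
    log_likelihood,
)

__all__ = [
    "McmcConfig",
    "FitResult",
    "ImputationModel",
    "fit",
    "prepare_design",
    "impute_step",
    "cdic",
]

# vague defaults (overridable); coefficients get PriorSpec entries instead
DELTA_PRIOR_VAR = 100.0  # skewness ~ N(0, 100)
SIGMA_UNIFORM_UPPER = 100.0  # residual sd ~ U(0, 100)
IW_DF = 3  # q + 1 for the 2x2 random-effects covariance
PHI_PRIOR_PRECISION = 1e-6  # imputation-model coefficients
OMEGA_IG_SHAPE = 1e-3  # imputation-model residual variance
OMEGA_IG_RATE = 1e-3


@dataclass
class McmcConfig:
    """Chains / iteration schedule.  ``n_iter`` counts post-burn-in draws."""

    n_chains: int = 3
    burn_in: int = 1000
    n_iter: int = 2000
    thin: int = 1
    seed: int = 0
    mc_error_target: float = diagnostics.MC_ERROR_TARGET

    def __post_init__(self):
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for the BGR diagnostic")
        if self.burn_in <= 0 or self.n_iter <= 0:
            raise ValueError("burn_in and n_iter must be positive")


#: iteration schedules used in the original analyses, plus a quick preset
PRESETS = {
    "poly2_slope": McmcConfig(burn_in=20_000, n_iter=45_000),
    "default": McmcConfig(burn_in=80_000, n_iter=100_000),
    "sn_slope": McmcConfig(burn_in=250_000, n_iter=250_000),
    "sn_asymptote": McmcConfig(burn_in=500_000, n_iter=500_000),
    "test": McmcConfig(burn_in=1000, n_iter=2000),
}


@dataclass
class ImputationModel:
    """Current state of the covariate imputation models.

    Linear models (baseline CD4, baseline log VL on intercept + sex + age)
    with residual variances, and a logistic model for sex on intercept +
    age + baseline CD4 + baseline log VL.
    """

    phi_cd4: np.ndarray
    omega2_cd4: float
    phi_lvl: np.ndarray
    omega2_lvl: float
    phi_sex: np.ndarray


def impute_step(rng, values: dict, masks: dict, model: ImputationModel) -> dict:
    """Draw missing baseline covariates from their imputation models.

    ``values`` maps covariate name -> per-patient array (current completed
    values); ``masks`` maps name -> boolean missing mask.  Baseline CD4 and
    baseline log VL are drawn first from the linear models, then sex from the
    logistic model using the just-imputed values.  Entries whose mask is
    False are returned unchanged.  Returns a new dict of arrays.
    """
    out = {k: np.array(v, dtype=float, copy=True) for k, v in values.items()}
    W = np.column_stack([np.ones_like(out["age"]), out["sex"], out["age"]])
    for name, phi, omega2 in (
        ("baseline_cd4", model.phi_cd4, model.omega2_cd4),
        ("baseline_log_vl", model.phi_lvl, model.omega2_lvl),
    ):
        m = masks.get(name)
        if m is not None and m.any():
            mu = W[m] @ phi
            out[name][m] = mu + np.sqrt(omega2) * rng.standard_normal(m.sum())
    m = masks.get("sex")
    if m is not None and m.any():
        Ws = np.column_stack(
            [
                np.ones(int(m.sum())),
                out["age"][m],
                out["baseline_cd4"][m],
                out["baseline_log_vl"][m],
            ]
        )
        p = expit(Ws @ model.phi_sex)
        out["sex"][m] = (rng.uniform(size=m.sum()) < p).astype(float)
    return out


@dataclass
class FitResult:
    """Posterior draws, summaries and diagnostics of one model fit."""

    spec: ModelSpec
    config: McmcConfig
    draws: dict  # name -> (chains, kept)
    b_draws: np.ndarray  # (chains, kept, n_patients, 2)
    deviance_draws: np.ndarray  # (chains, kept)
    imputed: dict  # target -> {"index": ..., "draws": (chains, kept, k)}
    summaries: pd.DataFrame = None
    cdic: float = np.nan
    pD: float = np.nan
    bgr: pd.Series = None
    mc_error_ok: pd.Series = None
    design: DesignMatrices = None

    def pooled(self, name: str) -> np.ndarray:
        return np.asarray(self.draws[name]).ravel()

    @property
    def beta_names(self):
        return [c for c in self.design.columns]

    def posterior_mean_params(self) -> ModelParameters:
        beta = np.array(
            [self.pooled(f"beta_{c}").mean() for c in self.design.columns]
        )
        b = self.b_draws.reshape(-1, *self.b_draws.shape[2:]).mean(axis=0)
        return ModelParameters(
            beta=beta,
            b=b,
            sigma_eps=float(self.pooled("sigma_eps").mean())
            if "sigma_eps" in self.draws
            else 1.0,
            delta_eps=float(self.pooled("delta_eps").mean())
            if "delta_eps" in self.draws
            else 0.0,
        )


# ---------------------------------------------------------------------------
# sampling utilities


def _truncated_positive_normal(rng, mean, sd):
    """Vectorized draw of N(mean, sd²) truncated to (0, inf)."""
    mean = np.asarray(mean, dtype=float)
    lo = ndtr(-mean / sd)
    u = rng.uniform(lo, 1.0)
    x = mean + sd * ndtri(np.clip(u, 1e-16, 1 - 1e-16))
    return np.maximum(x, 1e-12)


def _draw_invgamma(rng, shape, rate):
    return 1.0 / rng.gamma(shape, 1.0 / rate)


def _sample_mvn_from_precision(rng, P, h):
    """Draw N(P^{-1} h, P^{-1}) via Cholesky of the precision."""
    L = np.linalg.cholesky(P)
    mean = np.linalg.solve(P, h)
    z = rng.standard_normal(len(h))
    return mean + np.linalg.solve(L.T, z)


def _per_patient_sums(x, starts):
    return np.add.reduceat(x, starts)


class _BaseSampler:
    """Shared scaffolding: grouping, imputation models, storage."""

    def __init__(self, design: DesignMatrices, priors, cfg, rng):
        self.design = design
        self.spec = design.spec
        self.cfg = cfg
        self.rng = rng
        self.X = np.array(design.X, copy=True)
        self.Z = design.Z
        self.y = np.array(design.y, copy=True)
        self.group = design.group
        self.n = design.n_patients
        self.N = len(self.y)
        self.starts = np.searchsorted(self.group, np.arange(self.n))
        self.t = design.time
        # per-patient Z'Z entries
        ones = np.ones_like(self.t)
        self.m_i = _per_patient_sums(ones, self.starts)
        self.St_i = _per_patient_sums(self.t, self.starts)
        self.Stt_i = _per_patient_sums(self.t**2, self.starts)

        p = self.X.shape[1]
        self.prior_mean = np.zeros(p)
        self.prior_prec = np.full(p, 1e-6)
        if priors is not None:
            for j, name in enumerate(design.columns):
                self.prior_mean[j] = priors.mean(name)
                self.prior_prec[j] = priors.precision(name)

        self.missing_y = np.isnan(design.y)
        self.masks = {name: m for name, (_, m) in design.missing_cov.items()}
        self.cov_col = {name: c for name, (c, _) in design.missing_cov.items()}
        self._init_baseline_values()
        self._init_imputation_models()

    # -- baseline covariates -------------------------------------------------
    def _init_baseline_values(self):
        bl = self.design.baseline
        self.bvalues = {}
        for name in ("sex", "age", "baseline_cd4", "baseline_log_vl"):
            v = bl[name].to_numpy(dtype=float) if name in bl else np.zeros(self.n)
            v = np.array(v, copy=True)
            m = self.masks.get(name)
            if m is not None and m.any():
                if name == "sex":
                    p_obs = np.nanmean(v)
                    v[m] = (self.rng.uniform(size=m.sum()) < p_obs).astype(float)
                else:
                    v[m] = 0.0  # standardized mean
            if np.isnan(v).any():
                if name == "age":
                    raise ValueError("baseline age must be complete")
                v = np.nan_to_num(v)
            self.bvalues[name] = v
        self._sync_covariate_columns()

    def _sync_covariate_columns(self):
        for name, col in self.cov_col.items():
            self.X[:, col] = self.bvalues[name][self.group]

    def _init_imputation_models(self):
        self.imp = ImputationModel(
            phi_cd4=np.zeros(3),
            omega2_cd4=1.0,
            phi_lvl=np.zeros(3),
            omega2_lvl=1.0,
            phi_sex=np.zeros(4),
        )
        self.sex_step = 0.5
        self._needs_imputation = bool(self.masks)

    def _update_imputation_models(self, iteration, adapting):
        """Conjugate updates for the linear models, RW-Metropolis for sex."""
        rng = self.rng
        W = np.column_stack(
            [np.ones(self.n), self.bvalues["sex"], self.bvalues["age"]]
        )
        WtW = W.T @ W
        for name in ("baseline_cd4", "baseline_log_vl"):
            yv = self.bvalues[name]
            omega2 = self.imp.omega2_cd4 if name == "baseline_cd4" else self.imp.omega2_lvl
            P = PHI_PRIOR_PRECISION * np.eye(3) + WtW / omega2
            h = W.T @ yv / omega2
            phi = _sample_mvn_from_precision(rng, P, h)
            resid = yv - W @ phi
            omega2 = _draw_invgamma(
                rng,
                OMEGA_IG_SHAPE + self.n / 2.0,
                OMEGA_IG_RATE + 0.5 * float(resid @ resid),
            )
            if name == "baseline_cd4":
                self.imp.phi_cd4, self.imp.omega2_cd4 = phi, omega2
            else:
                self.imp.phi_lvl, self.imp.omega2_lvl = phi, omega2

        # logistic model for sex: joint random-walk Metropolis
        Ws = np.column_stack(
            [
                np.ones(self.n),
                self.bvalues["age"],
                self.bvalues["baseline_cd4"],
                self.bvalues["baseline_log_vl"],
            ]
        )
        sex = self.bvalues["sex"]

        def loglik(phi):
            eta = Ws @ phi
            return float(sex @ eta - np.logaddexp(0.0, eta).sum()) - 0.5 * float(
                PHI_PRIOR_PRECISION * phi @ phi
            )

        phi = self.imp.phi_sex
        prop = phi + self.sex_step * rng.standard_normal(4)
        log_a = loglik(prop) - loglik(phi)
        accept = np.log(rng.uniform()) < log_a
        if accept:
            self.imp.phi_sex = prop
        if adapting:
            self.sex_step *= np.exp((float(accept) - 0.234) / (1 + iteration) ** 0.6)

    def _impute_covariates(self, iteration, adapting):
        if not self._needs_imputation:
            return
        self.bvalues = impute_step(self.rng, self.bvalues, self.masks, self.imp)
        self._sync_covariate_columns()
        self._update_imputation_models(iteration, adapting)

    # -- storage --------------------------------------------------------------
    def _storage_names(self):
        raise NotImplementedError

    def run(self):
        cfg = self.cfg
        kept = cfg.n_iter // cfg.thin
        names = self._storage_names()
        store = {nm: np.empty(kept) for nm in names}
        b_store = np.empty((kept, self.n, 2))
        dev_store = np.empty(kept)
        imp_store = {
            name: np.empty((kept, int(mask.sum())))
            for name, mask in self.masks.items()
        }
        if self.missing_y.any():
            imp_store["y"] = np.empty((kept, int(self.missing_y.sum())))

        total = cfg.burn_in + cfg.n_iter
        k = 0
        for it in range(total):
            adapting = it < cfg.burn_in
            self._iterate(it, adapting)
            if it >= cfg.burn_in and (it - cfg.burn_in) % cfg.thin == 0 and k < kept:
                self._record(store, b_store, dev_store, imp_store, k)
                k += 1
        return store, b_store, dev_store, imp_store


class _SlopeSampler(_BaseSampler):
    """Gibbs sampler for the linear (slope) family, Gaussian or skew-normal."""

    def __init__(self, design, priors, cfg, rng):
        super().__init__(design, priors, cfg, rng)
        spec = self.spec
        self.sn_re = spec.re_dist == "skew_normal"
        self.sn_err = spec.error_dist == "skew_normal"

        # initial values, dispersed across chains
        obs = ~self.missing_y
        if self.missing_y.any():
            self.y[self.missing_y] = np.nanmean(self.design.y)
        Xo = self.X
        beta_ls, *_ = np.linalg.lstsq(Xo, self.y, rcond=None)
        scale = np.abs(beta_ls) * 0.5 + 5.0
        self.beta = beta_ls + rng.standard_normal(len(beta_ls)) * scale
        resid = self.y - Xo @ beta_ls
        self.sigma2 = float(np.var(resid)) * float(np.exp(0.5 * rng.standard_normal()))
        self.sigma2 = min(self.sigma2, SIGMA_UNIFORM_UPPER**2 * 0.9)
        self.Sigma_b = np.diag([50.0**2, 20.0**2]) * float(
            np.exp(0.3 * rng.standard_normal())
        )
        self.eta = np.zeros((self.n, 2))
        self.w_b = np.abs(rng.standard_normal((self.n, 2))) if self.sn_re else None
        self.delta_b = 0.5 * rng.standard_normal() if self.sn_re else 0.0
        self.w_eps = np.abs(rng.standard_normal(self.N)) if self.sn_err else None
        self.delta_eps = 0.5 * rng.standard_normal() if self.sn_err else 0.0

    # realized random effects
    @property
    def b(self):
        if self.sn_re:
            return self.delta_b * self.w_b + self.eta
        return self.eta

    def _zb(self, b=None):
        b = self.b if b is None else b
        return b[self.group, 0] + self.t * b[self.group, 1]

    def _iterate(self, it, adapting):
        rng = self.rng
        self._impute_covariates(it, adapting)

        # missing outcomes from the model predictive
        if self.missing_y.any():
            mu = (self.X @ self.beta + self._zb())[self.missing_y]
            if self.sn_err:
                mu = mu + self.delta_eps * self.w_eps[self.missing_y]
            self.y[self.missing_y] = mu + np.sqrt(self.sigma2) * rng.standard_normal(
                int(self.missing_y.sum())
            )

        sig = np.sqrt(self.sigma2)

        # skew-normal error latents and skewness
        if self.sn_err:
            e = self.y - self.X @ self.beta - self._zb()
            prec = 1.0 + self.delta_eps**2 / self.sigma2
            mean = (self.delta_eps * e / self.sigma2) / prec
            self.w_eps = _truncated_positive_normal(rng, mean, 1.0 / np.sqrt(prec))
            prec_d = 1.0 / DELTA_PRIOR_VAR + float(self.w_eps @ self.w_eps) / self.sigma2
            mean_d = float(self.w_eps @ e) / self.sigma2 / prec_d
            self.delta_eps = mean_d + rng.standard_normal() / np.sqrt(prec_d)

        err_off = self.delta_eps * self.w_eps if self.sn_err else 0.0

        # skew-normal RE latents and skewness
        if self.sn_re:
            r = self.y - self.X @ self.beta - err_off
            e = r - (self.eta[self.group, 0] + self.t * self.eta[self.group, 1])
            d = self.delta_b
            # component 1 given component 2
            e1 = e - d * self.t * self.w_b[self.group, 1]
            s1 = _per_patient_sums(e1, self.starts)
            prec1 = 1.0 + d**2 * self.m_i / self.sigma2
            mean1 = (d * s1 / self.sigma2) / prec1
            self.w_b[:, 0] = _truncated_positive_normal(rng, mean1, 1.0 / np.sqrt(prec1))
            # component 2 given (updated) component 1
            e2 = e - d * self.w_b[self.group, 0]
            s2 = _per_patient_sums(self.t * e2, self.starts)
            prec2 = 1.0 + d**2 * self.Stt_i / self.sigma2
            mean2 = (d * s2 / self.sigma2) / prec2
            self.w_b[:, 1] = _truncated_positive_normal(rng, mean2, 1.0 / np.sqrt(prec2))

        # gaussian RE kernel eta_i, conjugate bivariate normal
        r = self.y - self.X @ self.beta - err_off
        if self.sn_re:
            r = r - self.delta_b * (
                self.w_b[self.group, 0] + self.t * self.w_b[self.group, 1]
            )
        Sinv = np.linalg.inv(self.Sigma_b)
        a = Sinv[0, 0] + self.m_i / self.sigma2
        bq = Sinv[0, 1] + self.St_i / self.sigma2
        c = Sinv[1, 1] + self.Stt_i / self.sigma2
        h0 = _per_patient_sums(r, self.starts) / self.sigma2
        h1 = _per_patient_sums(self.t * r, self.starts) / self.sigma2
        det = a * c - bq**2
        mu0 = (c * h0 - bq * h1) / det
        mu1 = (a * h1 - bq * h0) / det
        # cholesky of the 2x2 covariance inv(P), closed form
        C00, C01, C11 = c / det, -bq / det, a / det
        L00 = np.sqrt(C00)
        L10 = C01 / L00
        L11 = np.sqrt(np.maximum(C11 - L10**2, 1e-300))
        z0 = rng.standard_normal(self.n)
        z1 = rng.standard_normal(self.n)
        self.eta[:, 0] = mu0 + L00 * z0
        self.eta[:, 1] = mu1 + L10 * z0 + L11 * z1

        # RE skewness delta_b, conjugate scalar
        if self.sn_re:
            g = self.w_b[self.group, 0] + self.t * self.w_b[self.group, 1]
            e = (
                self.y
                - self.X @ self.beta
                - (self.eta[self.group, 0] + self.t * self.eta[self.group, 1])
                - err_off
            )
            prec_d = 1.0 / DELTA_PRIOR_VAR + float(g @ g) / self.sigma2
            mean_d = float(g @ e) / self.sigma2 / prec_d
            self.delta_b = mean_d + rng.standard_normal() / np.sqrt(prec_d)

        # fixed effects, conjugate
        ytil = self.y - self._zb() - err_off
        XtX = self.X.T @ self.X
        P = np.diag(self.prior_prec) + XtX / self.sigma2
        h = self.prior_prec * self.prior_mean + self.X.T @ ytil / self.sigma2
        self.beta = _sample_mvn_from_precision(rng, P, h)

        # error variance: uniform(0, 100) prior on sigma
        resid = ytil - self.X @ self.beta
        SS = float(resid @ resid)
        for _ in range(20):
            s2 = _draw_invgamma(rng, (self.N - 1) / 2.0, SS / 2.0)
            if s2 < SIGMA_UNIFORM_UPPER**2:
                self.sigma2 = s2
                break

        # random-effects covariance, conjugate inverse-Wishart
        S = np.eye(2) + self.eta.T @ self.eta
        self.Sigma_b = invwishart.rvs(df=IW_DF + self.n, scale=S, random_state=rng)

    def _deviance(self) -> float:
        """-2 x conditional log-likelihood of the *observed* outcomes,
        with imputed covariates plugged in at their current values."""
        from .models import sn_logpdf

        obs = ~self.missing_y
        eta = (self.X @ self.beta + self._zb())[obs]
        ll = sn_logpdf(self.y[obs], eta, np.sqrt(self.sigma2), self.delta_eps)
        return -2.0 * float(np.sum(ll))

    def _storage_names(self):
        names = [f"beta_{c}" for c in self.design.columns]
        names += ["sigma_eps", "sigma0", "sigma1", "rho"]
        if self.sn_re:
            names.append("delta_b")
        if self.sn_err:
            names.append("delta_eps")
        return names

    def _record(self, store, b_store, dev_store, imp_store, k):
        for j, cname in enumerate(self.design.columns):
            store[f"beta_{cname}"][k] = self.beta[j]
        store["sigma_eps"][k] = np.sqrt(self.sigma2)
        store["sigma0"][k] = np.sqrt(self.Sigma_b[0, 0])
        store["sigma1"][k] = np.sqrt(self.Sigma_b[1, 1])
        store["rho"][k] = self.Sigma_b[0, 1] / np.sqrt(
            self.Sigma_b[0, 0] * self.Sigma_b[1, 1]
        )
        if self.sn_re:
            store["delta_b"][k] = self.delta_b
        if self.sn_err:
            store["delta_eps"][k] = self.delta_eps
        b_store[k] = self.b
        dev_store[k] = self._deviance()
        for name, mask in self.masks.items():
            imp_store[name][k] = self.bvalues[name][mask]
        if self.missing_y.any():
            imp_store["y"][k] = self.y[self.missing_y]


class _AsymptoteSampler(_BaseSampler):
    """Metropolis-within-Gibbs sampler for the logistic (asymptote) family."""

    def __init__(self, design, priors, cfg, rng):
        super().__init__(design, priors, cfg, rng)
        self.sn_re = self.spec.re_dist == "skew_normal"
        if self.missing_y.any():
            p0 = float(np.nanmean(self.design.y))
            self.y[self.missing_y] = (
                rng.uniform(size=int(self.missing_y.sum())) < p0
            ).astype(float)

        beta0, cov = self._irls()
        p = len(beta0)
        self.beta = beta0 + np.linalg.cholesky(cov + 1e-8 * np.eye(p)) @ (
            2.0 * rng.standard_normal(p)
        )
        self.beta_chol = np.linalg.cholesky(cov + 1e-8 * np.eye(p))
        self.beta_step = 1.0
        self.Sigma_b = np.diag([2.0**2, 0.7**2]) * float(
            np.exp(0.3 * rng.standard_normal())
        )
        self.eta = np.zeros((self.n, 2))
        self.b_step = np.full(self.n, 0.8)
        self.w_b = np.abs(rng.standard_normal((self.n, 2))) if self.sn_re else None
        self.w_step = np.full(self.n, 0.8) if self.sn_re else None
        self.delta_b = 0.3 * rng.standard_normal() if self.sn_re else 0.0
        self.delta_step = 0.3

    def _irls(self, iters: int = 15):
        """Quick logistic fit (no random effects) for the proposal geometry."""
        X, y = self.X, self.y
        beta = np.zeros(X.shape[1])
        for _ in range(iters):
            eta = X @ beta
            mu = expit(eta)
            w = np.maximum(mu * (1 - mu), 1e-6)
            H = X.T @ (X * w[:, None]) + 1e-6 * np.eye(X.shape[1])
            g = X.T @ (y - mu) - 1e-6 * beta
            step = np.linalg.solve(H, g)
            beta = beta + step
            if np.max(np.abs(step)) < 1e-8:
                break
        cov = np.linalg.inv(H)
        return beta, cov

    @property
    def b(self):
        if self.sn_re:
            return self.delta_b * self.w_b + self.eta
        return self.eta

    def _eta_lin(self, beta=None, b=None):
        beta = self.beta if beta is None else beta
        b = self.b if b is None else b
        return self.X @ beta + b[self.group, 0] + self.t * b[self.group, 1]

    @staticmethod
    def _bern_ll_rows(y, eta):
        return y * eta - np.logaddexp(0.0, eta)

    def _iterate(self, it, adapting):
        rng = self.rng
        self._impute_covariates(it, adapting)

        # missing binary outcomes from the predictive
        if self.missing_y.any():
            p = expit(self._eta_lin()[self.missing_y])
            self.y[self.missing_y] = (
                rng.uniform(size=int(self.missing_y.sum())) < p
            ).astype(float)

        # fixed effects: joint RW Metropolis, IRLS-preconditioned proposal
        prop = self.beta + self.beta_step * (
            self.beta_chol @ rng.standard_normal(len(self.beta))
        )

        def beta_logpost(beta):
            ll = float(np.sum(self._bern_ll_rows(self.y, self._eta_lin(beta=beta))))
            lp = -0.5 * float(
                np.sum(self.prior_prec * (beta - self.prior_mean) ** 2)
            )
            return ll + lp

        log_a = beta_logpost(prop) - beta_logpost(self.beta)
        acc = np.log(rng.uniform()) < log_a
        if acc:
            self.beta = prop
        if adapting:
            self.beta_step *= np.exp((float(acc) - 0.234) / (1 + it) ** 0.6)

        # random-effect kernels eta_i: per-patient RW Metropolis
        Lb = np.linalg.cholesky(self.Sigma_b)
        z = rng.standard_normal((self.n, 2))
        prop_eta = self.eta + self.b_step[:, None] * (z @ Lb.T)
        self._mh_eta(prop_eta, it, adapting)

        if self.sn_re:
            # positive latents: reflective random walk (symmetric proposal)
            zw = rng.standard_normal((self.n, 2))
            prop_w = np.abs(self.w_b + self.w_step[:, None] * zw)
            self._mh_w(prop_w, it, adapting)
            # skewness: scalar RW over the full likelihood
            prop_d = self.delta_b + self.delta_step * rng.standard_normal()
            cur = self._delta_logpost(self.delta_b)
            new = self._delta_logpost(prop_d)
            accd = np.log(rng.uniform()) < new - cur
            if accd:
                self.delta_b = prop_d
            if adapting:
                self.delta_step *= np.exp((float(accd) - 0.3) / (1 + it) ** 0.6)

        # covariance: conjugate inverse-Wishart on the gaussian kernel
        S = np.eye(2) + self.eta.T @ self.eta
        self.Sigma_b = invwishart.rvs(df=IW_DF + self.n, scale=S, random_state=rng)

    def _patient_ll(self, b):
        rows = self._bern_ll_rows(self.y, self._eta_lin(b=b))
        return _per_patient_sums(rows, self.starts)

    def _mh_eta(self, prop_eta, it, adapting):
        rng = self.rng
        Sinv = np.linalg.inv(self.Sigma_b)

        def prior_quad(eta):
            return -0.5 * (
                Sinv[0, 0] * eta[:, 0] ** 2
                + 2 * Sinv[0, 1] * eta[:, 0] * eta[:, 1]
                + Sinv[1, 1] * eta[:, 1] ** 2
            )

        b_cur = self.b
        b_prop = (self.delta_b * self.w_b if self.sn_re else 0.0) + prop_eta
        ll_cur = self._patient_ll(b_cur) + prior_quad(self.eta)
        ll_prop = self._patient_ll(b_prop) + prior_quad(prop_eta)
        acc = np.log(rng.uniform(size=self.n)) < ll_prop - ll_cur
        self.eta[acc] = prop_eta[acc]
        if adapting:
            self.b_step *= np.exp((acc.astype(float) - 0.25) / (1 + it) ** 0.6)

    def _mh_w(self, prop_w, it, adapting):
        rng = self.rng

        def prior_w(w):
            return -0.5 * (w[:, 0] ** 2 + w[:, 1] ** 2)

        b_cur = self.b
        b_prop = self.delta_b * prop_w + self.eta
        ll_cur = self._patient_ll(b_cur) + prior_w(self.w_b)
        ll_prop = self._patient_ll(b_prop) + prior_w(prop_w)
        acc = np.log(rng.uniform(size=self.n)) < ll_prop - ll_cur
        self.w_b[acc] = prop_w[acc]
        if adapting:
            self.w_step *= np.exp((acc.astype(float) - 0.25) / (1 + it) ** 0.6)

    def _delta_logpost(self, delta):
        b = delta * self.w_b + self.eta
        ll = float(np.sum(self._bern_ll_rows(self.y, self._eta_lin(b=b))))
        return ll - 0.5 * delta**2 / DELTA_PRIOR_VAR

    def _deviance(self) -> float:
        obs = ~self.missing_y
        eta = self._eta_lin()[obs]
        return -2.0 * float(np.sum(self._bern_ll_rows(self.y[obs], eta)))

    def _storage_names(self):
        names = [f"beta_{c}" for c in self.design.columns]
        names += ["sigma0", "sigma1", "rho"]
        if self.sn_re:
            names.append("delta_b")
        return names

    def _record(self, store, b_store, dev_store, imp_store, k):
        for j, cname in enumerate(self.design.columns):
            store[f"beta_{cname}"][k] = self.beta[j]
        store["sigma0"][k] = np.sqrt(self.Sigma_b[0, 0])
        store["sigma1"][k] = np.sqrt(self.Sigma_b[1, 1])
        store["rho"][k] = self.Sigma_b[0, 1] / np.sqrt(
            self.Sigma_b[0, 0] * self.Sigma_b[1, 1]
        )
        if self.sn_re:
            store["delta_b"][k] = self.delta_b
        b_store[k] = self.b
        dev_store[k] = self._deviance()
        for name, mask in self.masks.items():
            imp_store[name][k] = self.bvalues[name][mask]
        if self.missing_y.any():
            imp_store["y"][k] = self.y[self.missing_y]


# ---------------------------------------------------------------------------
# public API


def prepare_design(
    cohort: CohortTable,
    spec: ModelSpec,
    detection_limit: float = DEFAULT_DETECTION_LIMIT,
):
    """Exclusions -> standardization -> cVL2 -> design matrices."""
    excl, report = apply_exclusions(cohort, spec.outcome)
    std, info = standardize_covariates(excl)
    cvl = compute_cvl2(std.visits, detection_limit) if spec.cvl_adjusted else None
    design = build_design(std, spec, cvl)
    return design, report, info


def fit(
    spec: ModelSpec,
    design: DesignMatrices,
    priors=None,
    cfg: McmcConfig | None = None,
) -> FitResult:
    """Fit one model by MCMC; returns draws, summaries and diagnostics.

    Chains start from dispersed initial values; per-chain RNG streams are
    spawned deterministically from ``cfg.seed`` so identical configurations
    reproduce bitwise-identical draws.
    """
    cfg = cfg or PRESETS["test"]
    if design.spec != spec:
        design = replace(design, spec=spec)
    sampler_cls = _SlopeSampler if spec.outcome == "slope" else _AsymptoteSampler

    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_chains)
    chain_stores, chain_b, chain_dev, chain_imp = [], [], [], []
    for seq in seeds:
        rng = np.random.default_rng(seq)
        sampler = sampler_cls(design, priors, cfg, rng)
        store, b_store, dev_store, imp_store = sampler.run()
        chain_stores.append(store)
        chain_b.append(b_store)
        chain_dev.append(dev_store)
        chain_imp.append(imp_store)

    draws = {
        name: np.stack([cs[name] for cs in chain_stores])
        for name in chain_stores[0]
    }
    b_draws = np.stack(chain_b)
    dev_draws = np.stack(chain_dev)
    imputed = {}
    for name in chain_imp[0]:
        arr = np.stack([ci[name] for ci in chain_imp])
        if name == "y":
            index = np.nonzero(np.isnan(design.y))[0]
        else:
            index = design.patient_ids[design.missing_cov[name][1]]
        imputed[name] = {"index": index, "draws": arr}

    result = FitResult(
        spec=spec,
        config=cfg,
        draws=draws,
        b_draws=b_draws,
        deviance_draws=dev_draws,
        imputed=imputed,
        design=design,
    )
    result.summaries = diagnostics.summarize_draws(draws)
    result.bgr = diagnostics.bgr_table(draws)
    pooled_ok = {}
    for name, arr in draws.items():
        try:
            pooled_ok[name] = diagnostics.mc_error_check(
                arr.ravel(), cfg.mc_error_target
            )
        except ValueError:
            pooled_ok[name] = False
    result.mc_error_ok = pd.Series(pooled_ok, name="mc_error_ok")
    result.cdic, result.pD = cdic(result)
    return result


def cdic(fit_result: FitResult) -> tuple[float, float]:
    """Conditional DIC from the stored per-draw deviances.

    The plug-in deviance is evaluated at the posterior means of the fixed
    effects, random effects and error parameters; missing covariate cells are
    plugged in at their posterior-mean imputations.
    """
    design = fit_result.design
    params = fit_result.posterior_mean_params()
    if fit_result.imputed:
        X = np.array(design.X, copy=True)
        bl = design.baseline.copy()
        for name, rec in fit_result.imputed.items():
            if name == "y":
                continue
            col, mask = design.missing_cov[name]
            mean_vals = rec["draws"].reshape(-1, rec["draws"].shape[-1]).mean(axis=0)
            filled = bl[name].to_numpy(dtype=float)
            filled[mask] = mean_vals
            X[:, col] = filled[design.group]
        design = replace(design, X=X)
    dev_at_means = -2.0 * log_likelihood(params, design)
    return diagnostics.cdic_from_deviances(
        fit_result.deviance_draws.ravel(), dev_at_means
    )


def summarize(fit_result: FitResult, scale: str = "identity") -> pd.DataFrame:
    """Posterior mean + 95% equal-tail CI table, optionally as odds ratios.

    On the odds-ratio scale only the regression coefficients are reported
    (exponentiating variance parameters is meaningless).
    """
    draws = fit_result.draws
    if scale == "odds_ratio":
        draws = {k: v for k, v in draws.items() if k.startswith("beta_")}
    return diagnostics.summarize_draws(draws, scale=scale)
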