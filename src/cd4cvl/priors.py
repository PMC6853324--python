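"""Informative-prior elicitation from published historical estimates.

A historical study reports a coefficient estimate x̄ and the upper bound of
its 95% confidence interval, uCI = x̄ + 1.96·sqrt(s²/n).  Inverting for the
(within-study) variance gives

    s² = n · ((uCI − x̄) / 1.96)²

and the prior precision is 1/s².  The prior *mean* is the historical estimate
shifted by the change observed when moving from a simple one-covariate mixed
model to the full multivariable model on the current data:

    prior mean = historical + (full − simple).

Elicitation is only defined for the Gaussian polynomial slope models: the
historical studies fitted that form, and for the threshold (asymptote) models
historical studies used different CD4 thresholds, so no informative path
exists there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import yaml

#: normal 97.5% quantile as used in the published arithmetic (not recomputed
#: at higher precision, so elicited cells match the printed values)
Z_975 = 1.96

DEFAULT_VAGUE_MEAN = 0.0
DEFAULT_VAGUE_PRECISION = 1e-6


class ElicitationError(ValueError):
    """Prior elicitation requested where it is not defined."""


@dataclass
class HistoricalEstimate:
    """A published coefficient with its upper 95% CI bound and study size."""

    name: str
    estimate: float
    upper_ci: float
    n: int

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("historical study size must be >= 2")
        if self.upper_ci == self.estimate:
            raise ValueError("upper CI equal to the estimate implies zero variance")


def variance_from_uci(mean: float, upper_ci: float, n: int) -> float:
    """Within-study variance s² implied by a 95% upper confidence bound.

    s² = n·((uCI − x̄)/1.96)²; exactly inverts uCI = x̄ + 1.96·sqrt(s²/n).
    Sign-symmetric: a joint sign flip of (mean, CI bound) leaves s² unchanged.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if upper_ci == mean:
        raise ValueError("upper_ci equals mean: zero variance")
    return n * ((upper_ci - mean) / Z_975) ** 2


def uci_from_variance(mean: float, variance: float, n: int) -> float:
    """Forward formula uCI = x̄ + 1.96·sqrt(s²/n) (round-trip partner)."""
    if variance <= 0:
        raise ValueError("variance must be positive")
    return mean + Z_975 * (variance / n) ** 0.5


def precision_from_variance(variance: float) -> float:
    if not variance > 0:
        raise ValueError("variance must be positive")
    return 1.0 / variance


def adjusted_prior_mean(
    historical_est: float, simple_model_est: float, full_model_est: float
) -> tuple[float, float]:
    """Historical estimate shifted by the simple→full model change.

    Returns (prior_mean, change) with change = full − simple, so the prior
    mean is historical + change.  All three inputs must be on the same
    covariate scale.
    """
    change = full_model_est - simple_model_est
    return historical_est + change, change


@dataclass
class PriorSpec:
    """Per-coefficient Gaussian prior (mean, precision) with vague defaults."""

    entries: dict = field(default_factory=dict)  # name -> (mean, precision)
    vague_mean: float = DEFAULT_VAGUE_MEAN
    vague_precision: float = DEFAULT_VAGUE_PRECISION

    def mean(self, name: str) -> float:
        return self.entries.get(name, (self.vague_mean, self.vague_precision))[0]

    def precision(self, name: str) -> float:
        p = self.entries.get(name, (self.vague_mean, self.vague_precision))[1]
        if not p > 0:
            raise ValueError(f"non-positive precision for '{name}'")
        return p

    def set(self, name: str, mean: float, precision: float) -> None:
        if not precision > 0:
            raise ValueError("precision must be positive")
        self.entries[name] = (float(mean), float(precision))

    def to_yaml(self, path) -> None:
        payload = {
            "vague_mean": self.vague_mean,
            "vague_precision": self.vague_precision,
            "entries": {k: list(v) for k, v in self.entries.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "PriorSpec":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        spec = cls(
            vague_mean=payload.get("vague_mean", DEFAULT_VAGUE_MEAN),
            vague_precision=payload.get("vague_precision", DEFAULT_VAGUE_PRECISION),
        )
        for k, (m, p) in payload.get("entries", {}).items():
            spec.set(k, m, p)
        return spec


def elicit_priors(
    config: Mapping[str, Mapping[str, float]], model_spec=None
) -> PriorSpec:
    """Build an informative PriorSpec from historical + current-model inputs.

    ``config`` maps coefficient name -> dict with keys ``historical``,
    ``upper_ci``, ``n``, ``simple`` (simple-model estimate on current data)
    and ``full`` (full-model estimate).  If ``model_spec`` is given it must be
    a Gaussian polynomial slope model; elicitation for skew-normal, spline or
    asymptote models raises :class:`ElicitationError`.
    """
    if model_spec is not None:
        if getattr(model_spec, "outcome", "slope") != "slope":
            raise ElicitationError(
                "informative priors are not available for asymptote models: "
                "historical studies used different CD4 thresholds"
            )
        if getattr(model_spec, "time_basis", "poly2") != "poly2":
            raise ElicitationError(
                "informative priors are only defined for polynomial time bases"
            )
        if getattr(model_spec, "re_dist", "gaussian") != "gaussian" or (
            getattr(model_spec, "error_dist", "gaussian") != "gaussian"
        ):
            raise ElicitationError(
                "informative priors are only defined for Gaussian models"
            )

    spec = PriorSpec()
    for name, row in config.items():
        est = HistoricalEstimate(
            name=name,
            estimate=float(row["historical"]),
            upper_ci=float(row["upper_ci"]),
            n=int(row["n"]),
        )
        s2 = variance_from_uci(est.estimate, est.upper_ci, est.n)
        mean, _change = adjusted_prior_mean(
            est.estimate, float(row["simple"]), float(row["full"])
        )
        spec.set(name, mean, precision_from_variance(s2))
    return spec
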