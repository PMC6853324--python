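"""Convergence and model-comparison diagnostics.

* Brooks-Gelman-Rubin potential scale reduction across chains, with the
  conventional 1.1 convergence threshold.
* A Monte Carlo error rule: batch-means MC standard error must stay below 5%
  of the posterior standard deviation.
* Conditional DIC helpers: cDIC = mean posterior conditional deviance + pD,
  pD = mean deviance - deviance at the posterior means; model differences
  below ~10 are treated as "no clear choice".
"""

from __future__ import annotations

import numpy as np
import pandas as pd

BGR_THRESHOLD = 1.1
MC_ERROR_TARGET = 0.05
CDIC_CLEAR_DIFFERENCE = 10.0
MIN_BATCHES = 20


def bgr(chains) -> float:
    """Potential scale reduction factor for one parameter.

    ``chains`` is an (m, n) array of m >= 2 equal-length post-burn-in chains.
    Degenerate case: if the within-chain variance is zero the statistic is
    1.0 when the chains agree and inf when they do not.
    """
    draws = np.asarray(chains, dtype=float)
    if draws.ndim != 2 or draws.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    m, n = draws.shape
    if n < 2:
        raise ValueError("chains too short")
    chain_means = draws.mean(axis=1)
    W = draws.var(axis=1, ddof=1).mean()
    B_over_n = chain_means.var(ddof=1)
    if W == 0:
        return 1.0 if B_over_n == 0 else float("inf")
    var_hat = (n - 1) / n * W + B_over_n
    # the population quantity is >= 1; the sample estimate can dip below
    return float(max(np.sqrt(var_hat / W), 1.0))


def bgr_table(draws: dict) -> pd.Series:
    """BGR per parameter for a dict name -> (chains, draws) array."""
    return pd.Series({k: bgr(v) for k, v in draws.items()}, name="bgr")


def mc_error(draws, n_batches: int | None = None) -> float:
    """Batch-means Monte Carlo standard error of the mean of one chain."""
    x = np.asarray(draws, dtype=float).ravel()
    n = x.size
    if n_batches is None:
        n_batches = max(MIN_BATCHES, int(np.sqrt(n)))
    if n < 2 * MIN_BATCHES:
        raise ValueError(
            f"need at least {2 * MIN_BATCHES} draws for batch-means MC error"
        )
    batch = n // n_batches
    means = x[: batch * n_batches].reshape(n_batches, batch).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(n_batches))


def mc_error_check(draws, target: float = MC_ERROR_TARGET) -> bool:
    """True when the MC error is below ``target`` x the posterior sd."""
    x = np.asarray(draws, dtype=float).ravel()
    sd = x.std(ddof=1)
    if sd == 0:
        return True
    return mc_error(x) < target * sd


def equal_tail_interval(draws, prob: float = 0.95) -> tuple[float, float]:
    """Equal-tail credible interval (linear-interpolation percentiles)."""
    a = (1.0 - prob) / 2.0
    lo, hi = np.percentile(np.asarray(draws, dtype=float), [100 * a, 100 * (1 - a)])
    return float(lo), float(hi)


def summarize_draws(draws: dict, scale: str = "identity") -> pd.DataFrame:
    """Posterior mean + 95% equal-tail CI per parameter.

    ``draws`` maps name -> (chains, n) array; chains are pooled.  On the
    ``odds_ratio`` scale the draws are exponentiated *before* summarizing, so
    the reported estimate is the posterior mean odds ratio.
    """
    if scale not in ("identity", "odds_ratio"):
        raise ValueError(f"unknown scale '{scale}'")
    rows = {}
    for name, arr in draws.items():
        x = np.asarray(arr, dtype=float).ravel()
        if scale == "odds_ratio":
            x = np.exp(x)
        lo, hi = equal_tail_interval(x)
        rows[name] = {"mean": float(x.mean()), "ci_lower": lo, "ci_upper": hi}
    return pd.DataFrame.from_dict(rows, orient="index")


def cdic_from_deviances(deviance_draws, deviance_at_means: float) -> tuple[float, float]:
    """cDIC and pD from per-draw conditional deviances.

    cDIC = D̄ + pD with pD = D̄ − D(θ̄, b̄), the deviance evaluated at the
    posterior means of the parameters and random effects.
    """
    dbar = float(np.mean(np.asarray(deviance_draws, dtype=float)))
    pd_eff = dbar - deviance_at_means
    return dbar + pd_eff, pd_eff


def compare_cdic(cdic_a: float, cdic_b: float) -> str:
    """Label a pairwise cDIC comparison.

    Differences below ~10 do not support a clear model choice (and below 5
    none can even be expected); at >= 10 the lower-cDIC model is preferred.
    """
    diff = abs(cdic_a - cdic_b)
    if diff < CDIC_CLEAR_DIFFERENCE:
        return "no clear choice"
    return "clear choice: first" if cdic_a < cdic_b else "clear choice: second"
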