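"""Glomerular adequacy: how many glomeruli must a biopsy contain?

The glomerulosclerosis percentage drives the highest Remuzzi sub-score at
the 50% boundary, but it is estimated from a finite glomeruli sample.  The
criterion here treats the observed sclerotic fraction as a binomial
proportion and asks for the smallest number of glomeruli n* such that a
one-sided test at the boundary p_high (default 0.50) controls

- Type 1 error (declaring the true GS fraction lower than it is) at alpha
  when the true fraction is >= p_high, and
- Type 2 error (declaring it higher than it is) at beta when the true
  fraction is <= p_low (default 0.425),

leaving (p_low, p_high) as an indifference region where more glomeruli
would be needed.  Two modes are provided: the closed-form normal-
approximation sample size

    n* = ceil( ((z_a sqrt(p_h(1-p_h)) + z_b sqrt(p_l(1-p_l))) / (p_h-p_l))^2 )

and an exact binomial search for the smallest (n, c) whose tail
probabilities meet both budgets.  Combining n* with a low quantile of the
observed glomerular density per unit cortex area converts the criterion
into a minimum cortex area to sample.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import binom, norm

from .errors import ConfigError, DataError

logger = logging.getLogger(__name__)


@dataclass
class AdequacyConfig:
    """Error budgets and decision boundaries of the adequacy criterion."""

    alpha: float = 0.15
    beta: float = 0.20
    p_high: float = 0.50
    p_low: float = 0.425
    mode: str = "closed_form"

    def validate(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if not 0 < self.beta < 1:
            raise ConfigError("beta must lie in (0, 1)")
        if not 0 <= self.p_low < self.p_high <= 1:
            raise ConfigError("need 0 <= p_low < p_high <= 1")
        if self.p_high == self.p_low:
            raise ConfigError("p_high must exceed p_low (no indifference margin)")
        if self.mode not in ("closed_form", "exact_binomial"):
            raise ConfigError(f"mode must be closed_form or exact_binomial, got {self.mode!r}")
        if self.alpha >= 0.5 or self.beta >= 0.5:
            warnings.warn("error budget >= 0.5 makes the test degenerate", stacklevel=2)


@dataclass
class AdequacyResult:
    """Outcome of the minimal-count computation (plus optional area advice)."""

    n_star: int
    cutoff: float  # decision fraction t (closed_form) or count c (exact_binomial)
    achieved_alpha: float
    achieved_beta: float
    mode: str
    recommended_area: float | None = None
    recommended_area_rounded: int | None = None
    density_quantile_used: float | None = None
    config: AdequacyConfig = field(default_factory=AdequacyConfig)


def min_glomeruli(config: AdequacyConfig | None = None) -> AdequacyResult:
    """Smallest glomeruli count controlling both error budgets."""
    config = config or AdequacyConfig()
    config.validate()
    a, b, ph, pl = config.alpha, config.beta, config.p_high, config.p_low
    za, zb = norm.isf(a), norm.isf(b)

    if config.mode == "closed_form":
        root = (za * np.sqrt(ph * (1 - ph)) + zb * np.sqrt(pl * (1 - pl))) / (ph - pl)
        n = max(1, int(np.ceil(root**2)))
        # one-sided decision: declare "below the boundary" when the observed
        # fraction falls under t
        t = ph - za * np.sqrt(ph * (1 - ph) / n)
        achieved_alpha = float(norm.cdf((t - ph) * np.sqrt(n / (ph * (1 - ph)))))
        achieved_beta = float(norm.sf((t - pl) * np.sqrt(n / (pl * (1 - pl))))) if pl > 0 else 0.0
        return AdequacyResult(n, float(t), achieved_alpha, achieved_beta, config.mode,
                              config=config)

    # exact binomial: incremental search over n for a feasible integer cutoff c
    for n in range(1, 100_000):
        c = np.arange(-1, n + 1)
        alpha_tail = binom.cdf(c, n, ph)
        beta_tail = binom.sf(c, n, pl)
        feasible = (alpha_tail <= a) & (beta_tail <= b)
        if feasible.any():
            # take the largest feasible c (maximizes power against low GS)
            idx = int(np.flatnonzero(feasible)[-1])
            return AdequacyResult(
                n, float(c[idx]), float(alpha_tail[idx]), float(beta_tail[idx]),
                config.mode, config=config,
            )
    raise ConfigError("no feasible sample size found below 100000")  # pragma: no cover


def max_controlled_p_low(
    n: int, alpha: float = 0.15, beta: float = 0.2, p_high: float = 0.5
) -> float:
    """Largest p_low whose Type 2 error stays within ``beta`` at sample size n.

    Solves z_b sqrt(p(1-p)) = (p_high - p) sqrt(n) - z_a sqrt(p_high(1-p_high))
    for p on [0, p_high] by root bracketing/bisection.
    """
    if n < 1:
        raise ConfigError("n must be >= 1")
    za, zb = norm.isf(alpha), norm.isf(beta)

    def g(p: float) -> float:
        return (p_high - p) * np.sqrt(n) - za * np.sqrt(p_high * (1 - p_high)) \
            - zb * np.sqrt(p * (1 - p))

    if g(0.0) <= 0:
        raise DataError(f"n={n} too small: Type 2 error uncontrollable at any p_low")
    return float(brentq(g, 0.0, p_high, xtol=1e-12))


def density_quantile(per_area_densities, q: float) -> float:
    """Empirical q-quantile (inverse ECDF, lower interpolation) of glomerular
    density per unit cortex area."""
    dens = np.asarray(per_area_densities, dtype=float)
    dens = dens[~np.isnan(dens)]
    if dens.size == 0:
        raise DataError("no density observations (cortex-only slides required)")
    if np.any(dens <= 0):
        raise DataError("densities must be positive")
    if not 0 < q < 1:
        raise ConfigError("quantile q must lie in (0, 1)")
    return float(np.quantile(dens, q, method="inverted_cdf"))


def required_area(n_star: int, density: float) -> float:
    """Cortex area needed to expect ``n_star`` glomeruli at the given density
    (unrounded; round to integer area units for reporting)."""
    if density <= 0:
        raise DataError("density must be > 0")
    return n_star / density


def adequacy_report(
    cohort_derived: pd.DataFrame,
    config: AdequacyConfig | None = None,
    density_q: float = 0.10,
) -> tuple[AdequacyResult, pd.DataFrame]:
    """Adequacy criterion applied to a derived cohort table.

    Returns the filled :class:`AdequacyResult` (with the recommended cortex
    area from the ``density_q`` quantile of observed glomerular density) and
    a per-slide table flagging ``adequate = glomeruli_total >= n_star``.
    """
    config = config or AdequacyConfig()
    result = min_glomeruli(config)
    densities = cohort_derived["glomeruli_per_area"].to_numpy(float)
    d_q = density_quantile(densities, density_q)
    area = required_area(result.n_star, d_q)
    result = replace(
        result,
        recommended_area=area,
        recommended_area_rounded=int(round(area)),
        density_quantile_used=d_q,
    )

    flags = cohort_derived[["donor_id", "kidney_id", "biopsy_id", "stain"]].copy()
    flags["glomeruli_total"] = cohort_derived["glomeruli_total"]
    flags["adequate"] = cohort_derived["glomeruli_total"].to_numpy(float) >= result.n_star
    n_adequate = int(flags["adequate"].sum())
    logger.info(
        "adequacy: n*=%d, %d/%d slides adequate (%.1f%%), recommended area %.0f",
        result.n_star, n_adequate, len(flags), 100 * n_adequate / max(1, len(flags)),
        area,
    )
    return result, flags


def format_report(result: AdequacyResult, flags: pd.DataFrame) -> str:
    n_total = len(flags)
    n_adequate = int(flags["adequate"].sum())
    cfg = result.config
    lines = [
        "Glomerular adequacy criterion",
        f"  mode                : {result.mode}",
        f"  alpha / beta        : {cfg.alpha} / {cfg.beta}",
        f"  boundary / p_low    : {cfg.p_high} / {cfg.p_low}",
        f"  minimal count n*    : {result.n_star}",
        f"  decision cutoff     : {result.cutoff:.4f}",
        f"  achieved alpha/beta : {result.achieved_alpha:.4f} / {result.achieved_beta:.4f}",
    ]
    if result.recommended_area is not None:
        lines += [
            f"  density quantile    : {result.density_quantile_used:.4f} per area unit",
            f"  recommended area    : {result.recommended_area_rounded} area units"
            f" ({result.recommended_area:.2f} unrounded)",
        ]
    lines.append(
        f"  adequate slides     : {n_adequate}/{n_total}"
        f" ({100 * n_adequate / max(1, n_total):.1f}%)"
    )
    return "\n".join(lines)
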