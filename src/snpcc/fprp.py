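"""False-positive report probability (FPRP).

FPRP = alpha * (1 - pi) / (alpha * (1 - pi) + (1 - beta) * pi), where alpha
is the observed two-sided p (kept at full precision), 1 - beta the power to
detect a preset target odds ratio (1.50 for risk effects, 0.67 for
protective ones), and pi the prior probability of a true association.  An
association is "noteworthy" when FPRP at the headline prior falls below the
preset threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

from scipy import stats

from .association import EffectEstimate, Z975
from .data_model import TwoByTwo
from .errors import ValidationError

DEFAULT_PRIORS = (0.25, 0.1, 0.01, 0.001, 0.0001)


@dataclass(frozen=True)
class FprpConfig:
    priors: tuple[float, ...] = DEFAULT_PRIORS
    threshold: float = 0.2
    headline_prior: float = 0.1
    or1_risk: float = 1.50
    or1_protective: float = 0.67
    power_alpha: float = 0.05
    se_source: str = "ci"  # or "counts"

    def __post_init__(self) -> None:
        if not all(0 < p < 1 for p in self.priors):
            raise ValidationError("priors must lie in (0, 1)")
        if any(b <= a for a, b in zip(self.priors[1:], self.priors[:-1])):
            pass
        if list(self.priors) != sorted(self.priors, reverse=True):
            raise ValidationError("priors must be strictly decreasing")
        if not 0 < self.threshold < 1:
            raise ValidationError("threshold must lie in (0, 1)")
        if self.se_source not in ("ci", "counts"):
            raise ValidationError("se_source must be 'ci' or 'counts'")


@dataclass(frozen=True)
class FprpResult:
    estimate: EffectEstimate
    alpha: float
    power: float
    fprp_by_prior: Mapping[float, float]
    noteworthy: bool


def se_from_ci(ci_low: float, ci_high: float) -> float:
    """Reconstruct the log-OR SE from a 95% CI: (ln U - ln L) / (2 * 1.96)."""
    if not 0 < ci_low < ci_high:
        raise ValidationError(f"need 0 < L < U, got ({ci_low}, {ci_high})")
    return (math.log(ci_high) - math.log(ci_low)) / (2 * Z975)


def power_detect(or1: float, se_log: float, alpha: float) -> float:
    """Two-sided normal power to detect ``or1`` at significance ``alpha``
    given the estimate's log-OR standard error."""
    if se_log <= 0:
        raise ValidationError("se_log must be positive")
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    z = float(stats.norm.ppf(1 - alpha / 2))
    shift = abs(math.log(or1)) / se_log
    return float(stats.norm.sf(z - shift) + stats.norm.cdf(-z - shift))


def fprp_value(alpha: float, power: float, prior: float) -> float:
    """Exact evaluation of the FPRP formula."""
    for name, v in (("alpha", alpha), ("power", power), ("prior", prior)):
        if not 0 < v < 1:
            raise ValidationError(f"{name} must lie in (0, 1), got {v}")
    num = alpha * (1 - prior)
    return num / (num + power * prior)


def fprp_grid(
    estimate: EffectEstimate,
    cfg: FprpConfig = FprpConfig(),
    table: TwoByTwo | None = None,
    power: float | None = None,
) -> FprpResult:
    """FPRP across the prior grid for one effect estimate.

    alpha is the estimate's two-sided p at full precision.  Power is
    computed from the target OR matching the effect direction (>= 1 -> 1.50,
    < 1 -> 0.67) and the log-OR SE — from the CI by default, or from Woolf
    cell counts when ``cfg.se_source == "counts"`` (requires ``table``).  An
    externally supplied ``power`` (e.g. a published value) overrides both.
    """
    alpha = estimate.p
    if power is None:
        if cfg.se_source == "counts":
            if table is None:
                raise ValidationError("se_source='counts' needs the 2x2 table")
            cells = (table.a, table.b, table.c, table.d)
            if any(c == 0 for c in cells):
                raise ValidationError("zero cell; cannot derive SE from counts")
            se = math.sqrt(sum(1.0 / c for c in cells))
        else:
            se = se_from_ci(estimate.ci_low, estimate.ci_high)
        or1 = cfg.or1_risk if estimate.or_hat >= 1 else cfg.or1_protective
        power = power_detect(or1, se, cfg.power_alpha)
    grid = {prior: fprp_value(alpha, power, prior) for prior in cfg.priors}
    headline = fprp_value(alpha, power, cfg.headline_prior)
    return FprpResult(estimate, alpha, power, grid, headline < cfg.threshold)
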