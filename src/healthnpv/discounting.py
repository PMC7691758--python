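"""Discount-rate construction for each numeraire.

The consumption rate follows the Ramsey rule r_c = delta + eta * g_c.  The
health rate is anchored on the principal's real borrowing/saving rate r_s
net of expected growth in the health opportunity-cost threshold,
r_h = r_s - gk_h (or (1+r_s)/(1+gk_h) - 1 under the exact multiplicative
convention).  Dual (differential) rates for ICER-style reporting fold
parameter growth into the cost discount rate.  Persistent uncertainty about
consumption growth produces a declining, certainty-equivalent term structure;
an unrecoverable-catastrophe hazard and an additive project risk premium can
be layered onto any schedule.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass

import numpy as np

from .core import Convention, DiscountSpec, GrowthSpec, ValidationError

__all__ = [
    "RateSchedule",
    "DualMode",
    "ramsey_rate",
    "health_rate",
    "dual_cost_rate",
    "declining_schedule",
    "apply_catastrophic_hazard",
    "risk_adjusted_schedule",
    "consumption_schedule",
    "health_schedule",
    "icer_cost_schedule",
    "HORIZON_ADVISORY_PERIODS",
]

logger = logging.getLogger(__name__)

#: Horizon beyond which a constant consumption rate built from point growth
#: earns an advisory: under growth uncertainty, scenario-based declining
#: rates are recommended for long horizons.
HORIZON_ADVISORY_PERIODS = 30


@dataclass(frozen=True)
class RateSchedule:
    """Per-period forward rates and cumulative discount factors.

    ``forward[t-1]`` is the one-period rate over period t; ``factor(t)``
    (= D[t]) is the value at decision time of one unit accruing at the end
    of period t, D[t] = prod_{s<=t} 1/(1+forward[s]).  ``term_rates``, when
    present, holds the annualised term rates R(t) = D[t]**(-1/t) - 1 of a
    declining schedule.
    """

    forward: np.ndarray
    term_rates: np.ndarray | None = None

    def __post_init__(self):
        fwd = np.asarray(self.forward, dtype=float)
        if fwd.ndim != 1 or len(fwd) < 1:
            raise ValidationError("forward rates must be a non-empty 1-d series")
        if np.any(fwd <= -1):
            raise ValidationError("forward rates must exceed -1")
        object.__setattr__(self, "forward", fwd)
        if self.term_rates is not None:
            object.__setattr__(
                self, "term_rates", np.asarray(self.term_rates, dtype=float)
            )

    @classmethod
    def flat(cls, rate: float, T: int) -> "RateSchedule":
        if T < 1:
            raise ValidationError(f"T must be >= 1, got {T}")
        return cls(np.full(T, float(rate)))

    @property
    def T(self) -> int:
        return len(self.forward)

    @property
    def factors(self) -> np.ndarray:
        """D[t] for t = 1..T as a length-T array (index t-1)."""
        return np.cumprod(1.0 / (1.0 + self.forward))


def ramsey_rate(delta: float, eta: float, g_c: float) -> float:
    """Social time preference rate for consumption: r_c = delta + eta * g_c."""
    if delta < 0:
        raise ValidationError(f"delta must be >= 0, got {delta}")
    if not (eta > 0):
        raise ValidationError(f"eta must be > 0, got {eta}")
    return delta + eta * g_c


def health_rate(
    r_s: float,
    gk_h: float,
    convention: Convention = Convention.EXACT_MULTIPLICATIVE,
) -> float:
    """Social time preference rate for health.

    Growth in the threshold k_h means a unit of future health is worth less
    in current health-care resources, so r_h = r_s - gk_h (approximate) or
    (1+r_s)/(1+gk_h) - 1 (exact).
    """
    if not (gk_h > -1):
        raise ValidationError(f"gk_h must exceed -1, got {gk_h}")
    if Convention(convention) is Convention.APPROX_SUBTRACTIVE:
        return r_s - gk_h
    return (1.0 + r_s) / (1.0 + gk_h) - 1.0


class DualMode(str, enum.Enum):
    """Which growth adjustments a dual (differential) rate embeds."""

    ICER_COSTS = "icer_costs"  # r_h + gk_h: health-care costs in ICER reporting
    CONSUMPTION_HEALTH = "consumption_health"  # r_c - gV_h: health effects
    CONSUMPTION_COSTS = "consumption_costs"  # r_c - gV_h + gk_h: health-care costs


def dual_cost_rate(
    base_rate: float,
    gk_h: float = 0.0,
    gV_h: float = 0.0,
    mode: DualMode = DualMode.ICER_COSTS,
    convention: Convention = Convention.EXACT_MULTIPLICATIVE,
) -> float:
    """Dual-discounting rate embedding parameter growth in the discount rate.

    ``base_rate`` is r_h for ``ICER_COSTS`` and r_c for the consumption
    modes.  Dual discounting is reproduced for familiarity but the extensive
    per-period accounting is the recommended primary output.
    """
    mode = DualMode(mode)
    exact = Convention(convention) is Convention.EXACT_MULTIPLICATIVE
    if mode is DualMode.ICER_COSTS:
        if exact:
            return (1.0 + base_rate) * (1.0 + gk_h) - 1.0
        return base_rate + gk_h
    if mode is DualMode.CONSUMPTION_HEALTH:
        if exact:
            return (1.0 + base_rate) / (1.0 + gV_h) - 1.0
        return base_rate - gV_h
    if mode is DualMode.CONSUMPTION_COSTS:
        if exact:
            return (1.0 + base_rate) * (1.0 + gk_h) / (1.0 + gV_h) - 1.0
        return base_rate - gV_h + gk_h
    raise ValidationError(f"unknown dual-rate mode: {mode}")  # pragma: no cover


def declining_schedule(
    scenarios, delta: float, eta: float, T: int
) -> RateSchedule:
    """Certainty-equivalent declining term structure over growth scenarios.

    Each scenario (g_i, p_i) implies a Ramsey rate r_i = delta + eta * g_i.
    The certainty-equivalent factor at term t is the expected discount
    factor F(t) = sum_i p_i (1+r_i)^-t, and the annualised term rate is
    R(t) = F(t)^(-1/t) - 1.  Because low-growth scenarios dominate F(t) at
    long horizons, R(t) declines towards the minimum scenario rate — the
    precautionary-saving effect of persistent growth uncertainty.
    """
    scenarios = [(float(g), float(p)) for g, p in scenarios]
    if len(scenarios) == 0:
        raise ValidationError("scenario set must be non-empty")
    probs = np.array([p for _, p in scenarios])
    if np.any(probs <= 0) or abs(probs.sum() - 1.0) > 1e-9:
        raise ValidationError("scenario probabilities must be positive and sum to 1")
    if T < 1:
        raise ValidationError(f"T must be >= 1, got {T}")
    rates = np.array([ramsey_rate(delta, eta, g) for g, _ in scenarios])
    t = np.arange(1, T + 1, dtype=float)
    # F(t) = sum_i p_i (1+r_i)^-t, evaluated in log space for long horizons
    F = np.exp(
        np.logaddexp.reduce(
            np.log(probs)[:, None] - t[None, :] * np.log1p(rates)[:, None], axis=0
        )
    )
    term = F ** (-1.0 / t) - 1.0
    forward = np.empty(T)
    forward[0] = 1.0 / F[0] - 1.0
    if T > 1:
        forward[1:] = F[:-1] / F[1:] - 1.0
    return RateSchedule(forward, term_rates=term)


def apply_catastrophic_hazard(schedule: RateSchedule, p_cat: float) -> RateSchedule:
    """Thin every discount factor by per-period survival (1 - p_cat).

    D[t] becomes D[t] * (1-p_cat)^t, i.e. each forward rate r becomes
    (1+r)/(1-p_cat) - 1.  Only hazards of truly unrecoverable events belong
    here (recoverable shocks are macroeconomic or project risk).
    """
    if not (0 <= p_cat < 1):
        raise ValidationError(f"p_cat must lie in [0, 1), got {p_cat}")
    if p_cat == 0:
        return RateSchedule(schedule.forward.copy(), term_rates=None)
    return RateSchedule(
        (1.0 + schedule.forward) / (1.0 - p_cat) - 1.0,
        term_rates=None,
    )


def risk_adjusted_schedule(schedule: RateSchedule, beta_premium: float) -> RateSchedule:
    """Add a project-specific risk premium to every forward rate.

    Positive for procyclical projects (payoffs co-move with consumption
    growth), negative for countercyclical ones, which raises present value.
    """
    adjusted = schedule.forward + beta_premium
    if np.any(adjusted <= -1):
        raise ValidationError("risk adjustment drives a forward rate to -1 or below")
    return RateSchedule(adjusted, term_rates=None)


def consumption_schedule(discount: DiscountSpec, T: int) -> RateSchedule:
    """Build the consumption-numeraire schedule from a :class:`DiscountSpec`.

    Point growth yields a flat Ramsey rate; a scenario set yields the
    declining certainty-equivalent structure.  The catastrophic hazard and
    any project risk premium are applied on top, in that order.
    """
    if discount.has_scenarios:
        schedule = declining_schedule(discount.growth, discount.delta, discount.eta, T)
    else:
        if T > HORIZON_ADVISORY_PERIODS:
            logger.warning(
                "horizon of %d periods exceeds %d with a constant consumption "
                "rate from point growth; scenario-based declining rates are "
                "recommended for long horizons under growth uncertainty",
                T,
                HORIZON_ADVISORY_PERIODS,
            )
        schedule = RateSchedule.flat(
            ramsey_rate(discount.delta, discount.eta, discount.point_growth), T
        )
    if discount.p_cat > 0:
        schedule = apply_catastrophic_hazard(schedule, discount.p_cat)
    if discount.beta_premium != 0:
        schedule = risk_adjusted_schedule(schedule, discount.beta_premium)
    return schedule


def health_schedule(
    r_s: float,
    gk_h: float,
    T: int,
    convention: Convention = Convention.EXACT_MULTIPLICATIVE,
) -> RateSchedule:
    """Flat schedule at the health time-preference rate r_h."""
    return RateSchedule.flat(health_rate(r_s, gk_h, convention), T)


def icer_cost_schedule(
    r_s: float,
    gk_h: float,
    T: int,
    convention: Convention = Convention.EXACT_MULTIPLICATIVE,
) -> RateSchedule:
    """Dual cost schedule for ICER reporting, aligned with period-1 bases.

    Parameter paths are anchored at period 1 (k_h[1] is the base, growth
    applies from period 2), so the threshold-growth adjustment enters the
    cost discount factor with exponent t-1: the first forward rate is r_h
    and subsequent forward rates are (1+r_h)(1+gk_h) - 1 under the exact
    convention.  This makes "ICER < k_h1" coincide exactly with a positive
    discounted net health benefit.  Under the approximate convention the
    flat textbook rate r_h + gk_h is used throughout.
    """
    convention = Convention(convention)
    r_h = health_rate(r_s, gk_h, convention)
    dual = dual_cost_rate(r_h, gk_h=gk_h, mode=DualMode.ICER_COSTS, convention=convention)
    if convention is Convention.APPROX_SUBTRACTIVE:
        return RateSchedule.flat(dual, T)
    forward = np.full(T, dual)
    forward[0] = r_h
    return RateSchedule(forward)


def dual_rates_from_growth(
    discount: DiscountSpec, growth: GrowthSpec
) -> dict[str, float]:
    """Scalar dual rates implied by a country's growth spec (for reporting)."""
    convention = discount.convention
    r_c = ramsey_rate(discount.delta, discount.eta, discount.point_growth)
    r_h = health_rate(discount.r_s, growth.gk_h, convention)
    return {
        "r_c": r_c,
        "r_h": r_h,
        "icer_costs": dual_cost_rate(
            r_h, gk_h=growth.gk_h, mode=DualMode.ICER_COSTS, convention=convention
        ),
        "consumption_health": dual_cost_rate(
            r_c, gV_h=growth.gV_h, mode=DualMode.CONSUMPTION_HEALTH, convention=convention
        ),
        "consumption_costs": dual_cost_rate(
            r_c,
            gk_h=growth.gk_h,
            gV_h=growth.gV_h,
            mode=DualMode.CONSUMPTION_COSTS,
            convention=convention,
        ),
    }
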