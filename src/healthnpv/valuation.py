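"""Present values, decision statistics and multi-country aggregation.

The country NPV is the discounted sum of the equivalent net consumption
effects at the country's consumption rate; because every parameter (k_h,
k_c, V_h, g_c, hence r_c) is country specific, a multi-country project's
global NPV is the sum of country-specific NPVs, never a common-rate
discounting of pooled effects.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import (
    Convention,
    CountryContext,
    DiscountSpec,
    EffectStream,
    GrowthSpec,
    ParameterPath,
    Project,
    ValidationError,
    validate_stream,
)
from .discounting import (
    DualMode,
    RateSchedule,
    consumption_schedule,
    dual_cost_rate,
    health_schedule,
    icer_cost_schedule,
    ramsey_rate,
)
from .numeraires import (
    equivalent_consumption_effect,
    equivalent_health_effect,
    equivalent_resource_effect,
    extensive_table,
    net_health_benefit,
)

__all__ = [
    "Verdict",
    "Quadrant",
    "UndefinedICERError",
    "IcerResult",
    "AppraisalResult",
    "GlobalResult",
    "present_value",
    "decision_net_health",
    "icer_dual",
    "npv_country",
    "npv_global",
]


class Verdict(str, enum.Enum):
    ADOPT = "adopt"
    REJECT = "reject"
    INDIFFERENT = "indifferent"


class Quadrant(str, enum.Enum):
    """Cost-effectiveness plane location of the discounted (cost, health) pair."""

    TRADEOFF_NE = "more_effective_more_costly"
    DOMINANT = "more_effective_cost_saving"
    DOMINATED = "less_effective_more_costly"
    TRADEOFF_SW = "less_effective_cost_saving"


class UndefinedICERError(ValidationError):
    """Discounted health effect is zero; report net benefits instead of a ratio."""


def present_value(series, schedule: RateSchedule) -> float:
    """Value at decision time of a per-period series: sum_t series[t] * D[t]."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 1 or len(series) != schedule.T:
        raise ValidationError(
            f"series length {series.shape} does not match schedule horizon {schedule.T}"
        )
    return float(series @ schedule.factors)


def _verdict(value: float) -> Verdict:
    if value > 0:
        return Verdict.ADOPT
    if value < 0:
        return Verdict.REJECT
    return Verdict.INDIFFERENT


def decision_net_health(
    stream: EffectStream, params: ParameterPath, schedule: RateSchedule
) -> tuple[Verdict, float]:
    """Adopt/reject/indifferent by the sign of the discounted net health benefit.

    The verdict is the exact sign of the present value; no tolerance band is
    applied — rounding is the caller's decision.
    """
    pv = present_value(net_health_benefit(stream, params), schedule)
    return _verdict(pv), pv


@dataclass(frozen=True)
class IcerResult:
    """An ICER with its threshold comparison and plane quadrant.

    ``value`` is PV(health-care costs at the dual cost schedule) divided by
    PV(health effects at r_h); it is compared against the period-1 threshold
    k_h1.  In the dominant/dominated quadrants the ratio is reported with an
    explicit quadrant label rather than interpreted as a price.
    """

    value: float
    threshold: float
    quadrant: Quadrant
    verdict: Verdict
    pv_health: float
    pv_cost: float


def icer_dual(
    stream: EffectStream,
    params: ParameterPath,
    discount: DiscountSpec,
    gk_h: float,
) -> IcerResult:
    """ICER under dual discounting, compared against the period-1 threshold.

    Health effects are discounted at r_h and health-care costs at a rate
    additionally embedding threshold growth, so that the comparison with
    k_h1 reproduces the net-health decision (exactly so under the exact
    multiplicative convention).  Dual discounting is provided for
    familiarity; the extensive tables are the recommended primary output.
    """
    validate_stream(stream)
    T = stream.T
    h_sched = health_schedule(discount.r_s, gk_h, T, discount.convention)
    c_sched = icer_cost_schedule(discount.r_s, gk_h, T, discount.convention)
    pv_h = present_value(stream.delta_h, h_sched)
    pv_c = present_value(stream.delta_c_h, c_sched)
    if pv_h == 0.0:
        raise UndefinedICERError(
            "discounted health effect is zero; the ICER is undefined — report "
            "discounted net benefits instead"
        )
    k_h1 = float(params.k_h[0])
    icer = pv_c / pv_h
    if pv_h > 0 and pv_c > 0:
        quadrant = Quadrant.TRADEOFF_NE
        verdict = _verdict(k_h1 - icer)
    elif pv_h > 0:
        quadrant = Quadrant.DOMINANT
        verdict = Verdict.ADOPT
    elif pv_c >= 0:
        quadrant = Quadrant.DOMINATED
        verdict = Verdict.REJECT
    else:
        # Less effective but cost saving: adopt only if the resources freed
        # buy more health elsewhere than is given up, i.e. ICER > k_h1.
        quadrant = Quadrant.TRADEOFF_SW
        verdict = _verdict(icer - k_h1)
    return IcerResult(
        value=icer,
        threshold=k_h1,
        quadrant=quadrant,
        verdict=verdict,
        pv_health=pv_h,
        pv_cost=pv_c,
    )


@dataclass(frozen=True)
class AppraisalResult:
    """Full appraisal of one country's stream.

    The country NPV is the present value of the equivalent net consumption
    effects at the country's consumption schedule and always equals the sum
    of ``discounted_contributions``.  The extensive per-period table and the
    echoed parameters make every number re-derivable.
    """

    country_id: str
    currency: str
    convention: Convention
    npv: float
    discounted_contributions: np.ndarray
    discount_factors: np.ndarray
    pv_equivalent_consumption: float
    pv_equivalent_health: float | None
    pv_equivalent_resource: float | None
    pv_net_health: float | None
    verdict: Verdict
    icer: IcerResult | None
    rates: dict
    table: pd.DataFrame
    defaults_applied: tuple = ()
    notes: tuple = ("end-of-period accrual; discount factor (1+r)^-t",)


def npv_country(stream: EffectStream, context: CountryContext) -> AppraisalResult:
    """Appraise one country's stream under its own parameters and rates.

    Always computes the consumption-numeraire NPV.  When the context carries
    a :class:`~healthnpv.core.GrowthSpec`, also reports the dual-rate present
    values of the equivalent health and resource effects, the net-health
    decision at r_h, and the dual-discounted ICER.
    """
    validate_stream(stream)
    T = stream.T
    params = context.params
    if params.T < T:
        raise ValidationError(
            f"country {context.id!r}: parameter path covers {params.T} periods "
            f"but stream has {T}"
        )
    discount = context.discount
    c_sched = consumption_schedule(discount, T)
    eq_c = equivalent_consumption_effect(stream, params)
    contributions = eq_c * c_sched.factors
    npv = float(contributions.sum())

    rates: dict = {
        "convention": discount.convention.value,
        "r_c": (
            None
            if discount.has_scenarios
            else ramsey_rate(discount.delta, discount.eta, discount.point_growth)
        ),
        "r_s": discount.r_s,
        "p_cat": discount.p_cat,
        "beta_premium": discount.beta_premium,
    }

    pv_eq_h = pv_eq_r = pv_nhb = None
    icer = None
    growth = context.growth
    if growth is not None:
        conv = discount.convention
        h_sched = health_schedule(discount.r_s, growth.gk_h, T, conv)
        _, pv_nhb = decision_net_health(stream, params, h_sched)
        r_c = rates["r_c"]
        if r_c is not None:
            pv_eq_h = present_value(
                equivalent_health_effect(stream, params),
                RateSchedule.flat(
                    dual_cost_rate(
                        r_c, gV_h=growth.gV_h, mode=DualMode.CONSUMPTION_HEALTH,
                        convention=conv,
                    ),
                    T,
                ),
            )
            pv_eq_r = present_value(
                equivalent_resource_effect(stream, params),
                RateSchedule.flat(
                    dual_cost_rate(
                        r_c,
                        gk_h=growth.gk_h,
                        gV_h=growth.gV_h,
                        mode=DualMode.CONSUMPTION_COSTS,
                        convention=conv,
                    ),
                    T,
                ),
            )
        rates["r_h"] = float(h_sched.forward[0])
        rates["gk_h"] = growth.gk_h
        rates["gV_h"] = growth.gV_h
        try:
            icer = icer_dual(stream, params, discount, growth.gk_h)
        except UndefinedICERError:
            icer = None

    return AppraisalResult(
        country_id=context.id,
        currency=context.currency,
        convention=discount.convention,
        npv=npv,
        discounted_contributions=contributions,
        discount_factors=c_sched.factors,
        pv_equivalent_consumption=npv,
        pv_equivalent_health=pv_eq_h,
        pv_equivalent_resource=pv_eq_r,
        pv_net_health=pv_nhb,
        verdict=_verdict(npv),
        icer=icer,
        rates=rates,
        table=extensive_table(stream, params),
        defaults_applied=context.defaults_applied,
    )


@dataclass(frozen=True)
class GlobalResult:
    """Global NPV of a multi-country project with its country breakdown."""

    npv: float
    by_country: Mapping[str, AppraisalResult]
    currency: str

    @property
    def country_npvs(self) -> dict[str, float]:
        return {cid: res.npv for cid, res in self.by_country.items()}


def npv_global(
    project: Project, contexts: Mapping[str, CountryContext]
) -> GlobalResult:
    """Sum country-specific NPVs into the project's global NPV.

    Every country in the project must have a context, and all contexts must
    declare the same currency label — no exchange-rate conversion is
    performed, so mismatched labels are refused rather than summed.
    """
    missing = [cid for cid in project.streams if cid not in contexts]
    if missing:
        raise ValidationError(
            [f"no country context supplied for {cid!r}" for cid in missing]
        )
    currencies = {contexts[cid].currency for cid in project.streams}
    if len(currencies) > 1:
        raise ValidationError(
            "cannot sum NPVs across currencies without conversion: "
            f"found labels {sorted(currencies)}"
        )
    results = {
        cid: npv_country(stream, contexts[cid])
        for cid, stream in project.streams.items()
    }
    total = float(sum(res.npv for res in results.values()))
    return GlobalResult(npv=total, by_country=results, currency=currencies.pop())
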