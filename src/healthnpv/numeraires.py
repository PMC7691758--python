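"""Column algebra converting project effects between numeraires.

Every operation is a per-period identity.  Health-care costs displace health
elsewhere in the system (``delta_c_h / k_h``) and net production in the wider
economy (``k_c * delta_c_h``); health gains can equivalently be expressed as
the health-care resources that would have produced them (``k_h * delta_h``)
or as their consumption value (``V_h * delta_h``).  Composing these gives the
net effect of a project in any one of three numeraires — health, health-care
resources, or consumption — each to be discounted at its matched rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import EffectStream, ParameterPath, ValidationError, validate_stream

__all__ = [
    "health_opportunity_loss",
    "net_health_benefit",
    "net_consumption_cost",
    "equivalent_resources",
    "consumption_value_columns",
    "equivalent_consumption_effect",
    "equivalent_health_effect",
    "equivalent_resource_effect",
    "shadow_price_other_sector",
    "extensive_table",
    "EXTENSIVE_COLUMNS",
]


def _check_lengths(stream: EffectStream, params: ParameterPath) -> None:
    if params.T < stream.T:
        raise ValidationError(
            f"parameter path covers {params.T} periods but stream has {stream.T}"
        )


def _clip(params: ParameterPath, T: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    return params.k_h[:T], params.k_c[:T], params.V_h[:T]


def health_opportunity_loss(delta_c_h, k_h) -> np.ndarray:
    """Health forgone elsewhere per period: delta_c_h / k_h.

    Spending on the project displaces other health-care activity; dividing
    the incremental cost by the threshold k_h (cost per health unit at the
    margin) converts it into health units lost.  A cost saving (negative
    delta_c_h) is a health gain elsewhere.
    """
    delta_c_h = np.asarray(delta_c_h, dtype=float)
    k_h = np.asarray(k_h, dtype=float)
    if np.any(k_h <= 0):
        raise ValidationError("k_h must be strictly positive in every period")
    return delta_c_h / k_h


def net_health_benefit(stream: EffectStream, params: ParameterPath) -> np.ndarray:
    """Per-period net health benefit: delta_h - delta_c_h / k_h."""
    validate_stream(stream)
    _check_lengths(stream, params)
    k_h, _, _ = _clip(params, stream.T)
    return stream.delta_h - health_opportunity_loss(stream.delta_c_h, k_h)


def net_consumption_cost(stream: EffectStream, params: ParameterPath) -> np.ndarray:
    """Per-period net consumption cost: delta_c_c + k_c * delta_c_h.

    Direct consumption costs plus the net production forgone because
    health-care expenditure was displaced.
    """
    validate_stream(stream)
    _check_lengths(stream, params)
    _, k_c, _ = _clip(params, stream.T)
    if np.any(k_c < 0):
        raise ValidationError("k_c must be non-negative in every period")
    return stream.delta_c_c + k_c * stream.delta_c_h


def equivalent_resources(
    stream: EffectStream, params: ParameterPath
) -> tuple[np.ndarray, np.ndarray]:
    """Health-care-resource numeraire: benefits k_h * delta_h, costs delta_c_h."""
    validate_stream(stream)
    _check_lengths(stream, params)
    k_h, _, _ = _clip(params, stream.T)
    if np.any(k_h <= 0):
        raise ValidationError("k_h must be strictly positive in every period")
    return k_h * stream.delta_h, stream.delta_c_h.copy()


def consumption_value_columns(
    stream: EffectStream, params: ParameterPath
) -> tuple[np.ndarray, np.ndarray]:
    """Consumption value of health gained and lost.

    Benefits V_h * delta_h; costs V_h * (delta_c_h / k_h), the consumption
    value of the health displaced by the project's health-care costs.
    """
    validate_stream(stream)
    _check_lengths(stream, params)
    k_h, _, V_h = _clip(params, stream.T)
    if np.any(V_h <= 0):
        raise ValidationError("V_h must be strictly positive in every period")
    return V_h * stream.delta_h, V_h * health_opportunity_loss(stream.delta_c_h, k_h)


def equivalent_consumption_effect(
    stream: EffectStream, params: ParameterPath
) -> np.ndarray:
    """Net effect in the consumption numeraire per period.

    V_h * (delta_h - delta_c_h/k_h) - (delta_c_c + k_c * delta_c_h);
    positive values are net consumption-equivalent benefits.
    """
    _, _, V_h = _clip(params, stream.T)
    if np.any(V_h <= 0):
        raise ValidationError("V_h must be strictly positive in every period")
    return V_h * net_health_benefit(stream, params) - net_consumption_cost(
        stream, params
    )


def equivalent_health_effect(
    stream: EffectStream, params: ParameterPath
) -> np.ndarray:
    """Net effect in health units: NHB - net consumption cost / V_h."""
    _, _, V_h = _clip(params, stream.T)
    if np.any(V_h <= 0):
        raise ValidationError("V_h must be strictly positive in every period")
    return net_health_benefit(stream, params) - net_consumption_cost(
        stream, params
    ) / V_h


def equivalent_resource_effect(
    stream: EffectStream, params: ParameterPath
) -> np.ndarray:
    """Net effect in health-care-resource units: k_h * equivalent health effect."""
    k_h, _, _ = _clip(params, stream.T)
    return k_h * equivalent_health_effect(stream, params)


def shadow_price_other_sector(delta_c_x, ratio) -> np.ndarray:
    """Consumption value of displaced expenditure in another public sector x.

    Constrained public sectors are shadow-priced with the ratio V_x/k_x; in
    the absence of sector-specific estimates the health-sector ratio V_h/k_h
    is the default (expenditure decisions are expected to equalise the ratio
    across sectors).
    """
    delta_c_x = np.asarray(delta_c_x, dtype=float)
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio <= 0):
        raise ValidationError("shadow-price ratio must be strictly positive")
    return ratio * delta_c_x


#: Column order of the extensive per-period accounting table.
EXTENSIVE_COLUMNS = [
    "t",
    "delta_h",
    "delta_c_h",
    "delta_c_c",
    "k_h",
    "k_c",
    "V_h",
    "health_gained",
    "health_opportunity_loss",
    "net_health_benefit",
    "resource_benefit",
    "resource_cost",
    "consumption_value_health_gained",
    "consumption_value_health_lost",
    "net_consumption_cost",
    "equivalent_consumption_effect",
    "equivalent_health_effect",
    "equivalent_resource_effect",
]


def extensive_table(stream: EffectStream, params: ParameterPath) -> pd.DataFrame:
    """Assemble the full per-period accounting table.

    One row per period carrying the raw effects, the parameter paths, and
    every derived column of the three numeraire representations.  Both
    consumption representations of health-care costs are reported — the
    consumption value of displaced health, V_h * (delta_c_h/k_h), and the
    net-production loss, k_c * delta_c_h inside the net consumption cost —
    and neither is ever silently substituted for the other.
    """
    validate_stream(stream)
    _check_lengths(stream, params)
    T = stream.T
    k_h, k_c, V_h = _clip(params, T)
    res_benefit, res_cost = equivalent_resources(stream, params)
    cv_benefit, cv_cost = consumption_value_columns(stream, params)
    table = pd.DataFrame(
        {
            "t": np.arange(1, T + 1),
            "delta_h": stream.delta_h,
            "delta_c_h": stream.delta_c_h,
            "delta_c_c": stream.delta_c_c,
            "k_h": k_h,
            "k_c": k_c,
            "V_h": V_h,
            "health_gained": stream.delta_h,
            "health_opportunity_loss": health_opportunity_loss(stream.delta_c_h, k_h),
            "net_health_benefit": net_health_benefit(stream, params),
            "resource_benefit": res_benefit,
            "resource_cost": res_cost,
            "consumption_value_health_gained": cv_benefit,
            "consumption_value_health_lost": cv_cost,
            "net_consumption_cost": net_consumption_cost(stream, params),
            "equivalent_consumption_effect": equivalent_consumption_effect(
                stream, params
            ),
            "equivalent_health_effect": equivalent_health_effect(stream, params),
            "equivalent_resource_effect": equivalent_resource_effect(stream, params),
        }
    )
    return table[EXTENSIVE_COLUMNS]
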