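"""Default parameter profiles for country contexts.

Two named bundles cover the evidence-scarce case typical of low- and
middle-income settings: a conservative profile (k_c = 1, income elasticity
of demand for health 1, eta = 1, zero pure time preference, no catastrophic
hazard) and an alternative profile with a higher income elasticity (1.5)
and stronger inequality aversion (eta = 2).  The catastrophic hazard, when
enabled at all, should not exceed 0.1% per period, and constant rates built
from point growth earn an advisory beyond 30 periods.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["DefaultsProfile", "CONSERVATIVE", "ALTERNATIVE", "PROFILES", "P_CAT_BOUND"]

#: Upper bound on a per-period hazard of truly unrecoverable catastrophe.
P_CAT_BOUND = 0.001


@dataclass(frozen=True)
class DefaultsProfile:
    """A named bundle of default assumptions for omitted parameters."""

    name: str
    k_c: float = 1.0
    elasticity_V: float = 1.0
    eta: float = 1.0
    delta: float = 0.0
    p_cat: float = 0.0
    horizon_advisory: int = 30

    def __post_init__(self):
        if self.p_cat > P_CAT_BOUND:
            raise ValueError(
                f"profile p_cat {self.p_cat} exceeds the {P_CAT_BOUND} bound"
            )


#: 1 unit of health-care spending displaces 1 unit of net production (k_c = 1);
#: V_h grows with consumption (elasticity 1); r_c = g_c (eta = 1, delta = 0).
CONSERVATIVE = DefaultsProfile(name="conservative")

#: Less conservative: V_h grows at 1.5x consumption growth; r_c = 2 g_c.
ALTERNATIVE = DefaultsProfile(name="alternative", elasticity_V=1.5, eta=2.0)

PROFILES = {p.name: p for p in (CONSERVATIVE, ALTERNATIVE)}
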