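"""Domain types for time streams of project effects and country parameters.

A project is described by per-period (t = 1..T, end-of-period accrual)
incremental health effects ``delta_h`` (QALYs gained or DALYs averted),
incremental health-care costs ``delta_c_h`` and incremental consumption costs
``delta_c_c`` (real currency; negative values are consumption benefits).
Country parameters are per-period paths of the health opportunity-cost
threshold ``k_h`` (currency per health unit), the consumption opportunity
cost of health-care expenditure ``k_c`` (currency per currency) and the
consumption value of health ``V_h`` (currency per health unit), either given
explicitly or built from base values and constant growth rates.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ValidationError",
    "HealthMetric",
    "Convention",
    "GrowthScenario",
    "EffectStream",
    "GrowthSpec",
    "ParameterPath",
    "DiscountSpec",
    "CountryContext",
    "Project",
    "path_from_growth",
    "validate_stream",
]


class ValidationError(ValueError):
    """Raised when inputs violate a stream or parameter invariant.

    Carries every violation found, not just the first, so that a single
    round of correction suffices.
    """

    def __init__(self, problems: Sequence[str] | str):
        if isinstance(problems, str):
            problems = [problems]
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))


class HealthMetric(str, enum.Enum):
    """Unit of the health-effect series; sign-equivalent (improvement > 0)."""

    QALY_GAINED = "QALY_gained"
    DALY_AVERTED = "DALY_averted"


class Convention(str, enum.Enum):
    """Compounding convention for rate composition.

    ``APPROX_SUBTRACTIVE`` reproduces the textbook small-rate arithmetic
    (e.g. r_h = r_s - gk_h); ``EXACT_MULTIPLICATIVE`` composes gross rates
    ((1+r_h) = (1+r_s)/(1+gk_h)) and makes the cross-numeraire equivalences
    exact identities rather than approximations.
    """

    APPROX_SUBTRACTIVE = "approx_subtractive"
    EXACT_MULTIPLICATIVE = "exact_multiplicative"


def _as_series(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be one-dimensional, got shape {arr.shape}")
    return arr


def path_from_growth(base: float, g: float, T: int) -> np.ndarray:
    """Build a per-period parameter path from a base value and growth rate.

    The value at t = 1 equals ``base``; thereafter v[t] = base * (1+g)**(t-1).

    Parameters
    ----------
    base : positive starting value (the period-1 value).
    g : per-period real growth rate, must exceed -1.
    T : number of periods, at least 1.
    """
    problems = []
    if not (base > 0):
        problems.append(f"base must be positive, got {base}")
    if not (g > -1):
        problems.append(f"growth rate must exceed -1, got {g}")
    if T < 1:
        problems.append(f"period count T must be >= 1, got {T}")
    if problems:
        raise ValidationError(problems)
    return base * (1.0 + g) ** np.arange(T, dtype=float)


@dataclass(frozen=True)
class EffectStream:
    """Per-period incremental effects of a project in one country.

    Periods are 1-based: index t = 1 is the first period after the decision,
    and series element ``delta_h[0]`` holds the period-1 value.
    """

    country_id: str
    delta_h: np.ndarray
    delta_c_h: np.ndarray
    delta_c_c: np.ndarray
    health_metric: HealthMetric = HealthMetric.QALY_GAINED
    currency: str = "USD"

    def __post_init__(self):
        object.__setattr__(self, "delta_h", _as_series(self.delta_h, "delta_h"))
        object.__setattr__(self, "delta_c_h", _as_series(self.delta_c_h, "delta_c_h"))
        object.__setattr__(self, "delta_c_c", _as_series(self.delta_c_c, "delta_c_c"))
        object.__setattr__(self, "health_metric", HealthMetric(self.health_metric))

    @property
    def T(self) -> int:
        return len(self.delta_h)


def validate_stream(stream: EffectStream) -> EffectStream:
    """Validate an :class:`EffectStream`, reporting every violation at once.

    Checks that all three series share the same length T >= 1 and that every
    value is finite; error messages name the offending series and 1-based
    period.
    """
    problems = []
    T = stream.T
    if T < 1:
        problems.append("stream must have at least one period (T >= 1)")
    for name in ("delta_h", "delta_c_h", "delta_c_c"):
        series = getattr(stream, name)
        if len(series) != T:
            problems.append(
                f"length mismatch: {name} has {len(series)} periods, delta_h has {T}"
            )
        bad = np.flatnonzero(~np.isfinite(series))
        for i in bad:
            problems.append(f"non-finite value in {name} at period t={i + 1}")
    if problems:
        raise ValidationError(problems)
    return stream


@dataclass(frozen=True)
class GrowthSpec:
    """Constant per-period growth rates for the country parameters.

    ``g_c`` is real consumption growth; ``gk_h`` the growth of the health
    opportunity-cost threshold; the consumption value of health grows at
    ``elasticity_V * g_c`` (income elasticity of demand for health); ``g_kc``
    (growth of k_c) defaults to g_c — net-production opportunity costs are
    assumed to track consumption.
    """

    g_c: float = 0.0
    gk_h: float = 0.0
    elasticity_V: float = 1.0
    g_kc: float | None = None

    def __post_init__(self):
        problems = []
        for name in ("g_c", "gk_h"):
            if not (getattr(self, name) > -1):
                problems.append(f"{name} must exceed -1, got {getattr(self, name)}")
        if self.elasticity_V < 0:
            problems.append(f"elasticity_V must be >= 0, got {self.elasticity_V}")
        if self.g_kc is not None and not (self.g_kc > -1):
            problems.append(f"g_kc must exceed -1, got {self.g_kc}")
        if problems:
            raise ValidationError(problems)

    @property
    def gV_h(self) -> float:
        """Growth rate of the consumption value of health."""
        return self.elasticity_V * self.g_c

    @property
    def resolved_g_kc(self) -> float:
        return self.g_c if self.g_kc is None else self.g_kc


@dataclass(frozen=True)
class ParameterPath:
    """Per-period country parameter paths k_h, k_c and V_h (1-based periods)."""

    k_h: np.ndarray
    k_c: np.ndarray
    V_h: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "k_h", _as_series(self.k_h, "k_h"))
        object.__setattr__(self, "k_c", _as_series(self.k_c, "k_c"))
        object.__setattr__(self, "V_h", _as_series(self.V_h, "V_h"))
        problems = []
        T = len(self.k_h)
        for name in ("k_c", "V_h"):
            if len(getattr(self, name)) != T:
                problems.append(f"length mismatch: {name} vs k_h")
        if np.any(self.k_h <= 0):
            problems.append("k_h must be strictly positive in every period")
        if np.any(self.V_h <= 0):
            problems.append("V_h must be strictly positive in every period")
        if np.any(self.k_c < 0):
            problems.append("k_c must be non-negative in every period")
        if not (
            np.all(np.isfinite(self.k_h))
            and np.all(np.isfinite(self.k_c))
            and np.all(np.isfinite(self.V_h))
        ):
            problems.append("parameter paths must be finite")
        if problems:
            raise ValidationError(problems)

    @property
    def T(self) -> int:
        return len(self.k_h)

    @classmethod
    def from_growth(
        cls,
        k_h_base: float,
        k_c_base: float,
        V_h_base: float,
        growth: GrowthSpec,
        T: int,
    ) -> "ParameterPath":
        """Expand base values into geometric paths under a :class:`GrowthSpec`."""
        if k_c_base == 0:
            # path_from_growth requires base > 0; a zero k_c is legal (no
            # net-production displacement) and stays zero forever.
            k_c = np.zeros(T)
        else:
            k_c = path_from_growth(k_c_base, growth.resolved_g_kc, T)
        return cls(
            k_h=path_from_growth(k_h_base, growth.gk_h, T),
            k_c=k_c,
            V_h=path_from_growth(V_h_base, growth.gV_h, T),
        )


GrowthScenario = tuple[float, float]
"""A (growth rate, probability) pair in a consumption-growth scenario set."""


@dataclass(frozen=True)
class DiscountSpec:
    """Discounting inputs for one country.

    ``delta`` is pure time preference and ``eta`` the weight on the wealth
    effect in the Ramsey rule r_c = delta + eta * g_c.  ``growth`` is either a
    point consumption-growth rate or a scenario set [(g_i, p_i), ...] which
    induces a declining (certainty-equivalent) term structure.  ``r_s`` is the
    principal's real borrowing/saving rate, anchoring the health-numeraire
    rate r_h.  ``p_cat`` is a per-period hazard of unrecoverable catastrophe
    and ``beta_premium`` an additive project risk premium (negative for
    countercyclical projects).
    """

    delta: float = 0.0
    eta: float = 1.0
    growth: float | Sequence[GrowthScenario] = 0.0
    r_s: float = 0.03
    p_cat: float = 0.0
    beta_premium: float = 0.0
    convention: Convention = Convention.EXACT_MULTIPLICATIVE

    def __post_init__(self):
        object.__setattr__(self, "convention", Convention(self.convention))
        problems = []
        if self.delta < 0:
            problems.append(f"delta must be >= 0, got {self.delta}")
        if not (self.eta > 0):
            problems.append(f"eta must be > 0, got {self.eta}")
        if not (0 <= self.p_cat < 1):
            problems.append(f"p_cat must lie in [0, 1), got {self.p_cat}")
        if self.has_scenarios:
            scenarios = tuple((float(g), float(p)) for g, p in self.growth)
            object.__setattr__(self, "growth", scenarios)
            if len(scenarios) == 0:
                problems.append("scenario set must be non-empty")
            else:
                probs = np.array([p for _, p in scenarios])
                if np.any(probs <= 0):
                    problems.append("scenario probabilities must be positive")
                if not math.isclose(probs.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
                    problems.append(
                        f"scenario probabilities must sum to 1, got {probs.sum()}"
                    )
        if problems:
            raise ValidationError(problems)
        if self.p_cat > 0.001:
            warnings.warn(
                f"p_cat={self.p_cat} exceeds the 0.1% bound suggested for truly "
                "catastrophic (unrecoverable) events",
                stacklevel=2,
            )

    @property
    def has_scenarios(self) -> bool:
        return not np.isscalar(self.growth)

    @property
    def point_growth(self) -> float:
        """Point consumption growth, or the probability-weighted mean rate."""
        if self.has_scenarios:
            return float(sum(g * p for g, p in self.growth))
        return float(self.growth)


@dataclass(frozen=True)
class CountryContext:
    """Everything needed to appraise a stream for one country."""

    id: str
    params: ParameterPath
    discount: DiscountSpec
    growth: GrowthSpec | None = None
    shadow_ratio_x: np.ndarray | None = None
    currency: str = "USD"
    defaults_applied: tuple = ()

    def __post_init__(self):
        if self.shadow_ratio_x is not None:
            ratio = _as_series(self.shadow_ratio_x, "shadow_ratio_x")
            if np.any(ratio <= 0):
                raise ValidationError("shadow_ratio_x must be strictly positive")
            object.__setattr__(self, "shadow_ratio_x", ratio)

    def shadow_ratio(self) -> np.ndarray:
        """V_x/k_x for another constrained public sector; defaults to V_h/k_h."""
        if self.shadow_ratio_x is not None:
            return self.shadow_ratio_x
        return self.params.V_h / self.params.k_h


@dataclass(frozen=True)
class Project:
    """A project's effect streams keyed by country id."""

    streams: Mapping[str, EffectStream]
    shared_horizon: bool = False

    def __post_init__(self):
        if len(self.streams) < 1:
            raise ValidationError("a project needs at least one country stream")
        horizons = {s.T for s in self.streams.values()}
        if self.shared_horizon and len(horizons) > 1:
            raise ValidationError(
                f"shared_horizon requested but horizons differ: {sorted(horizons)}"
            )

    @property
    def countries(self) -> list[str]:
        return list(self.streams)
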