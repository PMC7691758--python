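"""Seeded toy-project generator and an independent straight-line oracle.

``make_project`` draws a multi-country project with realistic magnitudes
(health effects in single-digit to tens of QALYs, health-care costs in the
thousands, thresholds below typical income per head, consumption value of
health above the threshold) together with country contexts built from base
values and growth rates.  ``generate_fixture`` writes the streams CSV, the
contexts YAML and an expected-results JSON computed by :func:`oracle_npv` —
a deliberately naive per-term transcription of the accounting identities
that shares no arithmetic with the library's vectorised code paths.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core import (
    CountryContext,
    DiscountSpec,
    EffectStream,
    GrowthSpec,
    ParameterPath,
    Project,
    ValidationError,
)

__all__ = [
    "FixtureSpec",
    "make_project",
    "generate_fixture",
    "oracle_npv",
    "oracle_expected",
    "random_cases",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Seeded specification of a toy multi-country project."""

    seed: int = 42
    n_countries: int = 3
    T: int = 5
    delta_h_range: tuple[float, float] = (-10.0, 20.0)
    delta_c_h_range: tuple[float, float] = (-5000.0, 20000.0)
    delta_c_c_range: tuple[float, float] = (-2000.0, 5000.0)
    k_h_range: tuple[float, float] = (200.0, 5000.0)
    v_over_k_range: tuple[float, float] = (1.0, 4.0)
    g_c_range: tuple[float, float] = (0.0, 0.05)
    gk_h_range: tuple[float, float] = (0.0, 0.04)
    r_s_range: tuple[float, float] = (0.01, 0.06)

    def __post_init__(self):
        problems = []
        if self.T < 1:
            problems.append(f"T must be >= 1, got {self.T}")
        if self.n_countries < 1:
            problems.append(f"n_countries must be >= 1, got {self.n_countries}")
        for name in (
            "delta_h_range", "delta_c_h_range", "delta_c_c_range", "k_h_range",
            "v_over_k_range", "g_c_range", "gk_h_range", "r_s_range",
        ):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                problems.append(f"{name} is empty: ({lo}, {hi})")
        if self.k_h_range[0] <= 0 or self.v_over_k_range[0] < 1:
            problems.append("k_h must be positive and V_h/k_h at least 1")
        if problems:
            raise ValidationError(problems)


def _country_ids(n: int) -> list[str]:
    letters = string.ascii_uppercase
    ids = []
    for i in range(n):
        name = ""
        j = i
        while True:
            name = letters[j % 26] + name
            j = j // 26 - 1
            if j < 0:
                break
        ids.append(name)
    return ids


def make_project(
    spec: FixtureSpec,
) -> tuple[Project, dict[str, CountryContext]]:
    """Draw a seeded project and matching country contexts."""
    rng = np.random.default_rng(spec.seed)
    streams = {}
    contexts = {}
    for cid in _country_ids(spec.n_countries):
        streams[cid] = EffectStream(
            country_id=cid,
            delta_h=rng.uniform(*spec.delta_h_range, spec.T),
            delta_c_h=rng.uniform(*spec.delta_c_h_range, spec.T),
            delta_c_c=rng.uniform(*spec.delta_c_c_range, spec.T),
        )
        k_h_base = rng.uniform(*spec.k_h_range)
        growth = GrowthSpec(
            g_c=rng.uniform(*spec.g_c_range),
            gk_h=rng.uniform(*spec.gk_h_range),
            elasticity_V=float(rng.choice([1.0, 1.5])),
        )
        discount = DiscountSpec(
            delta=0.0,
            eta=float(rng.choice([1.0, 2.0])),
            growth=growth.g_c,
            r_s=rng.uniform(*spec.r_s_range),
        )
        contexts[cid] = CountryContext(
            id=cid,
            params=ParameterPath.from_growth(
                k_h_base=k_h_base,
                k_c_base=1.0,
                V_h_base=k_h_base * rng.uniform(*spec.v_over_k_range),
                growth=growth,
                T=spec.T,
            ),
            discount=discount,
            growth=growth,
        )
    return Project(streams=streams), contexts


def random_cases(seed: int, n: int, T_max: int = 10):
    """Yield ``n`` seeded single-country (stream, context) pairs, T <= T_max."""
    rng = np.random.default_rng(seed)
    for _ in range(n):
        T = int(rng.integers(1, T_max + 1))
        child = int(rng.integers(0, 2**31 - 1))
        project, contexts = make_project(
            FixtureSpec(seed=child, n_countries=1, T=T)
        )
        ((cid, stream),) = project.streams.items()
        yield stream, contexts[cid]


def oracle_npv(
    delta_h, delta_c_h, delta_c_c, k_h, k_c, V_h, r_c
) -> float:
    """Straight-line per-term oracle for a single country's NPV.

    A literal loop over the period-by-period accounting identities and the
    (1+r_c)^-t present-value sum, written in plain Python arithmetic so it
    shares no code with the vectorised library path.
    """
    total = 0.0
    T = len(delta_h)
    for t in range(1, T + 1):
        i = t - 1
        net_health = delta_h[i] - delta_c_h[i] / k_h[i]
        net_consumption_cost = delta_c_c[i] + k_c[i] * delta_c_h[i]
        equivalent_consumption = V_h[i] * net_health - net_consumption_cost
        total = total + equivalent_consumption / (1.0 + r_c) ** t
    return total


def oracle_expected(
    project: Project, contexts: dict[str, CountryContext]
) -> dict:
    """Expected per-country and global NPVs by the straight-line oracle."""
    per_country = {}
    for cid, stream in project.streams.items():
        ctx = contexts[cid]
        d = ctx.discount
        r_c = d.delta + d.eta * d.point_growth
        per_country[cid] = oracle_npv(
            list(stream.delta_h),
            list(stream.delta_c_h),
            list(stream.delta_c_c),
            list(ctx.params.k_h),
            list(ctx.params.k_c),
            list(ctx.params.V_h),
            r_c,
        )
    return {
        "country_npv": per_country,
        "global_npv": sum(per_country.values()),
    }


def generate_fixture(spec: FixtureSpec, out_dir) -> dict[str, Path]:
    """Write streams CSV, contexts YAML and oracle-expected JSON to a directory.

    Deterministic under the seed: the same spec always produces byte-identical
    files.  The expected results are computed by the straight-line oracle,
    never by the library's own valuation code.
    """
    from .io import write_streams  # deferred: io imports valuation

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    project, contexts = make_project(spec)

    streams_path = out / "streams.csv"
    write_streams(project, streams_path)

    lines = ["currency: USD", f"horizon: {spec.T}", "countries:"]
    for cid, ctx in contexts.items():
        g = ctx.growth
        d = ctx.discount
        lines += [
            f"  {cid}:",
            f"    k_h: {float(ctx.params.k_h[0])!r}",
            f"    k_c: {float(ctx.params.k_c[0])!r}",
            f"    V_h: {float(ctx.params.V_h[0])!r}",
            "    growth:",
            f"      g_c: {float(g.g_c)!r}",
            f"      gk_h: {float(g.gk_h)!r}",
            f"      elasticity_V: {float(g.elasticity_V)!r}",
            "    discount:",
            f"      delta: {float(d.delta)!r}",
            f"      eta: {float(d.eta)!r}",
            f"      r_s: {float(d.r_s)!r}",
        ]
    contexts_path = out / "contexts.yaml"
    contexts_path.write_text("\n".join(lines) + "\n")

    expected_path = out / "expected.json"
    expected_path.write_text(
        json.dumps(oracle_expected(project, contexts), indent=2, sort_keys=True) + "\n"
    )
    return {
        "streams": streams_path,
        "contexts": contexts_path,
        "expected": expected_path,
    }
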