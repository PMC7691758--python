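"""Readers, writers and report rendering.

Stream files are plain CSV with columns ``country,t,delta_h,delta_c_h,
delta_c_c`` (UTF-8, comma separator, ``.`` decimal, header required, t
contiguous from 1 within each country).  Country-parameter files are YAML or
JSON; omitted parameters are filled from a named defaults profile and every
fill is logged and recorded so reports can trace each number to user input
or a named default.
"""

from __future__ import annotations

import io as _io
import json
import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core import (
    CountryContext,
    DiscountSpec,
    EffectStream,
    GrowthSpec,
    ParameterPath,
    Project,
    ValidationError,
)
from .defaults import CONSERVATIVE, PROFILES, DefaultsProfile
from .valuation import AppraisalResult, GlobalResult

__all__ = [
    "STREAM_COLUMNS",
    "load_streams",
    "write_streams",
    "load_contexts",
    "render_extensive_report",
    "parse_extensive_csv",
    "summary_dict",
]

logger = logging.getLogger(__name__)

STREAM_COLUMNS = ["country", "t", "delta_h", "delta_c_h", "delta_c_c"]


def load_streams(path) -> Project:
    """Read a streams CSV into a :class:`~healthnpv.core.Project`.

    Errors name the offending column or the 1-based file line of a duplicate
    or non-contiguous period.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in STREAM_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError([f"missing column {c!r} in {path}" for c in missing])
    problems = []
    streams = {}
    for country, group in df.groupby("country", sort=False):
        t = group["t"].to_numpy()
        expected = np.arange(1, len(t) + 1)
        if not np.array_equal(np.sort(t), expected):
            # header is line 1, first data row line 2
            dup = group[group["t"].duplicated()]
            if len(dup):
                for idx, row in dup.iterrows():
                    problems.append(
                        f"duplicate period (country={country}, t={int(row['t'])}) "
                        f"at line {idx + 2}"
                    )
            else:
                problems.append(
                    f"periods for country {country!r} are not contiguous from 1: "
                    f"got t={sorted(int(x) for x in t)} "
                    f"(lines {group.index.min() + 2}-{group.index.max() + 2})"
                )
            continue
        ordered = group.sort_values("t")
        streams[str(country)] = EffectStream(
            country_id=str(country),
            delta_h=ordered["delta_h"].to_numpy(),
            delta_c_h=ordered["delta_c_h"].to_numpy(),
            delta_c_c=ordered["delta_c_c"].to_numpy(),
        )
    if problems:
        raise ValidationError(problems)
    return Project(streams=streams)


def write_streams(project: Project, path) -> None:
    """Write a project to the streams CSV schema (inverse of load_streams)."""
    rows = []
    for cid, s in project.streams.items():
        for i in range(s.T):
            rows.append(
                {
                    "country": cid,
                    "t": i + 1,
                    "delta_h": s.delta_h[i],
                    "delta_c_h": s.delta_c_h[i],
                    "delta_c_c": s.delta_c_c[i],
                }
            )
    pd.DataFrame(rows, columns=STREAM_COLUMNS).to_csv(path, index=False)


_KNOWN_COUNTRY_KEYS = {
    "k_h", "k_c", "V_h", "growth", "discount", "horizon", "profile",
    "currency", "shadow_ratio_x",
}
_KNOWN_GROWTH_KEYS = {"g_c", "gk_h", "elasticity_V", "g_kc"}
_KNOWN_DISCOUNT_KEYS = {
    "delta", "eta", "r_s", "p_cat", "beta_premium", "convention", "scenarios",
}


def _base_or_path(value, name: str, growth_rate: float, T: int) -> np.ndarray:
    """A parameter given as a scalar base (expanded geometrically) or a list."""
    from .core import path_from_growth

    if isinstance(value, (list, tuple)):
        arr = np.asarray(value, dtype=float)
        if len(arr) != T:
            raise ValidationError(
                f"explicit {name} path has {len(arr)} periods, horizon is {T}"
            )
        return arr
    base = float(value)
    if base == 0 and name == "k_c":
        return np.zeros(T)
    return path_from_growth(base, growth_rate, T)


def load_contexts(
    path, horizon: int | None = None
) -> dict[str, CountryContext]:
    """Read a YAML/JSON country-parameter file into country contexts.

    Parameters omitted in the file are filled from the country's named
    defaults profile (``profile:`` key, default ``conservative``); each fill
    is logged at INFO and recorded on the context.  Unknown keys are schema
    errors.  ``horizon`` (or a per-country ``horizon`` key) sets the number
    of periods when paths are expanded from base values.
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text)
    if not isinstance(doc, dict) or "countries" not in doc:
        raise ValidationError(f"{path}: expected a mapping with a 'countries' key")
    top_currency = doc.get("currency", "USD")
    top_horizon = doc.get("horizon", horizon)
    extra_top = set(doc) - {"countries", "currency", "horizon"}
    if extra_top:
        raise ValidationError([f"unknown top-level key {k!r}" for k in sorted(extra_top)])

    contexts: dict[str, CountryContext] = {}
    for cid, spec in doc["countries"].items():
        cid = str(cid)
        unknown = set(spec) - _KNOWN_COUNTRY_KEYS
        if unknown:
            raise ValidationError(
                [f"country {cid}: unknown key {k!r}" for k in sorted(unknown)]
            )
        profile: DefaultsProfile = PROFILES[spec.get("profile", CONSERVATIVE.name)]
        applied: list[str] = []

        def default(section: dict, key: str, value, applied=applied, cid=cid):
            if key in section:
                return section[key]
            applied.append(f"{key}={value} ({profile.name} default)")
            logger.info(
                "country %s: using %s default %s=%s", cid, profile.name, key, value
            )
            return value

        growth_doc = dict(spec.get("growth", {}))
        unknown = set(growth_doc) - _KNOWN_GROWTH_KEYS
        if unknown:
            raise ValidationError(
                [f"country {cid}: unknown growth key {k!r}" for k in sorted(unknown)]
            )
        discount_doc = dict(spec.get("discount", {}))
        unknown = set(discount_doc) - _KNOWN_DISCOUNT_KEYS
        if unknown:
            raise ValidationError(
                [f"country {cid}: unknown discount key {k!r}" for k in sorted(unknown)]
            )

        growth = GrowthSpec(
            g_c=float(growth_doc.get("g_c", 0.0)),
            gk_h=float(growth_doc.get("gk_h", 0.0)),
            elasticity_V=float(
                default(growth_doc, "elasticity_V", profile.elasticity_V)
            ),
            g_kc=(None if growth_doc.get("g_kc") is None else float(growth_doc["g_kc"])),
        )
        scenarios = discount_doc.get("scenarios")
        discount = DiscountSpec(
            delta=float(default(discount_doc, "delta", profile.delta)),
            eta=float(default(discount_doc, "eta", profile.eta)),
            growth=(
                [(float(g), float(p)) for g, p in scenarios]
                if scenarios is not None
                else growth.g_c
            ),
            r_s=float(discount_doc.get("r_s", 0.03)),
            p_cat=float(default(discount_doc, "p_cat", profile.p_cat)),
            beta_premium=float(discount_doc.get("beta_premium", 0.0)),
            convention=discount_doc.get("convention", "exact_multiplicative"),
        )

        T = spec.get("horizon", top_horizon)
        explicit = all(
            isinstance(spec.get(k), (list, tuple)) for k in ("k_h", "k_c", "V_h")
            if k in spec
        ) and isinstance(spec.get("k_h"), (list, tuple))
        if T is None:
            if explicit:
                T = len(spec["k_h"])
            else:
                raise ValidationError(
                    f"country {cid}: a horizon is required to expand parameter "
                    "paths from base values"
                )
        T = int(T)
        if "k_h" not in spec:
            raise ValidationError(f"country {cid}: k_h is required")
        if "V_h" not in spec:
            raise ValidationError(f"country {cid}: V_h is required")
        k_c_value = default(spec, "k_c", profile.k_c)
        params = ParameterPath(
            k_h=_base_or_path(spec["k_h"], "k_h", growth.gk_h, T),
            k_c=_base_or_path(k_c_value, "k_c", growth.resolved_g_kc, T),
            V_h=_base_or_path(spec["V_h"], "V_h", growth.gV_h, T),
        )
        shadow = spec.get("shadow_ratio_x")
        contexts[cid] = CountryContext(
            id=cid,
            params=params,
            discount=discount,
            growth=growth,
            shadow_ratio_x=(None if shadow is None else np.asarray(shadow, float)),
            currency=str(spec.get("currency", top_currency)),
            defaults_applied=tuple(applied),
        )
    return contexts


def _summary_rows(result: AppraisalResult) -> list[tuple[str, object]]:
    rows: list[tuple[str, object]] = [
        ("country", result.country_id),
        ("currency", result.currency),
        ("convention", result.convention.value),
        ("npv", result.npv),
        ("verdict", result.verdict.value),
    ]
    for key in ("pv_equivalent_health", "pv_equivalent_resource", "pv_net_health"):
        value = getattr(result, key)
        if value is not None:
            rows.append((key, value))
    if result.icer is not None:
        rows += [
            ("icer", result.icer.value),
            ("icer_threshold_k_h1", result.icer.threshold),
            ("icer_quadrant", result.icer.quadrant.value),
            ("icer_verdict", result.icer.verdict.value),
        ]
    for name, rate in result.rates.items():
        if rate is not None:
            rows.append((f"rate.{name}", rate))
    for note in result.notes:
        rows.append(("note", note))
    for d in result.defaults_applied:
        rows.append(("default_applied", d))
    return rows


def render_extensive_report(result: AppraisalResult, format: str = "csv") -> str:
    """Render the extensive per-period accounting plus the NPV block.

    ``csv`` emits the table followed by a blank line and ``key,value``
    summary rows; parsing the table back with :func:`parse_extensive_csv`
    reproduces the numbers exactly.  ``text`` mirrors the three tabular
    layouts (health effects, resource equivalents, consumption equivalents)
    in aligned columns.
    """
    table = result.table.copy()
    table["discount_factor"] = result.discount_factors
    table["discounted_contribution"] = result.discounted_contributions
    if format == "csv":
        buf = _io.StringIO()
        table.to_csv(buf, index=False)
        buf.write("\n")
        for key, value in _summary_rows(result):
            buf.write(f"{key},{value}\n")
        return buf.getvalue()
    if format == "text":
        lines = [f"Extensive report — country {result.country_id} ({result.currency})"]
        groups = {
            "Effects of the project": ["t", "delta_h", "delta_c_h", "delta_c_c"],
            "Health effects": [
                "t", "health_gained", "health_opportunity_loss", "net_health_benefit",
            ],
            "Equivalent health care resources": ["t", "resource_benefit", "resource_cost"],
            "Equivalent consumption effects": [
                "t",
                "consumption_value_health_gained",
                "consumption_value_health_lost",
                "net_consumption_cost",
                "equivalent_consumption_effect",
                "discounted_contribution",
            ],
        }
        for title, cols in groups.items():
            lines.append("")
            lines.append(title)
            lines.append(table[cols].to_string(index=False))
        lines.append("")
        for key, value in _summary_rows(result):
            lines.append(f"{key}: {value}")
        return "\n".join(lines) + "\n"
    raise ValidationError(f"unknown report format {format!r} (use 'csv' or 'text')")


def parse_extensive_csv(text: str) -> pd.DataFrame:
    """Parse the table section of a CSV extensive report back to a DataFrame."""
    table_part = text.split("\n\n", 1)[0]
    return pd.read_csv(_io.StringIO(table_part), float_precision="round_trip")


def summary_dict(result: GlobalResult) -> dict:
    """JSON-ready appraisal summary: NPVs, verdicts, rates and provenance."""
    return {
        "currency": result.currency,
        "global_npv": result.npv,
        "countries": {
            cid: {
                "npv": res.npv,
                "verdict": res.verdict.value,
                "convention": res.convention.value,
                "rates": {k: v for k, v in res.rates.items() if v is not None},
                "icer": (
                    None
                    if res.icer is None
                    else {
                        "value": res.icer.value,
                        "threshold_k_h1": res.icer.threshold,
                        "quadrant": res.icer.quadrant.value,
                        "verdict": res.icer.verdict.value,
                    }
                ),
                "pv_equivalent_health": res.pv_equivalent_health,
                "pv_equivalent_resource": res.pv_equivalent_resource,
                "pv_net_health": res.pv_net_health,
                "defaults_applied": list(res.defaults_applied),
                "notes": list(res.notes),
            }
            for cid, res in result.by_country.items()
        },
    }
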