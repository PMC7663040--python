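"""Exposure assessment and safety routing.

Each substance's modelled beverage migration is converted into an infant
dietary exposure (0.75 L of water per day at 5 kg body weight by default)
and routed through one of three evaluation paths:

* ``genotoxic_ttc`` — substances with (corrected) genotoxic potential, and
  unidentified substances under the worst-case assumption that they are
  genotoxic, are compared against the TTC-derived benchmark of
  0.0025 µg per kg body weight per day.
* ``general_migration`` — all other identified substances, regardless of
  Cramer class, are screened against a flat 1 µg/L migration limit.
* ``volatile_excluded`` — very volatile solvents (ethanol, 2-butanone and
  similar) are removed by super-clean processes at efficiencies of at least
  99%; instead of silently skipping them, the verdict re-applies a 99%
  cleaning efficiency before screening so the claim stays testable.

The curated alert overrides take precedence over the raw decision-tree
flags: a known human carcinogen with a missed alert is routed genotoxic,
and spurious alerts (aliphatic aldehydes, benzaldehyde, carvone, eugenol,
anisaldehyde, 2-hydroxybiphenyl) fall back to the general route.  Cramer
class TTC thresholds are carried in the data model but deliberately not
used for verdicts; the flat migration screen is the operative rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from .diffusion import get_model
from .migration import MigrationResult, ScenarioConfig, chain_concentration, migrate
from .tables import (
    ContaminationSurvey,
    PooledUnknown,
    SubstanceRecord,
    aggregate_unknowns,
    group_mean,
)

__all__ = [
    "SafetyVerdict",
    "Unevaluable",
    "EvaluationReport",
    "GENOTOXIC_TTC_THRESHOLD",
    "GENERAL_MIGRATION_LIMIT",
    "DEFAULT_VOLATILE_NAMES",
    "VOLATILE_RT_CUTOFF_MIN",
    "exposure",
    "safety_factor",
    "is_genotoxic",
    "is_volatile",
    "evaluate_substance",
    "evaluate_all",
    "estimate_nonfood_fraction",
]

#: TTC-derived benchmark for potentially genotoxic migrants, µg/kg bw/day.
GENOTOXIC_TTC_THRESHOLD = 0.0025
#: Flat migration screen for non-genotoxic substances, µg/L beverage.
GENERAL_MIGRATION_LIMIT = 1.0
#: Cleaning efficiency re-applied to very volatile solvents before routing.
VOLATILE_CLEANING_EFFICIENCY = 0.99
#: Name-based volatile-solvent list (case-insensitive substring match).
DEFAULT_VOLATILE_NAMES = ("ethanol", "2-butanone")
#: Unidentified substances eluting at or before this GC retention time
#: (minutes) are treated as volatile solvents; the named solvents elute at
#: 1.7-2.2 min in the survey's chromatographic method.
VOLATILE_RT_CUTOFF_MIN = 2.2


@dataclass(frozen=True)
class SafetyVerdict:
    """Outcome of the safety screen for one substance (or pooled surrogate)."""

    substance: str
    route: str  # genotoxic_ttc | general_migration | volatile_excluded
    migration: float  # µg/L beverage
    threshold: float  # µg/kg bw/day (genotoxic route) or µg/L (general)
    threshold_units: str
    safety_factor: float  # threshold / observed; inf when nothing migrates
    conclusion: str  # no_concern | concern
    exposure: float | None = None  # µg/kg bw/day, genotoxic route only
    scenario: str = "default"
    category_id: str | None = None


@dataclass(frozen=True)
class Unevaluable:
    """A substance the screen cannot evaluate, with the reason why."""

    substance: str
    category_id: str | None
    reason: str


@dataclass
class EvaluationReport:
    """All verdicts of a whole-table sweep plus any unevaluable records."""

    verdicts: list[SafetyVerdict]
    unevaluable: list[Unevaluable] = field(default_factory=list)
    scenario: str = "default"

    def summary(self) -> dict:
        routes: dict[str, int] = {}
        conclusions: dict[str, int] = {}
        for v in self.verdicts:
            routes[v.route] = routes.get(v.route, 0) + 1
            conclusions[v.conclusion] = conclusions.get(v.conclusion, 0) + 1
        return {
            "scenario": self.scenario,
            "n_verdicts": len(self.verdicts),
            "n_unevaluable": len(self.unevaluable),
            "by_route": routes,
            "by_conclusion": conclusions,
        }


def exposure(migration: float, consumption: float, body_weight: float) -> float:
    """Dietary exposure in µg/kg bw/day from a beverage concentration in µg/L."""
    if migration < 0 or consumption < 0:
        raise ValueError("migration and consumption must be non-negative")
    if body_weight <= 0:
        raise ValueError("body weight must be strictly positive")
    return migration * consumption / body_weight


def safety_factor(observed: float, threshold: float) -> float:
    """How far the observed value sits below its threshold (threshold/observed).

    An observed value of exactly zero yields an infinite margin rather than
    an error.
    """
    if observed < 0:
        raise ValueError("observed value must be non-negative")
    if observed == 0.0:
        return math.inf
    return threshold / observed


def is_genotoxic(record: SubstanceRecord, *, assume_genotoxic_unknowns: bool = True) -> bool:
    """Corrected genotoxicity call: footnote overrides beat raw alert flags."""
    if record.alert_override is not None:
        kind = record.alert_override.kind
        if kind in ("known_genotoxic", "wrong_negative"):
            return True
        if kind == "wrong_positive":
            return False
    if record.is_unknown:
        return assume_genotoxic_unknowns
    return record.gtc_alert


def is_volatile(
    record: SubstanceRecord,
    volatile_names: Sequence[str] = DEFAULT_VOLATILE_NAMES,
    rt_cutoff: float = VOLATILE_RT_CUTOFF_MIN,
) -> bool:
    """Very-volatile-solvent test: by name, or by elution window for unknowns."""
    lowered = record.name.lower()
    if any(v.lower() in lowered for v in volatile_names):
        return True
    if record.is_unknown and record.retention_time is not None:
        return record.retention_time <= rt_cutoff
    return False


def evaluate_substance(
    record: SubstanceRecord,
    migration_result: MigrationResult,
    cfg: ScenarioConfig,
    *,
    assume_genotoxic_unknowns: bool = True,
    volatile_names: Sequence[str] = DEFAULT_VOLATILE_NAMES,
    volatile_rt_cutoff: float = VOLATILE_RT_CUTOFF_MIN,
    scenario: str = "default",
) -> SafetyVerdict:
    """Route one substance's migration through the safety screen."""
    if migration_result.substance and migration_result.substance != record.name:
        raise ValueError(
            f"record {record.name!r} does not match migration result "
            f"{migration_result.substance!r}"
        )
    migration = migration_result.migration
    volatile = is_volatile(record, volatile_names, volatile_rt_cutoff)
    if volatile:
        # re-apply the >= 99% removal such solvents actually experience
        effective_cleaning = max(cfg.cleaning_efficiency, VOLATILE_CLEANING_EFFICIENCY)
        if cfg.cleaning_efficiency < 1.0:
            migration *= (1.0 - effective_cleaning) / (1.0 - cfg.cleaning_efficiency)

    genotoxic = is_genotoxic(record, assume_genotoxic_unknowns=assume_genotoxic_unknowns)
    if genotoxic and not volatile:
        expo = exposure(migration, cfg.consumption, cfg.body_weight)
        factor = safety_factor(expo, GENOTOXIC_TTC_THRESHOLD)
        return SafetyVerdict(
            substance=record.name,
            route="genotoxic_ttc",
            migration=migration,
            exposure=expo,
            threshold=GENOTOXIC_TTC_THRESHOLD,
            threshold_units="µg/kg bw/day",
            safety_factor=factor,
            conclusion="no_concern" if factor > 1.0 else "concern",
            scenario=scenario,
            category_id=record.category_id,
        )
    factor = safety_factor(migration, GENERAL_MIGRATION_LIMIT)
    return SafetyVerdict(
        substance=record.name,
        route="volatile_excluded" if volatile else "general_migration",
        migration=migration,
        threshold=GENERAL_MIGRATION_LIMIT,
        threshold_units="µg/L",
        safety_factor=factor,
        conclusion="no_concern" if factor > 1.0 else "concern",
        scenario=scenario,
        category_id=record.category_id,
    )


def evaluate_all(
    survey: ContaminationSurvey,
    model: str | Callable[[float, float], float] = "piringer",
    cfg: ScenarioConfig | None = None,
    *,
    pool_unknowns: bool = True,
    assume_genotoxic_unknowns: bool = True,
    volatile_names: Sequence[str] = DEFAULT_VOLATILE_NAMES,
    volatile_rt_cutoff: float = VOLATILE_RT_CUTOFF_MIN,
    scenario: str = "default",
    method: str = "semi_infinite",
) -> EvaluationReport:
    """Whole-table sweep: one verdict per evaluable substance.

    Each substance is evaluated at its category group-mean concentration.
    Unidentified substances are screened individually under the
    assumed-genotoxic worst case, and additionally — when ``pool_unknowns``
    is set — each category's non-volatile unknowns are pooled into a single
    surrogate (sum of group means, representative molecular weight from the
    union of the estimated ranges) and screened on the genotoxic route.
    Unevaluable records are reported, not raised.
    """
    cfg = cfg or ScenarioConfig()
    model_fn = get_model(model) if isinstance(model, str) else model
    verdicts: list[SafetyVerdict] = []
    unevaluable: list[Unevaluable] = []

    for record in survey.records:
        category = survey.categories[record.category_id]
        c_mean = group_mean(record, category)
        try:
            mw = record.effective_molecular_weight
        except Exception:
            if not (record.is_unknown and assume_genotoxic_unknowns):
                unevaluable.append(
                    Unevaluable(record.name, record.category_id, "no molecular weight available")
                )
                continue
            unevaluable.append(
                Unevaluable(
                    record.name, record.category_id,
                    "assumed genotoxic but no molecular weight or range to model migration",
                )
            )
            continue
        c_p0 = chain_concentration(c_mean, cfg.nonfood_fraction, cfg.cleaning_efficiency)
        if c_p0 == 0.0:
            result = MigrationResult(
                substance=record.name, c_p0=0.0, diffusion_coefficient=1.0,
                migration=0.0, fractional_depletion=0.0, c_nonfood=c_mean, method=method,
            )
        else:
            D = model_fn(mw, cfg.temperature)
            result = migrate(c_p0, D, cfg, method=method,
                             substance=record.name, c_nonfood=c_mean)
        verdicts.append(
            evaluate_substance(
                record, result, cfg,
                assume_genotoxic_unknowns=assume_genotoxic_unknowns,
                volatile_names=volatile_names,
                volatile_rt_cutoff=volatile_rt_cutoff,
                scenario=scenario,
            )
        )

    if pool_unknowns:
        for cat_id in survey.categories:
            nonvolatile = [
                r for r in survey.unknowns_in(cat_id)
                if not is_volatile(r, volatile_names, volatile_rt_cutoff)
            ]
            pooled = aggregate_unknowns(survey, cat_id, records=nonvolatile)
            if pooled is None:
                continue
            c_p0 = chain_concentration(
                pooled.pooled_concentration, cfg.nonfood_fraction, cfg.cleaning_efficiency
            )
            name = f"Pooled unknowns ({cat_id})"
            if c_p0 == 0.0:
                migration_value, expo = 0.0, 0.0
            else:
                D = model_fn(pooled.representative_molecular_weight, cfg.temperature)
                result = migrate(c_p0, D, cfg, method=method, substance=name,
                                 c_nonfood=pooled.pooled_concentration)
                migration_value = result.migration
                expo = exposure(migration_value, cfg.consumption, cfg.body_weight)
            factor = safety_factor(expo, GENOTOXIC_TTC_THRESHOLD)
            verdicts.append(
                SafetyVerdict(
                    substance=name,
                    route="genotoxic_ttc",
                    migration=migration_value,
                    exposure=expo,
                    threshold=GENOTOXIC_TTC_THRESHOLD,
                    threshold_units="µg/kg bw/day",
                    safety_factor=factor,
                    conclusion="no_concern" if factor > 1.0 else "concern",
                    scenario=scenario,
                    category_id=cat_id,
                )
            )
    return EvaluationReport(verdicts=verdicts, unevaluable=unevaluable, scenario=scenario)


def estimate_nonfood_fraction(beverage_share: float, nonfood_container_share: float) -> float:
    """Non-food share of the recycling feed stream from market shares, percent.

    The feed stream is assumed to consist of the beverage-bottle resin share
    plus the non-food container share only (77% + 4% of the resin market
    gives 4.94%, conventionally displayed as 5%).  Use ``round()`` of the
    result for display.
    """
    if beverage_share < 0 or nonfood_container_share < 0:
        raise ValueError("market shares must be non-negative")
    total = beverage_share + nonfood_container_share
    if total == 0:
        raise ValueError("at least one market share must be positive")
    return 100.0 * nonfood_container_share / total
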