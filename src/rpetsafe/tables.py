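"""Contamination survey tables: data model, bundled fixture, group statistics.

The bundled fixture transcribes a market survey of 36 post-consumer PET
containers from six liquid non-food product categories (dishwashing
detergents; antifreeze and dish-rinsing agents; mouthwashes; sanitary
cleaners; shampoos; shower gels and liquid soaps).  Each record is one
substance detected in the container walls of one category, with per-sample
concentrations in mg/kg PET, a Cramer toxicity class, structural-alert
flags for (non-)genotoxic carcinogenicity, and — where the published
footnotes correct a spurious or missing alert — an explicit override so
downstream routing can use the curated toxicology instead of the raw flags.

Group means count non-detected samples as zero: the survey's summary values
are arithmetic means over *all* samples of a category (e.g. benzene found at
0.9 mg/kg in one of six dishwashing bottles has a group mean of 0.15 mg/kg).
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "AlertOverride",
    "SubstanceRecord",
    "ProductCategory",
    "PooledUnknown",
    "ContaminationSurvey",
    "TableParseError",
    "TableSchemaError",
    "UndefinedMeanError",
    "TranscriptionWarning",
    "load_tables",
    "write_tables",
    "group_mean",
    "aggregate_unknowns",
]

#: Largest concentration the schema admits; the biggest surveyed value is
#: 1110 mg/kg (ethanol in a shampoo bottle).
MAX_CONCENTRATION = 2000.0

#: Molecular-weight window (g/mol) the headspace-GC method can observe.
MW_WINDOW = (40.0, 260.0)

#: Default estimated molecular-weight range for unidentified substances
#: (g/mol).  The survey states 130-160 g/mol for the sanitary-cleaner
#: unknowns; other categories' unknowns inherit it as an assumption.
DEFAULT_UNKNOWN_MW_RANGE = (130.0, 160.0)

CRAMER_CLASSES = ("I", "II", "III", "unclassifiable")
OVERRIDE_KINDS = ("wrong_positive", "wrong_negative", "known_genotoxic")


class TableParseError(ValueError):
    """A fixture row could not be parsed or violates a record invariant."""


class TableSchemaError(ValueError):
    """The fixture refers to an unknown category or malformed schema."""


class UndefinedMeanError(ValueError):
    """Group mean requested for a category with zero samples."""


class TranscriptionWarning(UserWarning):
    """A printed table value disagrees with arithmetic over the printed samples."""


@dataclass(frozen=True)
class AlertOverride:
    """Curated correction of a raw structural-alert assignment."""

    kind: str  # one of OVERRIDE_KINDS
    rationale: str = ""

    def __post_init__(self) -> None:
        if self.kind not in OVERRIDE_KINDS:
            raise TableSchemaError(f"unknown alert override kind: {self.kind!r}")


@dataclass
class SubstanceRecord:
    """One contaminant in one product category.

    ``concentrations`` maps sample id -> mg/kg in PET; absence of a sample id
    means the substance was not detected in that bottle.  Unidentified
    substances carry no CAS number and no point molecular weight, but an
    estimated molecular-weight range ``mw_range`` (g/mol).
    """

    name: str
    category_id: str
    cas: str | None = None
    molecular_weight: float | None = None
    mw_range: tuple[float, float] | None = None
    retention_time: float | None = None  # minutes
    cramer_class: str = "unclassifiable"
    gtc_alert: bool = False
    ngtc_alert: bool = False
    alert_override: AlertOverride | None = None
    concentrations: dict[int, float] = field(default_factory=dict)
    mean_printed: float | None = None
    discrepancy: str | None = None

    @property
    def is_unknown(self) -> bool:
        return self.cramer_class == "unclassifiable"

    @property
    def effective_molecular_weight(self) -> float:
        """Point molecular weight, or the midpoint of the estimated range."""
        if self.molecular_weight is not None:
            return self.molecular_weight
        if self.mw_range is not None:
            return 0.5 * (self.mw_range[0] + self.mw_range[1])
        raise TableSchemaError(f"{self.name}: no molecular weight or range available")

    def validate(self, category: "ProductCategory") -> None:
        if self.cramer_class not in CRAMER_CLASSES:
            raise TableParseError(f"{self.name}: bad Cramer class {self.cramer_class!r}")
        for sample, conc in self.concentrations.items():
            if not (0.0 <= conc <= MAX_CONCENTRATION):
                raise TableParseError(
                    f"{self.name}: concentration {conc} mg/kg outside [0, {MAX_CONCENTRATION}]"
                )
            if sample not in category.sample_ids:
                raise TableParseError(
                    f"{self.name}: sample {sample} does not belong to category {category.id!r}"
                )
        if self.molecular_weight is not None and not (
            MW_WINDOW[0] < self.molecular_weight < MW_WINDOW[1]
        ):
            raise TableParseError(
                f"{self.name}: molecular weight {self.molecular_weight} g/mol outside {MW_WINDOW}"
            )
        if self.is_unknown and self.cas:
            raise TableParseError(f"{self.name}: unidentified substance must not carry a CAS number")


@dataclass(frozen=True)
class ProductCategory:
    """One of the surveyed non-food product categories."""

    id: str
    label: str
    sample_ids: tuple[int, ...]


@dataclass(frozen=True)
class PooledUnknown:
    """All unidentified substances of a category collapsed to one surrogate."""

    category_id: str
    pooled_concentration: float  # mg/kg, sum of group means (optionally rounded up)
    representative_molecular_weight: float  # g/mol, midpoint of the overall range
    n_substances: int


@dataclass
class ContaminationSurvey:
    """Parsed survey: categories plus per-substance records."""

    categories: dict[str, ProductCategory]
    records: list[SubstanceRecord]

    def records_in(self, category_id: str) -> list[SubstanceRecord]:
        return [r for r in self.records if r.category_id == category_id]

    def unknowns_in(self, category_id: str) -> list[SubstanceRecord]:
        return [r for r in self.records_in(category_id) if r.is_unknown]

    def find(self, name: str, category_id: str | None = None) -> SubstanceRecord:
        for r in self.records:
            if r.name == name and (category_id is None or r.category_id == category_id):
                return r
        raise KeyError(f"no record named {name!r}" + (f" in {category_id!r}" if category_id else ""))


# ---------------------------------------------------------------------------
# fixture I/O

def _fixture_paths() -> tuple[Path, Path]:
    base = resources.files("rpetsafe") / "data"
    return (
        Path(str(base / "nonfood_pet_survey.csv")),
        Path(str(base / "nonfood_pet_survey_categories.json")),
    )


def _parse_float(cell: str, *, row: int, column: str) -> float | None:
    cell = cell.strip()
    if not cell:
        return None
    try:
        return float(cell)
    except ValueError as exc:
        raise TableParseError(f"row {row}: cannot parse {column}={cell!r} as a number") from exc


def load_tables(
    path: str | Path | None = None,
    sidecar: str | Path | None = None,
    *,
    warn_discrepancies: bool = True,
) -> ContaminationSurvey:
    """Read a survey CSV plus its category sidecar (defaults: bundled fixture).

    The CSV is UTF-8, comma-separated, one row per (substance, category),
    concentrations in wide per-sample columns ``s1`` ... ``sN``.  Printed
    summary values that disagree with arithmetic over the printed samples are
    surfaced as :class:`TranscriptionWarning`, not errors.
    """
    if path is None or sidecar is None:
        default_csv, default_json = _fixture_paths()
        path = Path(path) if path is not None else default_csv
        sidecar = Path(sidecar) if sidecar is not None else default_json
    path, sidecar = Path(path), Path(sidecar)

    with open(sidecar, encoding="utf-8") as fh:
        meta = json.load(fh)
    try:
        categories = {
            c["id"]: ProductCategory(c["id"], c["label"], tuple(c["samples"]))
            for c in meta["categories"]
        }
    except (KeyError, TypeError) as exc:
        raise TableSchemaError(f"malformed category sidecar {sidecar}") from exc

    with open(path, encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "name" not in reader.fieldnames:
            raise TableParseError(f"{path}: empty file or missing header")
        sample_columns = [c for c in reader.fieldnames if c.startswith("s") and c[1:].isdigit()]
        records: list[SubstanceRecord] = []
        for i, row in enumerate(reader, start=2):
            cat_id = (row.get("category") or "").strip()
            if cat_id not in categories:
                raise TableSchemaError(f"row {i}: unknown category id {cat_id!r}")
            category = categories[cat_id]
            conc: dict[int, float] = {}
            for col in sample_columns:
                value = _parse_float(row.get(col, ""), row=i, column=col)
                if value is not None:
                    conc[int(col[1:])] = value
            mw_low = _parse_float(row.get("mw_low", ""), row=i, column="mw_low")
            mw_high = _parse_float(row.get("mw_high", ""), row=i, column="mw_high")
            override = None
            if (row.get("override") or "").strip():
                override = AlertOverride(row["override"].strip(), (row.get("override_note") or "").strip())
            record = SubstanceRecord(
                name=row["name"].strip(),
                category_id=cat_id,
                cas=(row.get("cas") or "").strip() or None,
                molecular_weight=_parse_float(row.get("mw", ""), row=i, column="mw"),
                mw_range=(mw_low, mw_high) if mw_low is not None and mw_high is not None else None,
                retention_time=_parse_float(row.get("rt_min", ""), row=i, column="rt_min"),
                cramer_class=(row.get("cramer") or "unclassifiable").strip(),
                gtc_alert=(row.get("gtc") or "0").strip() in ("1", "true", "True", "+"),
                ngtc_alert=(row.get("ngtc") or "0").strip() in ("1", "true", "True", "+"),
                alert_override=override,
                concentrations=conc,
                mean_printed=_parse_float(row.get("mean_printed", ""), row=i, column="mean_printed"),
                discrepancy=(row.get("discrepancy") or "").strip() or None,
            )
            record.validate(category)
            if record.discrepancy and warn_discrepancies:
                warnings.warn(
                    f"{record.name} ({cat_id}): {record.discrepancy}", TranscriptionWarning,
                    stacklevel=2,
                )
            records.append(record)
    if not records:
        raise TableParseError(f"{path}: no substance rows")
    return ContaminationSurvey(categories=categories, records=records)


def write_tables(
    survey: ContaminationSurvey, path: str | Path, sidecar: str | Path
) -> None:
    """Serialize a survey back to the CSV schema used by :func:`load_tables`."""
    all_samples = sorted({s for c in survey.categories.values() for s in c.sample_ids})
    header = [
        "name", "cas", "mw", "mw_low", "mw_high", "rt_min", "cramer", "gtc", "ngtc",
        "override", "override_note", "category", "mean_printed", "discrepancy",
    ] + [f"s{s}" for s in all_samples]
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=header)
        writer.writeheader()
        for r in survey.records:
            row = {
                "name": r.name,
                "cas": r.cas or "",
                "mw": "" if r.molecular_weight is None else r.molecular_weight,
                "mw_low": "" if r.mw_range is None else r.mw_range[0],
                "mw_high": "" if r.mw_range is None else r.mw_range[1],
                "rt_min": "" if r.retention_time is None else r.retention_time,
                "cramer": r.cramer_class,
                "gtc": int(r.gtc_alert),
                "ngtc": int(r.ngtc_alert),
                "override": r.alert_override.kind if r.alert_override else "",
                "override_note": r.alert_override.rationale if r.alert_override else "",
                "category": r.category_id,
                "mean_printed": "" if r.mean_printed is None else r.mean_printed,
                "discrepancy": r.discrepancy or "",
            }
            row.update({f"s{s}": c for s, c in r.concentrations.items()})
            writer.writerow(row)
    with open(sidecar, "w", encoding="utf-8") as fh:
        json.dump(
            {
                "categories": [
                    {"id": c.id, "label": c.label, "samples": list(c.sample_ids)}
                    for c in survey.categories.values()
                ]
            },
            fh,
            indent=1,
        )


# ---------------------------------------------------------------------------
# group statistics

def group_mean(record: SubstanceRecord, category: ProductCategory) -> float:
    """Arithmetic mean over all samples of the category, non-detects as zero."""
    if record.category_id != category.id:
        raise ValueError(
            f"record {record.name!r} belongs to {record.category_id!r}, not {category.id!r}"
        )
    n = len(category.sample_ids)
    if n == 0:
        raise UndefinedMeanError(f"category {category.id!r} has no samples")
    return sum(record.concentrations.values()) / n


def aggregate_unknowns(
    survey: ContaminationSurvey,
    category_id: str,
    *,
    records: Sequence[SubstanceRecord] | None = None,
    rounding: str = "none",
    use_printed_means: bool = True,
) -> PooledUnknown | None:
    """Collapse a category's unidentified substances into one surrogate.

    The pooled concentration is the sum of the constituent group means,
    optionally rounded up to the next integer (``rounding="ceil"``); the
    representative molecular weight is the midpoint of the union of the
    constituents' estimated ranges.  Returns ``None`` when the category has
    no unknowns (an empty aggregate, not an error).

    By default the published per-substance summary means are summed where
    available (``use_printed_means=True``), matching the published pooling
    of the sanitary-cleaner unknowns to 1.82 mg/kg; recomputed means are
    used otherwise.
    """
    if rounding not in ("none", "ceil"):
        raise ValueError(f"unknown rounding policy {rounding!r}")
    category = survey.categories[category_id]
    unknowns = list(records) if records is not None else survey.unknowns_in(category_id)
    unknowns = [r for r in unknowns if r.is_unknown]
    if not unknowns:
        return None
    total = 0.0
    lows, highs = [], []
    for r in unknowns:
        if use_printed_means and r.mean_printed is not None:
            total += r.mean_printed
        else:
            total += group_mean(r, category)
        low, high = r.mw_range if r.mw_range is not None else DEFAULT_UNKNOWN_MW_RANGE
        lows.append(low)
        highs.append(high)
    if rounding == "ceil":
        total = float(math.ceil(total))
    return PooledUnknown(
        category_id=category_id,
        pooled_concentration=total,
        representative_molecular_weight=0.5 * (min(lows) + max(highs)),
        n_substances=len(unknowns),
    )
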