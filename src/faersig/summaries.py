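"""Descriptive outputs: demographics, quarterly report counts, sex scans.

Percentage conventions follow the published-table style of this family
of analyses: age/sex/reporter/country percentages use the total report
count as denominator, while outcome percentages use the total number of
outcome *entries* (a report can carry several outcomes, and reports with
none contribute an "Unknown" entry).  All percentages are rounded
half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

from .faers_io import QuarterRange, iterate_quarters
from .meddra import MeddraHierarchy
from .preprocess import AGE_BAND_LABELS, CaseReport, DrugMention, ReactionMention, age_band
from .signal_engine import SignalConfig, SignalResult, build_tables, evaluate_signals

OUTCOME_LABELS = {
    "HO": "Hospitalization",
    "DE": "Death",
    "LT": "Life-threatening",
    "DS": "Disability",
    "RI": "Required intervention",
    "CA": "Congenital anomaly",
    "OT": "Other",
}
OUTCOME_ORDER = ("HO", "DE", "LT", "DS", "RI", "CA", "OT")

SEX_LABELS = {"F": "Female", "M": "Male", "UNK": "Unknown"}

TOP_COUNTRIES = 4


def pct(count: int, denominator: int) -> float:
    """Percentage rounded half-up to two decimals; 0.0 on an empty denominator."""
    if denominator == 0:
        return 0.0
    value = Decimal(count) * 100 / Decimal(denominator)
    return float(value.quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class DemographicsSummary:
    """Per-drug counts/percentages by section (age, sex, reporter, country, outcome)."""

    drug: str
    n_reports: int
    sections: dict[str, list[tuple[str, int, float]]] = field(default_factory=dict)

    def lookup(self, section: str, category: str) -> tuple[int, float]:
        for cat, count, p in self.sections.get(section, []):
            if cat == category:
                return count, p
        raise KeyError(f"{section}/{category} not in summary")

    def as_rows(self) -> list[dict]:
        rows = []
        for section, entries in self.sections.items():
            for category, count, p in entries:
                rows.append({
                    "drug": self.drug, "section": section,
                    "category": category, "count": count, "pct": p,
                })
        return rows


def _counted(counts: dict[str, int], denominator: int,
             order: Sequence[str] | None = None) -> list[tuple[str, int, float]]:
    keys = list(order) if order is not None else sorted(counts, key=lambda k: (-counts[k], k))
    return [(k, counts.get(k, 0), pct(counts.get(k, 0), denominator)) for k in keys
            if counts.get(k, 0) > 0 or (order is not None)]


def summarize_demographics(reports: Sequence[CaseReport], drug: str = "") -> DemographicsSummary:
    """Table-style summary of one drug's deduplicated reports."""
    n = len(reports)
    summary = DemographicsSummary(drug=drug, n_reports=n)
    if n == 0:
        return summary

    age_counts: dict[str, int] = {}
    sex_counts: dict[str, int] = {}
    reporter_counts: dict[str, int] = {}
    country_counts: dict[str, int] = {}
    outcome_counts: dict[str, int] = {}
    n_no_outcome = 0
    for r in reports:
        age_counts[age_band(r.age_years)] = age_counts.get(age_band(r.age_years), 0) + 1
        sex_counts[r.sex] = sex_counts.get(r.sex, 0) + 1
        reporter_counts[r.reporter] = reporter_counts.get(r.reporter, 0) + 1
        country_counts[r.country] = country_counts.get(r.country, 0) + 1
        if r.outcomes:
            for code in r.outcomes:
                outcome_counts[code] = outcome_counts.get(code, 0) + 1
        else:
            n_no_outcome += 1

    summary.sections["age"] = _counted(age_counts, n, order=AGE_BAND_LABELS)
    summary.sections["sex"] = [
        (SEX_LABELS[code], sex_counts.get(code, 0), pct(sex_counts.get(code, 0), n))
        for code in ("F", "M", "UNK")
    ]
    summary.sections["reporter"] = _counted(reporter_counts, n)

    # top-k countries by count, remainder pooled as Other (UNK pools too)
    named = {k: v for k, v in country_counts.items() if k != "UNK"}
    top = sorted(named, key=lambda k: (-named[k], k))[:TOP_COUNTRIES]
    country_rows = [(k, named[k], pct(named[k], n)) for k in top]
    other = n - sum(named[k] for k in top)
    if other:
        country_rows.append(("Other", other, pct(other, n)))
    summary.sections["country"] = country_rows

    # outcome entries denominator: all outcome codes plus no-outcome reports
    denominator = sum(outcome_counts.values()) + n_no_outcome
    outcome_rows = [
        (OUTCOME_LABELS[code], outcome_counts[code], pct(outcome_counts[code], denominator))
        for code in OUTCOME_ORDER if code in outcome_counts
    ]
    outcome_rows.append(("Unknown", n_no_outcome, pct(n_no_outcome, denominator)))
    summary.sections["outcome"] = outcome_rows
    return summary


@dataclass
class QuarterSeries:
    """Report counts per quarter, zeros filled over a contiguous range."""

    drug: str
    points: list[tuple[str, int]]

    def total(self) -> int:
        return sum(count for _, count in self.points)


def quarter_series(reports: Iterable[CaseReport], qrange: QuarterRange,
                   drug: str = "") -> QuarterSeries:
    """Count deduplicated reports per quarter across ``qrange``."""
    counts: dict[str, int] = {label: 0 for label in iterate_quarters(qrange)}
    for r in reports:
        if r.quarter in counts:
            counts[r.quarter] += 1
    return QuarterSeries(drug=drug, points=list(counts.items()))


def sex_stratified_signals(
    reports: Sequence[CaseReport],
    drug_mentions: Sequence[DrugMention],
    reaction_mentions: Sequence[ReactionMention],
    target_drug: str,
    config: SignalConfig | None = None,
    level: str = "PT",
    hierarchy: MeddraHierarchy | None = None,
    strata: Sequence[str] = ("F", "M"),
) -> list[SignalResult]:
    """Rebuild tables and recompute all four statistics within each sex.

    Reports of unknown sex are excluded from the default F/M scan; the
    pooled table cells equal the cellwise sum over F, M and UNK strata.
    """
    results: list[SignalResult] = []
    for stratum in strata:
        sub_reports = [r for r in reports if r.sex == stratum]
        if not sub_reports:
            continue
        pids = {r.primaryid for r in sub_reports}
        sub_drugs = [m for m in drug_mentions if m.primaryid in pids]
        sub_reacs = [m for m in reaction_mentions if m.primaryid in pids]
        tables = build_tables(sub_reports, sub_drugs, sub_reacs, target_drug,
                              level=level, hierarchy=hierarchy)
        results.extend(evaluate_signals(
            tables, config, drug=target_drug, level=level,
            hierarchy=hierarchy, stratum=stratum,
        ))
    return results
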