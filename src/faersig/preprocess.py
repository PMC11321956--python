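"""Case deduplication, demographic cleaning, and drug-name standardization.

Spontaneous reports arrive as repeated versions of the same case; before
any counting, exactly one report per case id is retained — the one with
the latest receipt date (FDA_DT), ties broken by the larger numeric
primaryid so the result is deterministic.  Demographic fields are
cleaned (age unit conversion, implausible values censored), verbatim
drug names are mapped onto standard generic names through a synonym
dictionary, and the per-report data model is assembled with referential
integrity against the surviving primaryids.
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

UNMAPPED = "UNMAPPED"

VALID_OUTCOMES = ("HO", "DE", "LT", "DS", "RI", "CA", "OT")
DRUG_ROLES = ("PS", "SS", "C", "I")

REPORTER_CODES = {
    "MD": "physician",
    "PH": "pharmacist",
    "OT": "other-health-professional",
    "CN": "consumer",
    "LW": "lawyer",
    "RN": "registered-nurse",
}

#: multiplier converting an age value under a given unit code into years
AGE_UNIT_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "": 1.0,  # blank unit: value taken as years
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.143,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

AGE_MIN, AGE_MAX = 0.0, 120.0


@dataclass
class CaseReport:
    """One deduplicated safety report."""

    primaryid: str
    caseid: str
    fda_date: str
    event_date: str | None = None
    age_years: float | None = None
    sex: str = "UNK"
    reporter: str = "unknown"
    country: str = "UNK"
    quarter: str = ""
    outcomes: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class DrugMention:
    primaryid: str
    seq: int
    role: str
    verbatim_name: str
    standard_name: str


@dataclass(frozen=True)
class ReactionMention:
    primaryid: str
    pt: str


@dataclass
class CleaningAction:
    """One censored/normalized field, for the cleaning log."""

    field: str
    raw_value: str
    action: str


@dataclass
class SynonymDictionary:
    """Verbatim drug name -> standard generic name lookup.

    Keys are case-folded, punctuation-stripped, whitespace-collapsed.
    """

    entries: dict[str, str] = field(default_factory=dict)

    @classmethod
    def load(cls, path: str | Path) -> "SynonymDictionary":
        """Load a two-column tab-separated file; '#' starts a comment line."""
        entries: dict[str, str] = {}
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) < 2 or not parts[1].strip():
                    raise ValueError(f"synonym line needs two columns: {line!r}")
                entries[normalize_drug_name(parts[0])] = parts[1].strip().lower()
        return cls(entries)

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("# verbatim\tstandard\n")
            for verbatim, standard in sorted(self.entries.items()):
                fh.write(f"{verbatim}\t{standard}\n")


_PUNCT_TABLE = str.maketrans({ch: " " for ch in string.punctuation})
_NUMBER_RE = re.compile(r"^\d+(\.\d+)?$")

#: dose/route tokens dropped on the second lookup attempt
_SUFFIX_TOKENS = {"mg", "ml", "tablet", "tablets", "injection", "capsule", "capsules"}


def normalize_drug_name(name: str) -> str:
    """Case-fold, strip punctuation, collapse whitespace."""
    return " ".join(name.casefold().translate(_PUNCT_TABLE).split())


def standardize_drug(
    verbatim: str,
    synonyms: SynonymDictionary,
    log: list[CleaningAction] | None = None,
) -> str:
    """Map a verbatim drug name to its standard generic name.

    Lookup runs on the normalized name; on a miss, dose/route suffix
    tokens (pure numbers, MG, ML, TABLET, INJECTION, ...) are stripped
    and the lookup retried.  Unmapped names return :data:`UNMAPPED`.
    """
    key = normalize_drug_name(verbatim)
    if key in synonyms.entries:
        return synonyms.entries[key]
    stripped = " ".join(
        tok for tok in key.split()
        if tok not in _SUFFIX_TOKENS and not _NUMBER_RE.match(tok)
    )
    if stripped and stripped in synonyms.entries:
        return synonyms.entries[stripped]
    if log is not None:
        log.append(CleaningAction("drugname", verbatim, "unmapped"))
    return UNMAPPED


def clean_age(
    raw_age: str,
    age_code: str,
    log: list[CleaningAction] | None = None,
) -> float | None:
    """Convert a raw (value, unit-code) age pair into years.

    Unparsable values, unknown unit codes, and results outside
    [0, 120] years become missing; anomalies are appended to ``log``.
    """
    raw_age = (raw_age or "").strip()
    code = (age_code or "").strip().upper()
    if raw_age == "":
        return None
    factor = AGE_UNIT_FACTORS.get(code)
    if factor is None:
        if log is not None:
            log.append(CleaningAction("age", f"{raw_age} {code}", "unknown-unit"))
        return None
    try:
        value = float(raw_age)
    except ValueError:
        if log is not None:
            log.append(CleaningAction("age", raw_age, "unparsable"))
        return None
    years = value * factor
    if not AGE_MIN <= years <= AGE_MAX:
        if log is not None:
            log.append(CleaningAction("age", f"{raw_age} {code}", "out-of-range"))
        return None
    return years


AGE_BAND_LABELS = ("<18", "18-45", "45-65", "65-75", ">=75", "Unknown")


def age_band(age_years: float | None) -> str:
    """Age band with half-open boundaries [0,18), [18,45), [45,65), [65,75), [75,inf)."""
    if age_years is None:
        return "Unknown"
    if age_years < 18:
        return "<18"
    if age_years < 45:
        return "18-45"
    if age_years < 65:
        return "45-65"
    if age_years < 75:
        return "65-75"
    return ">=75"


def _clean_sex(raw: str) -> str:
    raw = (raw or "").strip().upper()
    return raw if raw in ("F", "M") else "UNK"


def _clean_reporter(raw: str) -> str:
    return REPORTER_CODES.get((raw or "").strip().upper(), "unknown")


def _clean_country(row: Mapping[str, str]) -> str:
    country = (row.get("OCCR_COUNTRY") or "").strip()
    if not country:
        country = (row.get("REPORTER_COUNTRY") or "").strip()
    return country or "UNK"


def _report_from_row(row: Mapping[str, str], log: list[CleaningAction]) -> CaseReport:
    sex = _clean_sex(row.get("SEX") or row.get("GNDR_COD") or "")
    return CaseReport(
        primaryid=(row.get("PRIMARYID") or "").strip(),
        caseid=(row.get("CASEID") or "").strip(),
        fda_date=(row.get("FDA_DT") or "").strip(),
        event_date=(row.get("EVENT_DT") or "").strip() or None,
        age_years=clean_age(row.get("AGE", ""), row.get("AGE_COD", ""), log),
        sex=sex,
        reporter=_clean_reporter(row.get("OCCP_COD", "")),
        country=_clean_country(row),
        quarter=(row.get("QUARTER") or "").strip(),
        outcomes=set(),
    )


def _date_key(fda_date: str) -> int:
    digits = re.sub(r"\D", "", fda_date)
    return int(digits) if digits else -1


def _numeric_id(primaryid: str) -> int:
    digits = re.sub(r"\D", "", primaryid)
    return int(digits) if digits else -1


def _caseid_sort_key(caseid: str) -> tuple[int, str]:
    return (int(caseid), "") if caseid.isdigit() else (1 << 62, caseid)


def deduplicate(
    demo_rows: Iterable[Mapping[str, str]],
    log: list[CleaningAction] | None = None,
) -> tuple[list[CaseReport], list[Mapping[str, str]]]:
    """Retain exactly one report per caseid: latest FDA_DT, then max primaryid.

    Returns ``(survivors, rejects)``; rows without a caseid are routed to
    the rejects list, never silently dropped.  Output is sorted by caseid.
    """
    if log is None:
        log = []
    best: dict[str, tuple[tuple[int, int], CaseReport]] = {}
    rejects: list[Mapping[str, str]] = []
    for row in demo_rows:
        caseid = (row.get("CASEID") or "").strip()
        if not caseid:
            rejects.append(row)
            continue
        report = _report_from_row(row, log)
        key = (_date_key(report.fda_date), _numeric_id(report.primaryid))
        incumbent = best.get(caseid)
        if incumbent is None or key > incumbent[0]:
            best[caseid] = (key, report)
    survivors = [report for _, report in best.values()]
    survivors.sort(key=lambda r: _caseid_sort_key(r.caseid))
    return survivors, rejects


@dataclass
class AssembledCorpus:
    """Deduplicated reports plus mention tables restricted to them."""

    reports: list[CaseReport]
    drug_mentions: list[DrugMention]
    reaction_mentions: list[ReactionMention]
    rejects: dict[str, int] = field(default_factory=dict)


def assemble(
    reports: list[CaseReport],
    drug_rows: Iterable[Mapping[str, str]],
    reac_rows: Iterable[Mapping[str, str]],
    outc_rows: Iterable[Mapping[str, str]],
    synonyms: SynonymDictionary,
    log: list[CleaningAction] | None = None,
) -> AssembledCorpus:
    """Attach drug/reaction/outcome rows to surviving reports.

    Mentions whose primaryid is not among the survivors (orphans of
    deleted duplicate versions, or genuinely dangling rows) are counted
    in the rejects tally.  Referential integrity holds on the output.
    """
    by_pid = {r.primaryid: r for r in reports}
    rejects = {"orphan_drug": 0, "orphan_reac": 0, "orphan_outc": 0,
               "bad_role": 0, "empty_pt": 0, "bad_outcome": 0}

    drug_mentions: list[DrugMention] = []
    for i, row in enumerate(drug_rows):
        pid = (row.get("PRIMARYID") or "").strip()
        if pid not in by_pid:
            rejects["orphan_drug"] += 1
            continue
        role = (row.get("ROLE_COD") or "").strip().upper()
        if role not in DRUG_ROLES:
            rejects["bad_role"] += 1
            continue
        verbatim = (row.get("DRUGNAME") or "").strip()
        seq_raw = (row.get("DRUG_SEQ") or "").strip()
        drug_mentions.append(DrugMention(
            primaryid=pid,
            seq=int(seq_raw) if seq_raw.isdigit() else i,
            role=role,
            verbatim_name=verbatim,
            standard_name=standardize_drug(verbatim, synonyms, log),
        ))

    reaction_mentions: list[ReactionMention] = []
    for row in reac_rows:
        pid = (row.get("PRIMARYID") or "").strip()
        if pid not in by_pid:
            rejects["orphan_reac"] += 1
            continue
        pt = (row.get("PT") or "").strip()
        if not pt:
            rejects["empty_pt"] += 1
            continue
        reaction_mentions.append(ReactionMention(primaryid=pid, pt=pt))

    for row in outc_rows:
        pid = (row.get("PRIMARYID") or "").strip()
        if pid not in by_pid:
            rejects["orphan_outc"] += 1
            continue
        code = (row.get("OUTC_COD") or "").strip().upper()
        if code not in VALID_OUTCOMES:
            rejects["bad_outcome"] += 1
            continue
        by_pid[pid].outcomes.add(code)

    return AssembledCorpus(
        reports=reports,
        drug_mentions=drug_mentions,
        reaction_mentions=reaction_mentions,
        rejects=rejects,
    )


def pool_quarters(rawsets: Iterable) -> tuple[list[dict], list[dict], list[dict], list[dict]]:
    """Concatenate quarter table sets, stamping DEMO rows with their quarter."""
    demo: list[dict] = []
    drug: list[dict] = []
    reac: list[dict] = []
    outc: list[dict] = []
    for ts in rawsets:
        for row in ts.demo_rows:
            stamped = dict(row)
            stamped["QUARTER"] = ts.quarter
            demo.append(stamped)
        drug.extend(ts.drug_rows)
        reac.extend(ts.reac_rows)
        outc.extend(ts.outc_rows)
    return demo, drug, reac, outc
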