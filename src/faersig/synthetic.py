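"""FAERS-like corpus generator with known ground truth.

Reports are drawn from a multinomial background of adverse-event terms;
selected (drug, PT) pairs carry a planted relative risk (optionally
sex-specific) applied multiplicatively and renormalized, so the odds of
reporting the planted term on the planted drug versus any other drug is
the configured rho.  Duplicate case submissions, missing demographics,
and per-drug marketing-start quarters are all emulated, and the
generator keeps its own bookkeeping (:class:`GroundTruth`) so pipeline
cell counts can be verified against an independent tally.

Fixed seed => byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .faers_io import QuarterRange, RawTableSet, quarter_index, quarter_label, write_quarter
from .meddra import MeddraHierarchy
from .preprocess import SynonymDictionary, normalize_drug_name
from .signal_engine import ContingencyTable


class ConfigError(ValueError):
    """Infeasible or inconsistent synthetic configuration."""


@dataclass(frozen=True)
class DrugSpec:
    name: str
    marketing_start: str
    share: float


@dataclass(frozen=True)
class EventSpec:
    pt: str
    soc: str
    p: float


@dataclass(frozen=True)
class PlantedSignal:
    """A (drug, PT) pair reported with relative risk ``rr`` (sex multipliers optional)."""

    drug: str
    pt: str
    rr: float
    female_mult: float = 1.0
    male_mult: float = 1.0


_COUNTRIES = ("US", "FR", "KR", "JP", "DE", "GB")
_COUNTRY_P = (0.45, 0.12, 0.12, 0.08, 0.13, 0.10)
_OCCP = ("MD", "PH", "OT", "CN", "")
_OCCP_P = (0.35, 0.2, 0.18, 0.22, 0.05)


@dataclass
class SyntheticConfig:
    seed: int
    n_reports: int
    quarter_range: QuarterRange
    drugs: list[DrugSpec]
    events: list[EventSpec]
    planted: list[PlantedSignal] = field(default_factory=list)
    duplicate_rate: float = 0.0
    missing_age: float = 0.1
    missing_sex: float = 0.05
    missing_country: float = 0.05
    female_share: float = 0.55
    pts_per_report: dict[int, float] = field(
        default_factory=lambda: {1: 0.35, 2: 0.30, 3: 0.20, 4: 0.15})
    n_background_drugs: int = 10
    outcome_probs: dict[str, float] = field(
        default_factory=lambda: {"HO": 0.12, "DE": 0.04, "LT": 0.02, "OT": 0.10})
    concomitant_rate: float = 0.2
    verbatim_noise: float = 0.2

    def __post_init__(self) -> None:
        if self.n_reports <= 0:
            raise ConfigError("n_reports must be positive")
        total_share = sum(d.share for d in self.drugs)
        if total_share > 1.0 + 1e-9:
            raise ConfigError("drug shares sum to more than 1")
        if total_share < 1.0 - 1e-9 and self.n_background_drugs == 0:
            raise ConfigError("shares below 1 need background drugs to absorb the rest")
        for rate in (self.duplicate_rate, self.missing_age, self.missing_sex,
                     self.missing_country, self.female_share, self.concomitant_rate,
                     self.verbatim_noise):
            if not 0.0 <= rate <= 1.0:
                raise ConfigError(f"rate {rate} outside [0, 1]")
        psum = sum(e.p for e in self.events)
        if psum <= 0:
            raise ConfigError("event baseline probabilities must sum to a positive value")
        if abs(psum - 1.0) > 1e-6:
            raise ConfigError("event baseline probabilities must sum to 1")
        event_names = {e.pt for e in self.events}
        drug_names = {d.name for d in self.drugs}
        p_by_pt = {e.pt: e.p for e in self.events}
        for sig in self.planted:
            if sig.rr <= 0:
                raise ConfigError("planted relative risk must be positive")
            if sig.drug not in drug_names:
                raise ConfigError(f"planted drug {sig.drug!r} not in drug list")
            if sig.pt not in event_names:
                raise ConfigError(f"planted PT {sig.pt!r} not in event list")
            worst = sig.rr * max(sig.female_mult, sig.male_mult)
            if p_by_pt[sig.pt] * worst >= 0.95:
                raise ConfigError(
                    f"planted risk for {sig.drug}/{sig.pt} too large to renormalize")
        for d in self.drugs:
            if quarter_index(d.marketing_start) > quarter_index(self.quarter_range.end):
                raise ConfigError(
                    f"{d.name}: marketing start {d.marketing_start} after range end")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            seed=int(raw["seed"]),
            n_reports=int(raw["n_reports"]),
            quarter_range=QuarterRange(raw["quarter_start"], raw["quarter_end"]),
            drugs=[DrugSpec(d["name"], d["marketing_start"], float(d["share"]))
                   for d in raw["drugs"]],
            events=[EventSpec(e["pt"], e["soc"], float(e["p"])) for e in raw["events"]],
            planted=[PlantedSignal(
                p["drug"], p["pt"], float(p["rr"]),
                float(p.get("female_mult", 1.0)), float(p.get("male_mult", 1.0)),
            ) for p in raw.get("planted", [])],
            **{k: raw[k] for k in (
                "duplicate_rate", "missing_age", "missing_sex", "missing_country",
                "female_share", "n_background_drugs", "concomitant_rate",
                "verbatim_noise",
            ) if k in raw},
            **({"pts_per_report": {int(k): float(v)
                                   for k, v in raw["pts_per_report"].items()}}
               if "pts_per_report" in raw else {}),
            **({"outcome_probs": {str(k): float(v)
                                  for k, v in raw["outcome_probs"].items()}}
               if "outcome_probs" in raw else {}),
        )


@dataclass(frozen=True)
class ReportTruth:
    """Final (post-dedup) content of one case."""

    primaryid: str
    caseid: str
    drug: str
    pts: tuple[str, ...]
    sex: str
    age: float | None
    quarter: str


@dataclass
class GroundTruth:
    """Generator bookkeeping for oracle checks against the pipeline."""

    reports: list[ReportTruth]
    versions: dict[str, list[tuple[str, str]]]  # caseid -> [(primaryid, fda_dt), ...]
    planted: list[PlantedSignal]
    drug_names: list[str]
    event_names: list[str]

    def truth_table(self, drug: str, pt: str) -> ContingencyTable:
        """Realized 2x2 cell counts, tallied directly from the bookkeeping.

        Deliberately independent of the pipeline's table builder: a plain
        loop over final report contents.
        """
        if not self.reports:
            raise ValueError("empty corpus")
        if drug not in self.drug_names:
            raise KeyError(f"unknown drug {drug!r}")
        if pt not in self.event_names:
            raise KeyError(f"unknown PT {pt!r}")
        a = b = c = d = 0
        for r in self.reports:
            hits = 1 if pt in r.pts else 0
            others = len(r.pts) - hits
            if r.drug == drug:
                a += hits
                b += others
            else:
                c += hits
                d += others
        return ContingencyTable(a=a, b=b, c=c, d=d)


def truth_table(gt: GroundTruth, drug: str, pt: str) -> ContingencyTable:
    return gt.truth_table(drug, pt)


def synonyms_for(config: SyntheticConfig) -> SynonymDictionary:
    """Identity synonym entries for every generated drug name."""
    entries = {}
    for name in _all_drug_names(config):
        entries[normalize_drug_name(name)] = name.lower()
    return SynonymDictionary(entries)


def hierarchy_for(config: SyntheticConfig) -> MeddraHierarchy:
    """PT -> SOC hierarchy matching the configured event list."""
    return MeddraHierarchy({" ".join(e.pt.casefold().split()): e.soc for e in config.events})


def _all_drug_names(config: SyntheticConfig) -> list[str]:
    background = [f"backdrug{i:02d}" for i in range(config.n_background_drugs)]
    return [d.name for d in config.drugs] + background


def _event_pvec(config: SyntheticConfig, drug: str, sex: str,
                base: np.ndarray, index: Mapping[str, int]) -> np.ndarray:
    weights = base.copy()
    for sig in config.planted:
        if sig.drug != drug:
            continue
        mult = sig.rr * (sig.female_mult if sex == "F" else sig.male_mult)
        weights[index[sig.pt]] *= mult
    return weights / weights.sum()


def generate(config: SyntheticConfig) -> tuple[dict[str, RawTableSet], GroundTruth]:
    """Draw a synthetic corpus; returns per-quarter raw tables and ground truth."""
    rng = np.random.default_rng(config.seed)
    n = config.n_reports

    drug_names = _all_drug_names(config)
    shares = np.array(
        [d.share for d in config.drugs]
        + [(1.0 - sum(d.share for d in config.drugs)) / max(config.n_background_drugs, 1)]
        * config.n_background_drugs
    )
    shares = np.clip(shares, 0.0, None)
    shares /= shares.sum()

    event_names = [e.pt for e in config.events]
    event_index = {pt: i for i, pt in enumerate(event_names)}
    base_p = np.array([e.p for e in config.events])

    starts = np.array(
        [max(quarter_index(d.marketing_start), quarter_index(config.quarter_range.start))
         for d in config.drugs]
        + [quarter_index(config.quarter_range.start)] * config.n_background_drugs
    )
    end = quarter_index(config.quarter_range.end)

    # --- vector draws (fixed order for determinism) -----------------------
    drug_idx = rng.choice(len(drug_names), size=n, p=shares)
    true_female = rng.random(n) < config.female_share
    sex_missing = rng.random(n) < config.missing_sex
    ages = np.clip(rng.normal(55.0, 15.0, size=n), 1.0, 95.0).round(1)
    age_missing = rng.random(n) < config.missing_age
    country_idx = rng.choice(len(_COUNTRIES), size=n, p=_COUNTRY_P)
    country_missing = rng.random(n) < config.missing_country
    occp_idx = rng.choice(len(_OCCP), size=n, p=_OCCP_P)
    spans = end - starts[drug_idx] + 1
    q_idx = starts[drug_idx] + np.floor(rng.random(n) * spans).astype(int)
    k_values = np.array(sorted(config.pts_per_report))
    k_probs = np.array([config.pts_per_report[k] for k in k_values], dtype=float)
    k_probs /= k_probs.sum()
    n_pts = rng.choice(k_values, size=n, p=k_probs)
    base_month = rng.integers(0, 3, size=n)
    base_day = rng.integers(1, 26, size=n)
    dup_mask = rng.random(n) < config.duplicate_rate
    dup_extra = rng.integers(1, 3, size=n)  # 1 or 2 extra versions
    outcome_masks = {
        code: rng.random(n) < p for code, p in sorted(config.outcome_probs.items())
    }
    concomitant = (rng.random(n) < config.concomitant_rate) & (config.n_background_drugs > 0)
    concomitant_pick = (
        rng.integers(0, config.n_background_drugs, size=n)
        if config.n_background_drugs > 0 else np.zeros(n, dtype=int)
    )
    noisy_name = rng.random(n) < config.verbatim_noise

    # --- event draws, grouped by shared probability vector ----------------
    planted_drugs = {sig.drug for sig in config.planted}
    group_of = np.zeros(n, dtype=np.int64)
    group_keys: dict[tuple[str, str], int] = {}
    for i in range(n):
        name = drug_names[drug_idx[i]]
        key = (name, "F" if true_female[i] else "M") if name in planted_drugs else ("", "")
        if key not in group_keys:
            group_keys[key] = len(group_keys)
        group_of[i] = group_keys[key]

    pts_of: list[tuple[str, ...]] = [()] * n
    for key, gid in sorted(group_keys.items(), key=lambda kv: kv[1]):
        members = np.flatnonzero(group_of == gid)
        if key == ("", ""):
            pvec = base_p / base_p.sum()
        else:
            pvec = _event_pvec(config, key[0], key[1], base_p, event_index)
        cum = np.cumsum(pvec)
        cum[-1] = 1.0
        max_k = int(n_pts[members].max())
        draws = np.searchsorted(cum, rng.random((len(members), max_k)), side="right")
        for row, i in enumerate(members):
            seen = dict.fromkeys(draws[row, : n_pts[i]])
            pts_of[i] = tuple(event_names[j] for j in seen)

    # --- emit rows --------------------------------------------------------
    by_quarter: dict[str, RawTableSet] = {
        label: RawTableSet(quarter=label)
        for label in QuarterRange(config.quarter_range.start,
                                  config.quarter_range.end).labels()
    }
    reports: list[ReportTruth] = []
    versions: dict[str, list[tuple[str, str]]] = {}

    for i in range(n):
        caseid = str(10_000_000 + i)
        quarter = quarter_label(int(q_idx[i]))
        year, q = int(quarter[:4]), int(quarter[-1])
        month = (q - 1) * 3 + 1 + int(base_month[i])
        n_versions = 1 + (int(dup_extra[i]) if dup_mask[i] else 0)
        drug = drug_names[drug_idx[i]]
        sex = "" if sex_missing[i] else ("F" if true_female[i] else "M")
        age = "" if age_missing[i] else f"{ages[i]:g}"
        country = "" if country_missing[i] else _COUNTRIES[country_idx[i]]
        verbatim = drug.upper() + (" 125 MG" if noisy_name[i] else "")
        tables = by_quarter[quarter]

        case_versions: list[tuple[str, str]] = []
        for v in range(1, n_versions + 1):
            primaryid = f"{caseid}{v}"
            fda_dt = f"{year:04d}{month:02d}{int(base_day[i]) + v - 1:02d}"
            case_versions.append((primaryid, fda_dt))
            tables.demo_rows.append({
                "PRIMARYID": primaryid, "CASEID": caseid, "FDA_DT": fda_dt,
                "EVENT_DT": "", "AGE": age, "AGE_COD": "YR" if age else "",
                "SEX": sex, "OCCP_COD": _OCCP[occp_idx[i]],
                "OCCR_COUNTRY": country, "REPORTER_COUNTRY": country,
            })
            tables.drug_rows.append({
                "PRIMARYID": primaryid, "DRUG_SEQ": "1", "ROLE_COD": "PS",
                "DRUGNAME": verbatim,
            })
            if concomitant[i]:
                tables.drug_rows.append({
                    "PRIMARYID": primaryid, "DRUG_SEQ": "2", "ROLE_COD": "C",
                    "DRUGNAME": f"backdrug{int(concomitant_pick[i]):02d}".upper(),
                })
            for pt in pts_of[i]:
                tables.reac_rows.append({"PRIMARYID": primaryid, "PT": pt})
            for code, mask in outcome_masks.items():
                if mask[i]:
                    tables.outc_rows.append({"PRIMARYID": primaryid, "OUTC_COD": code})

        versions[caseid] = case_versions
        reports.append(ReportTruth(
            primaryid=case_versions[-1][0],
            caseid=caseid,
            drug=drug,
            pts=pts_of[i],
            sex=sex or "UNK",
            age=float(ages[i]) if not age_missing[i] else None,
            quarter=quarter,
        ))

    gt = GroundTruth(
        reports=reports,
        versions=versions,
        planted=list(config.planted),
        drug_names=drug_names,
        event_names=event_names,
    )
    return by_quarter, gt


def generate_to_dir(config: SyntheticConfig, directory: str | Path,
                    ) -> tuple[dict[str, RawTableSet], GroundTruth]:
    """Generate and write quarter files plus sidecar dictionaries/ground truth."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    by_quarter, gt = generate(config)
    for tables in by_quarter.values():
        write_quarter(tables, directory)

    synonyms_for(config).save(directory / "synonyms.tsv")
    with open(directory / "hierarchy.tsv", "w", encoding="utf-8") as fh:
        fh.write("pt\tsoc\n")
        for e in config.events:
            fh.write(f"{e.pt}\t{e.soc}\n")
    with open(directory / "ground_truth_reports.tsv", "w", encoding="utf-8") as fh:
        fh.write("primaryid\tcaseid\tdrug\tpts\tsex\tage\tquarter\n")
        for r in gt.reports:
            age = "" if r.age is None else f"{r.age:g}"
            fh.write(f"{r.primaryid}\t{r.caseid}\t{r.drug}\t{';'.join(r.pts)}"
                     f"\t{r.sex}\t{age}\t{r.quarter}\n")
    with open(directory / "ground_truth_planted.tsv", "w", encoding="utf-8") as fh:
        fh.write("drug\tpt\trr\tfemale_mult\tmale_mult\ta\tb\tc\td\n")
        for sig in gt.planted:
            t = gt.truth_table(sig.drug, sig.pt)
            fh.write(f"{sig.drug}\t{sig.pt}\t{sig.rr:g}\t{sig.female_mult:g}"
                     f"\t{sig.male_mult:g}\t{t.a}\t{t.b}\t{t.c}\t{t.d}\n")
    return by_quarter, gt
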