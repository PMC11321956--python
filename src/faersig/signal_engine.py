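"""Drug–event 2x2 contingency tables and disproportionality statistics.

Every statistic consumes the same 2x2 table of (report, term) pair
counts::

                    target event    other events
    target drug          a               b
    other drugs          c               d

with N = a + b + c + d.  Four statistics are computed, each with the
signal rule conventional in the spontaneous-reporting literature:

* ROR  — reporting odds ratio, Woolf (log-scale) 95% CI; signal when the
  lower bound exceeds 1.
* PRR  — proportional reporting ratio plus the Pearson chi-square of the
  table; signal when PRR >= 2 and chi2 >= 4.
* BCPNN IC — information component log2(a·N / ((a+b)(a+c))) with the
  closed-form Bayesian lower bound IC025 = E(IC) - 2*sqrt(V(IC)); signal
  when IC025 > 0.
* EBGM — observed/expected ratio a·N/((a+b)(a+c)) with the one-sided
  lower 5% bound EB05 = exp(ln EBGM - 1.64*sqrt(1/a+1/b+1/c+1/d));
  signal when EB05 > 2.  A full gamma-mixture empirical-Bayes backend
  (:func:`mgps_ebgm`) is available as an optional alternative.

Terms reported fewer than ``min_a`` times (default 3) are excluded
before any statistic is computed.  Zero cells make a statistic
degenerate (reported as NaN) unless the Haldane +0.5 policy is enabled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize, special, stats

from .meddra import UNMAPPED, MeddraHierarchy, soc_of
from .preprocess import CaseReport, DrugMention, ReactionMention

logger = logging.getLogger(__name__)

Z_95 = 1.96        # two-sided 95% normal quantile (Woolf CI)
Z_90_ONE_SIDED = 1.64   # one-sided 5% bound for EB05
LN2 = math.log(2.0)

# closed-form BCPNN prior constants (Bate et al. convention)
BCPNN_ALPHA1 = 1.0
BCPNN_BETA1 = 1.0
BCPNN_ALPHA = 2.0
BCPNN_BETA = 2.0
BCPNN_GAMMA11 = 1.0


@dataclass(frozen=True)
class ContingencyTable:
    """The a, b, c, d cells of one drug–event 2x2 table."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ValueError(f"cell {name} must be a non-negative integer, got {value!r}")
        if self.N == 0:
            raise ValueError("empty table: N must be positive")

    @property
    def N(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class SignalThresholds:
    """Signal rules: a>=min_a, ROR lower CI>1, PRR>=2 & chi2>=4, IC025>0, EB05>2."""

    min_a: int = 3
    ror_ci_lower: float = 1.0
    prr_min: float = 2.0
    chi2_min: float = 4.0
    ic025_min: float = 0.0
    eb05_min: float = 2.0

    def __post_init__(self) -> None:
        if self.min_a < 1:
            raise ValueError("min_a must be >= 1")


@dataclass(frozen=True)
class SignalConfig:
    """Statistic options: zero-cell policy, Yates switch, EBGM backend."""

    thresholds: SignalThresholds = field(default_factory=SignalThresholds)
    zero_cell: str = "degenerate"      # "degenerate" | "haldane"
    yates: bool = False
    ebgm_backend: str = "closed_form"  # "closed_form" | "mgps"

    def __post_init__(self) -> None:
        if self.zero_cell not in ("degenerate", "haldane"):
            raise ValueError(f"unknown zero-cell policy {self.zero_cell!r}")
        if self.ebgm_backend not in ("closed_form", "mgps"):
            raise ValueError(f"unknown EBGM backend {self.ebgm_backend!r}")


@dataclass
class SignalResult:
    """One drug–event row with all four statistics and their flags."""

    drug: str
    term: str
    level: str                  # "PT" | "SOC"
    a: int
    b: int
    c: int
    d: int
    ror: float
    ror_lo: float
    ror_hi: float
    prr: float
    chi2: float
    ic: float
    ic025: float
    ebgm: float
    eb05: float
    flag_ror: bool
    flag_prr: bool
    flag_bcpnn: bool
    flag_ebgm: bool
    soc: str = ""
    stratum: str = ""

    @property
    def n_positive(self) -> int:
        return sum((self.flag_ror, self.flag_prr, self.flag_bcpnn, self.flag_ebgm))


# ---------------------------------------------------------------------------
# statistics on a single table
# ---------------------------------------------------------------------------

def _effective_cells(t: ContingencyTable, zero_cell: str) -> tuple[float, float, float, float]:
    cells = t.cells()
    if zero_cell == "haldane" and 0 in cells:
        return tuple(x + 0.5 for x in cells)  # type: ignore[return-value]
    return tuple(float(x) for x in cells)  # type: ignore[return-value]


def ror(t: ContingencyTable, zero_cell: str = "degenerate") -> tuple[float, float, float]:
    """Reporting odds ratio with Woolf 95% CI: exp(ln ROR ± 1.96·SE).

    Any zero cell makes the statistic degenerate (NaN) under the default
    policy; the "haldane" policy adds 0.5 to every cell instead.
    """
    a, b, c, d = _effective_cells(t, zero_cell)
    if min(a, b, c, d) == 0:
        return (math.nan, math.nan, math.nan)
    point = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (point, point * math.exp(-Z_95 * se), point * math.exp(Z_95 * se))


def chi_square(t: ContingencyTable, yates: bool = False) -> float:
    """Pearson chi-square with expected counts from the fixed margins."""
    a, b, c, d = (float(x) for x in t.cells())
    n = a + b + c + d
    rows = (a + b, c + d)
    cols = (a + c, b + d)
    if 0 in rows or 0 in cols:
        return math.nan
    observed = ((a, b), (c, d))
    total = 0.0
    for i in range(2):
        for j in range(2):
            expected = rows[i] * cols[j] / n
            diff = abs(observed[i][j] - expected)
            if yates:
                diff = max(diff - 0.5, 0.0)
            total += diff * diff / expected
    return total


def prr(
    t: ContingencyTable,
    zero_cell: str = "degenerate",
    yates: bool = False,
) -> tuple[float, float]:
    """Proportional reporting ratio and the table's chi-square.

    PRR = [a/(a+b)] / [c/(c+d)].  A zero margin (or zero c under the
    default policy) makes PRR degenerate; chi-square only needs positive
    margins and is computed on the raw cells.
    """
    chi2 = chi_square(t, yates=yates)
    a, b, c, d = _effective_cells(t, zero_cell)
    if a + b == 0 or c + d == 0 or c == 0:
        return (math.nan, chi2)
    return ((a / (a + b)) / (c / (c + d)), chi2)


def _observed_over_expected(a: float, b: float, c: float, d: float) -> float:
    n = a + b + c + d
    denom = (a + b) * (a + c)
    if denom == 0:
        return math.nan
    return a * n / denom


def bcpnn_ic(t: ContingencyTable) -> tuple[float, float]:
    """BCPNN information component and its closed-form lower bound IC025.

    The point estimate is ``log2(a·N / ((a+b)(a+c)))`` (``-inf`` when
    a = 0).  IC025 = E(IC) − 2·sqrt(V(IC)) uses the closed-form posterior
    moments with priors alpha1 = beta1 = 1, alpha = beta = 2, gamma11 = 1
    and gamma tuned so the prior IC expectation is 0; the prior keeps the
    moments finite even at a = 0.
    """
    a, b, c, d = (float(x) for x in t.cells())
    n = a + b + c + d
    if n == 0:
        raise ValueError("empty table")
    oe = _observed_over_expected(a, b, c, d)
    if math.isnan(oe):
        ic_point = math.nan
    elif oe == 0.0:
        ic_point = -math.inf
    else:
        ic_point = math.log2(oe)

    a1, b1 = BCPNN_ALPHA1, BCPNN_BETA1
    al, be, g11 = BCPNN_ALPHA, BCPNN_BETA, BCPNN_GAMMA11
    row = a + b
    col = a + c
    gamma = g11 * (n + al) * (n + be) / ((row + a1) * (col + b1))
    e_ic = math.log2(
        (a + g11) * (n + al) * (n + be) / ((n + gamma) * (row + a1) * (col + b1))
    )
    v_ic = (
        (n - a + gamma - g11) / ((a + g11) * (1 + n + gamma))
        + (n - row + al - a1) / ((row + a1) * (1 + n + al))
        + (n - col + be - b1) / ((col + b1) * (1 + n + be))
    ) / (LN2 * LN2)
    ic025 = e_ic - 2.0 * math.sqrt(v_ic)
    return (ic_point, ic025)


def ebgm(t: ContingencyTable, zero_cell: str = "degenerate") -> tuple[float, float]:
    """Observed/expected ratio EBGM = a·N/((a+b)(a+c)) with its EB05 bound.

    EB05 = exp(ln EBGM − 1.64·sqrt(1/a + 1/b + 1/c + 1/d)); a zero cell
    leaves EB05 degenerate while EBGM is still reported when the margins
    are positive.
    """
    a0, b0, c0, d0 = (float(x) for x in t.cells())
    point = _observed_over_expected(a0, b0, c0, d0)
    a, b, c, d = _effective_cells(t, zero_cell)
    if min(a, b, c, d) == 0 or math.isnan(point) or point == 0.0:
        return (point, math.nan)
    if zero_cell == "haldane" and 0 in t.cells():
        point_eff = _observed_over_expected(a, b, c, d)
    else:
        point_eff = point
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return (point, point_eff * math.exp(-Z_90_ONE_SIDED * se))


# ---------------------------------------------------------------------------
# optional full empirical-Bayes (gamma-mixture) EBGM backend
# ---------------------------------------------------------------------------

def _nb_logpmf(a: np.ndarray, alpha: float, beta: float, e: np.ndarray) -> np.ndarray:
    # marginal of Poisson(lambda*E) with lambda ~ Gamma(alpha, rate beta)
    p = np.clip(beta / (beta + e), 1e-12, 1.0 - 1e-12)
    return (
        special.gammaln(a + alpha)
        - special.gammaln(alpha)
        - special.gammaln(a + 1)
        + alpha * np.log(p)
        + a * np.log1p(-p)
    )


def _mixture_negloglik(params: np.ndarray, a: np.ndarray, e: np.ndarray) -> float:
    la1, lb1, la2, lb2, logit_w = params
    w = 1.0 / (1.0 + math.exp(-logit_w))
    lp1 = _nb_logpmf(a, math.exp(la1), math.exp(lb1), e) + math.log(w)
    lp2 = _nb_logpmf(a, math.exp(la2), math.exp(lb2), e) + math.log1p(-w)
    return -float(np.logaddexp(lp1, lp2).sum())


def mgps_ebgm(tables: Sequence[ContingencyTable]) -> list[tuple[float, float]]:
    """Gamma-mixture empirical-Bayes EBGM/EB05 (DuMouchel-style MGPS).

    The two-component gamma prior on the relative reporting ratio is fit
    by maximum marginal likelihood across all supplied tables; the
    posterior for each table is a two-component gamma mixture from which
    EBGM = 2^E[log2 lambda] and EB05 = posterior 5th percentile.
    """
    if not tables:
        return []
    a = np.array([t.a for t in tables], dtype=float)
    e = np.array([(t.a + t.b) * (t.a + t.c) / t.N for t in tables], dtype=float)
    e = np.maximum(e, 1e-12)
    x0 = np.array([math.log(0.2), math.log(0.1), math.log(2.0), math.log(4.0), 0.0])
    res = optimize.minimize(
        _mixture_negloglik, x0, args=(a, e), method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-6, "fatol": 1e-8},
    )
    la1, lb1, la2, lb2, logit_w = res.x
    al1, be1, al2, be2 = map(math.exp, (la1, lb1, la2, lb2))
    w = 1.0 / (1.0 + math.exp(-logit_w))

    out: list[tuple[float, float]] = []
    for ai, ei in zip(a, e):
        lq1 = _nb_logpmf(np.array([ai]), al1, be1, np.array([ei]))[0] + math.log(w)
        lq2 = _nb_logpmf(np.array([ai]), al2, be2, np.array([ei]))[0] + math.log1p(-w)
        norm = np.logaddexp(lq1, lq2)
        q1 = math.exp(lq1 - norm)
        post = (
            (q1, al1 + ai, be1 + ei),
            (1.0 - q1, al2 + ai, be2 + ei),
        )
        elog = sum(wk * (special.digamma(ak) - math.log(bk)) for wk, ak, bk in post)
        ebgm_val = math.exp(elog)

        def cdf(x: float) -> float:
            return sum(wk * stats.gamma.cdf(x, ak, scale=1.0 / bk) for wk, ak, bk in post)

        lo, hi = 1e-8, 1.0
        while cdf(hi) < 0.05:
            hi *= 2.0
        eb05_val = optimize.brentq(lambda x: cdf(x) - 0.05, lo, hi)
        out.append((ebgm_val, eb05_val))
    return out


# ---------------------------------------------------------------------------
# table construction and evaluation
# ---------------------------------------------------------------------------

def target_report_ids(drug_mentions: Iterable[DrugMention], target_drug: str) -> set[str]:
    """Primaryids of reports where ``target_drug`` is the primary suspect (role PS)."""
    target = target_drug.lower()
    return {
        m.primaryid for m in drug_mentions
        if m.role == "PS" and m.standard_name == target
    }


def report_term_pairs(
    reports: Sequence[CaseReport],
    reaction_mentions: Iterable[ReactionMention],
    level: str = "PT",
    hierarchy: MeddraHierarchy | None = None,
) -> set[tuple[str, str]]:
    """Distinct (primaryid, term) pairs — the counting unit of every table.

    At SOC level each PT is first mapped through the hierarchy and a SOC
    is counted at most once per report; unmapped PTs fall into the
    UNMAPPED pseudo-SOC so pair totals are conserved.
    """
    pids = {r.primaryid for r in reports}
    if level == "PT":
        return {(m.primaryid, m.pt) for m in reaction_mentions if m.primaryid in pids}
    if level == "SOC":
        if hierarchy is None:
            raise ValueError("SOC-level counting requires a hierarchy")
        return {
            (m.primaryid, soc_of(m.pt, hierarchy))
            for m in reaction_mentions
            if m.primaryid in pids
        }
    raise ValueError(f"unknown level {level!r}")


def build_tables(
    reports: Sequence[CaseReport],
    drug_mentions: Sequence[DrugMention],
    reaction_mentions: Sequence[ReactionMention],
    target_drug: str,
    level: str = "PT",
    hierarchy: MeddraHierarchy | None = None,
) -> dict[str, ContingencyTable]:
    """One 2x2 table per term for ``target_drug`` primary-suspect reports.

    Counting unit is the distinct (report, term) pair; a = pairs on
    PS-target reports mentioning the term, b = other pairs on those
    reports, c/d the analogues on all remaining reports, N = all pairs.
    """
    pairs = report_term_pairs(reports, reaction_mentions, level=level, hierarchy=hierarchy)
    target_pids = target_report_ids(drug_mentions, target_drug)
    if not target_pids:
        logger.warning("target drug %r absent from corpus", target_drug)
        return {}

    n_total = len(pairs)
    a_counts: dict[str, int] = {}
    term_totals: dict[str, int] = {}
    target_pairs = 0
    for pid, term in pairs:
        term_totals[term] = term_totals.get(term, 0) + 1
        if pid in target_pids:
            a_counts[term] = a_counts.get(term, 0) + 1
            target_pairs += 1

    tables: dict[str, ContingencyTable] = {}
    for term, a in a_counts.items():
        c = term_totals[term] - a
        b = target_pairs - a
        d = n_total - target_pairs - c
        tables[term] = ContingencyTable(a=a, b=b, c=c, d=d)
    return tables


def _sort_key(result: SignalResult) -> tuple[int, float, str]:
    # descending ROR, degenerate (NaN) values last, term as final tiebreak
    if math.isnan(result.ror):
        return (1, 0.0, result.term)
    return (0, -result.ror, result.term)


def evaluate_signals(
    tables: Mapping[str, ContingencyTable],
    config: SignalConfig | None = None,
    drug: str = "",
    level: str = "PT",
    hierarchy: MeddraHierarchy | None = None,
    stratum: str = "",
) -> list[SignalResult]:
    """Score every term with all four statistics and threshold flags.

    Terms with a < min_a are excluded before any statistic is computed;
    output is sorted by descending ROR (degenerates last).
    """
    config = config or SignalConfig()
    th = config.thresholds
    kept = {term: t for term, t in tables.items() if t.a >= th.min_a}

    if config.ebgm_backend == "mgps":
        ordered_terms = sorted(kept)
        mgps = dict(zip(ordered_terms, mgps_ebgm([kept[t] for t in ordered_terms])))
    else:
        mgps = {}

    results: list[SignalResult] = []
    for term, t in kept.items():
        ror_pt, ror_lo, ror_hi = ror(t, config.zero_cell)
        prr_pt, chi2 = prr(t, config.zero_cell, yates=config.yates)
        ic_pt, ic025 = bcpnn_ic(t)
        if config.ebgm_backend == "mgps":
            ebgm_pt, eb05 = mgps[term]
        else:
            ebgm_pt, eb05 = ebgm(t, config.zero_cell)
        soc = ""
        if level == "PT" and hierarchy is not None:
            soc = soc_of(term, hierarchy)
        elif level == "SOC":
            soc = term
        results.append(SignalResult(
            drug=drug,
            term=term,
            level=level,
            a=t.a, b=t.b, c=t.c, d=t.d,
            ror=ror_pt, ror_lo=ror_lo, ror_hi=ror_hi,
            prr=prr_pt, chi2=chi2,
            ic=ic_pt, ic025=ic025,
            ebgm=ebgm_pt, eb05=eb05,
            flag_ror=bool(ror_lo > th.ror_ci_lower) if not math.isnan(ror_lo) else False,
            flag_prr=bool(prr_pt >= th.prr_min and chi2 >= th.chi2_min)
            if not (math.isnan(prr_pt) or math.isnan(chi2)) else False,
            flag_bcpnn=bool(ic025 > th.ic025_min) if not math.isnan(ic025) else False,
            flag_ebgm=bool(eb05 > th.eb05_min) if not math.isnan(eb05) else False,
            soc=soc,
            stratum=stratum,
        ))
    results.sort(key=_sort_key)
    return results


SIGNAL_TABLE_COLUMNS = [
    "drug", "level", "term", "soc", "a", "b", "c", "d",
    "ror", "ror_lo", "ror_hi", "prr", "chi2", "ic", "ic025", "ebgm", "eb05",
    "flag_ror", "flag_prr", "flag_bcpnn", "flag_ebgm", "n_positive", "stratum",
]


def results_to_rows(results: Iterable[SignalResult]) -> list[dict]:
    """Flatten results into dict rows matching :data:`SIGNAL_TABLE_COLUMNS`."""
    rows = []
    for r in results:
        row = {col: getattr(r, col) for col in SIGNAL_TABLE_COLUMNS if col != "n_positive"}
        row["n_positive"] = r.n_positive
        rows.append({col: row[col] for col in SIGNAL_TABLE_COLUMNS})
    return rows
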