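"""Survey-weighted cause distributions and EAVA-vs-PCVA comparison statistics.

Implements the study-style analytic toolkit:

* cause-specific mortality fractions (CSMF) under survey cluster
  weights, with Wilson confidence intervals on the Kish effective
  sample size;
* the uncorrected two-sample (Pearson) chi-square test of proportions,
  with an exact mid-p variant of the p-value available by flag;
* Cohen's kappa for 2x2 agreement with the large-sample CI and the
  conventional grading (>0.80 excellent, >0.60 good, >0.40 moderate,
  >0.20 fair, else poor / less than chance);
* per-cause 2x2 agreement tables between two cause-set assignments;
* dense rank-order comparison of two cause distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .records import VARecord
from .rules import UNSPECIFIED

__all__ = [
    "CauseDistribution", "TestResult", "AgreementResult",
    "weighted_csmf", "two_prop_chi2", "cohen_kappa", "agreement_table",
    "rank_comparison", "kappa_grade",
]


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str  # "asymptotic" or "mid-p exact"
    label: str = ""

    def __post_init__(self) -> None:
        assert self.statistic >= 0 and 0 <= self.p_value <= 1


@dataclass
class AgreementResult:
    a: float  # both positive
    b: float  # method 1 only
    c: float  # method 2 only
    d: float  # both negative
    kappa: float
    ci_low: float
    ci_high: float
    grade: str
    weighted: bool = False


@dataclass
class CauseDistribution:
    """Per-cause unweighted counts and weighted proportions (%) with CIs."""

    age_group: str
    table: pd.DataFrame  # index cause; columns n, percent, ci_low, ci_high
    n_total: int

    def percent(self, cause: str) -> float:
        return float(self.table.loc[cause, "percent"])

    def count(self, cause: str) -> int:
        return int(self.table.loc[cause, "n"])


def _wilson(p: float, n_eff: float, z: float = 1.959963984540054) -> tuple[float, float]:
    if n_eff <= 0:
        return 0.0, 100.0
    denom = 1 + z * z / n_eff
    centre = p + z * z / (2 * n_eff)
    half = z * math.sqrt(p * (1 - p) / n_eff + z * z / (4 * n_eff * n_eff))
    lo = max(0.0, (centre - half) / denom)
    hi = min(1.0, (centre + half) / denom)
    return 100 * lo, 100 * hi


def weighted_csmf(records: Iterable[VARecord],
                  assignments: Mapping[str, object] | Iterable,
                  cause_of: Callable[[object], str] | None = None,
                  causes: list[str] | None = None,
                  age_group: str | None = None) -> CauseDistribution:
    """Survey-weighted cause-specific mortality fractions.

    *assignments* maps death_id to an assignment object (or is an
    iterable of objects with a ``death_id``); *cause_of* extracts the
    cause label from one assignment (default: its ``reporting_cause``
    or the object itself if it is a string).  Proportions are
    weighted — proportion(X) = sum of weights with cause X / total
    weight — while counts stay unweighted.  The 95% CI is a Wilson
    interval on the Kish effective sample size n_eff = (Σw)²/Σw².
    """
    records = list(records)
    if not isinstance(assignments, Mapping):
        assignments = {a.death_id: a for a in assignments}
    if cause_of is None:
        cause_of = lambda a: a if isinstance(a, str) else a.reporting_cause

    weights, labels = [], []
    for r in records:
        if r.death_id not in assignments:
            raise KeyError(f"no cause assignment for death {r.death_id!r}")
        weights.append(r.survey_weight)
        labels.append(cause_of(assignments[r.death_id]))
    w = np.asarray(weights, dtype=float)
    lab = pd.Series(labels)

    cause_list = causes if causes is not None else sorted(lab.unique())
    for c in lab.unique():
        if c not in cause_list:
            cause_list = list(cause_list) + [c]
    total_w = w.sum()
    n_eff = total_w ** 2 / np.sum(w ** 2) if len(w) else 0.0

    rows = []
    for cause in cause_list:
        mask = (lab == cause).to_numpy()
        p = w[mask].sum() / total_w if total_w > 0 else 0.0
        lo, hi = _wilson(p, n_eff)
        rows.append({"cause": cause, "n": int(mask.sum()), "percent": 100 * p,
                     "ci_low": lo, "ci_high": hi})
    table = pd.DataFrame(rows).set_index("cause")
    if len(table) and total_w > 0:
        assert abs(table["percent"].sum() - 100.0) < 1e-6
    group = age_group or (records[0].age_group if records else "")
    return CauseDistribution(group, table, len(records))


def two_prop_chi2(x1: int, n1: int, x2: int, n2: int,
                  mid_p: bool = False, label: str = "") -> TestResult:
    """Two-sample test of proportions x1/n1 vs x2/n2.

    The statistic is the uncorrected Pearson chi-square
    ``(p1-p2)^2 / [pbar(1-pbar)(1/n1+1/n2)]`` with pooled pbar; the
    default p-value is asymptotic (chi-square, 1 df).  With
    ``mid_p=True`` the p-value is the exact two-sided mid-p — the
    hypergeometric tail probability counting half the probability of
    the observed table — and the statistic is unchanged.
    """
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2 and n1 > 0 and n2 > 0):
        raise ValueError("need 0 <= xi <= ni and ni > 0")
    pbar = (x1 + x2) / (n1 + n2)
    if pbar in (0.0, 1.0):
        return TestResult(0.0, 1.0, "asymptotic", label)
    p1, p2 = x1 / n1, x2 / n2
    stat = (p1 - p2) ** 2 / (pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    if mid_p:
        p_val = _midp_two_sided(x1, n1, x2, n2)
        return TestResult(stat, p_val, "mid-p exact", label)
    return TestResult(stat, float(sps.chi2.sf(stat, df=1)), "asymptotic", label)


def _midp_two_sided(x1: int, n1: int, x2: int, n2: int) -> float:
    """Exact conditional two-sided mid-p: sum the probabilities of all
    tables (fixed margins) no more probable than the observed one, but
    count the observed table itself at half weight."""
    k = x1 + x2
    rv = sps.hypergeom(n1 + n2, n1, k)
    support = np.arange(max(0, k - n2), min(k, n1) + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(x1)
    eps = 1e-12
    p = probs[probs <= p_obs * (1 + eps)].sum() - 0.5 * p_obs
    return float(min(1.0, max(0.0, p)))


def kappa_grade(kappa: float) -> str:
    if kappa > 0.80:
        return "excellent"
    if kappa > 0.60:
        return "good"
    if kappa > 0.40:
        return "moderate"
    if kappa > 0.20:
        return "fair"
    return "poor"


def cohen_kappa(a: float, b: float, c: float, d: float,
                weighted: bool = False) -> AgreementResult:
    """Cohen's kappa from a 2x2 agreement table.

    po = (a+d)/N, pe = [(a+b)(a+c) + (c+d)(b+d)] / N², kappa =
    (po-pe)/(1-pe).  The 95% CI uses the large-sample standard error
    sqrt(po(1-po)) / ((1-pe) sqrt(N)).  Degenerate margins (pe = 1)
    yield kappa 1 for perfect agreement, else an error.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cells must be non-negative")
    n = a + b + c + d
    if n <= 0:
        raise ValueError("empty table")
    po = (a + d) / n
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / n ** 2
    if pe >= 1.0:
        if po == 1.0:
            return AgreementResult(a, b, c, d, 1.0, 1.0, 1.0, "excellent", weighted)
        raise ValueError("degenerate margins (pe = 1) with imperfect agreement")
    kappa = (po - pe) / (1 - pe)
    se = math.sqrt(po * (1 - po) / n) / (1 - pe)
    z = 1.959963984540054
    lo, hi = max(-1.0, kappa - z * se), min(1.0, kappa + z * se)
    return AgreementResult(a, b, c, d, kappa, lo, hi, kappa_grade(kappa), weighted)


def agreement_table(sets1: Mapping[str, frozenset | set],
                    sets2: Mapping[str, frozenset | set],
                    cause: str,
                    weights: Mapping[str, float] | None = None
                    ) -> tuple[float, float, float, float]:
    """2x2 cells for one cause between two per-death cause-set
    assignments: a = both contain it, b = method-1 only, c = method-2
    only, d = neither.  Optional per-death weights give weighted cells."""
    if set(sets1) != set(sets2):
        raise ValueError("assignment universes differ")
    a = b = c = d = 0.0
    for death_id in sets1:
        w = 1.0 if weights is None else float(weights[death_id])
        in1 = cause in sets1[death_id]
        in2 = cause in sets2[death_id]
        if in1 and in2:
            a += w
        elif in1:
            b += w
        elif in2:
            c += w
        else:
            d += w
    return a, b, c, d


def rank_comparison(dist1: CauseDistribution, dist2: CauseDistribution,
                    exclude: tuple[str, ...] = (UNSPECIFIED,)) -> pd.DataFrame:
    """Dense ranks of the shared causes by descending proportion, with
    per-cause rank difference.  Unspecified deaths are left aside; ties
    keep cause-list order and are flagged."""
    causes = [c for c in dist1.table.index if c in dist2.table.index
              and c not in exclude]

    def ranks(dist: CauseDistribution) -> tuple[dict[str, int], set[str]]:
        pct = {c: dist.percent(c) for c in causes}
        distinct = sorted({v for v in pct.values()}, reverse=True)
        level = {v: i + 1 for i, v in enumerate(distinct)}
        tied = {c for c in causes
                if sum(1 for o in causes if pct[o] == pct[c]) > 1}
        return {c: level[pct[c]] for c in causes}, tied

    r1, t1 = ranks(dist1)
    r2, t2 = ranks(dist2)
    return pd.DataFrame({
        "percent_1": [dist1.percent(c) for c in causes],
        "percent_2": [dist2.percent(c) for c in causes],
        "rank_1": [r1[c] for c in causes],
        "rank_2": [r2[c] for c in causes],
        "rank_diff": [r1[c] - r2[c] for c in causes],
        "tied": [c in t1 or c in t2 for c in causes],
    }, index=pd.Index(causes, name="cause"))
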