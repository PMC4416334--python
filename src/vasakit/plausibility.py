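"""Internal-validity (plausibility) analyses.

Two checks probe whether the expert-algorithm diagnoses behave like
real disease rather than artifacts of the rules:

* **Maternal infection vs early-onset neonatal infection** — severe
  neonatal infections (meningitis, pneumonia, sepsis) with illness
  onset before day 2 of life should be associated with infection of the
  mother before or during delivery; late-onset infections should not.
  Each cause group gets a 2x2 (early vs late onset x maternal infection
  yes/no) and a two-proportion chi-square, plus the contrast of
  early-onset severe infection against all other deaths.

* **Regional meningitis ecology** — the VA-diagnosed child
  meningitis-specific proportional mortality per region is set against
  each region's share of the national surveillance-notified meningitis
  cases and deaths.  Agreement in geographic profile supports the VA
  diagnosis.  A Spearman rank correlation summarises the profile match
  (an artifact-level addition — the underlying comparison is
  qualitative), with small-denominator regions flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats as sps

from .classify import EARLY, LATE, NOT_APPLICABLE, CauseAssignment, early_onset
from .records import SurveillanceTable, VARecord
from .stats import TestResult, two_prop_chi2

SEVERE_INFECTION_CAUSES = ("meningitis", "pneumonia", "sepsis")


@dataclass
class OnsetAssociation:
    """One cause group's early/late stratification with its test."""

    group: str
    n_group: int
    early_n: int
    early_maternal: int
    late_n: int
    late_maternal: int
    not_applicable_n: int
    early_maternal_pct: float      # weighted %
    late_maternal_pct: float       # weighted %
    test: TestResult | None
    flagged: str = ""


def _weighted_pct(num_w: float, den_w: float) -> float:
    return 100.0 * num_w / den_w if den_w > 0 else float("nan")


def onset_association(records: Iterable[VARecord],
                      assignments: Mapping[str, CauseAssignment] | Iterable,
                      maternal_flags: Mapping[str, bool],
                      groups: Mapping[str, tuple[str, ...]] | None = None,
                      ) -> list[OnsetAssociation]:
    """Build the early/late-onset x maternal-infection 2x2 per cause
    group and test it with the two-proportion chi-square.

    *groups* maps a label to the primary causes it covers; the default
    is each severe infection separately plus all three combined.  The
    severe-early-vs-all-other-deaths contrast is always appended.
    An empty stratum flags the result instead of failing.
    """
    records = list(records)
    if not isinstance(assignments, Mapping):
        assignments = {a.death_id: a for a in assignments}
    if groups is None:
        groups = {c: (c,) for c in SEVERE_INFECTION_CAUSES}
        groups["severe_infection"] = SEVERE_INFECTION_CAUSES

    onset = {r.death_id: early_onset(r) for r in records}
    weight = {r.death_id: r.survey_weight for r in records}
    primary = {r.death_id: assignments[r.death_id].primary for r in records}

    def stratify(ids: list[str]) -> tuple[dict, dict]:
        strata = {EARLY: [], LATE: [], NOT_APPLICABLE: []}
        for i in ids:
            strata[onset[i]].append(i)
        return strata, {
            k: sum(weight[i] for i in v if maternal_flags.get(i, False))
            for k, v in strata.items()}

    results: list[OnsetAssociation] = []
    for label, causes in groups.items():
        ids = [i for i in primary if primary[i] in causes]
        strata, _ = stratify(ids)
        results.append(_assoc_row(label, len(ids), strata, maternal_flags, weight))

    # early-onset severe infection vs all other deaths
    severe_ids = [i for i in primary if primary[i] in SEVERE_INFECTION_CAUSES]
    early_ids = [i for i in severe_ids if onset[i] == EARLY]
    other_ids = [i for i in primary if i not in set(early_ids)]
    strata = {EARLY: early_ids, LATE: other_ids, NOT_APPLICABLE: []}
    row = _assoc_row("severe_early_vs_all_other", len(primary), strata,
                     maternal_flags, weight)
    results.append(row)
    return results


def _assoc_row(label: str, n_group: int, strata: dict,
               maternal_flags: Mapping[str, bool],
               weight: Mapping[str, float]) -> OnsetAssociation:
    e_ids, l_ids, na_ids = strata[EARLY], strata[LATE], strata[NOT_APPLICABLE]
    e_m = sum(1 for i in e_ids if maternal_flags.get(i, False))
    l_m = sum(1 for i in l_ids if maternal_flags.get(i, False))
    e_w = sum(weight[i] for i in e_ids)
    l_w = sum(weight[i] for i in l_ids)
    e_mw = sum(weight[i] for i in e_ids if maternal_flags.get(i, False))
    l_mw = sum(weight[i] for i in l_ids if maternal_flags.get(i, False))
    flagged = ""
    test = None
    if e_ids and l_ids:
        test = two_prop_chi2(e_m, len(e_ids), l_m, len(l_ids), label=label)
    else:
        flagged = "empty stratum"
    return OnsetAssociation(
        group=label, n_group=n_group,
        early_n=len(e_ids), early_maternal=e_m,
        late_n=len(l_ids), late_maternal=l_m,
        not_applicable_n=len(na_ids),
        early_maternal_pct=_weighted_pct(e_mw, e_w),
        late_maternal_pct=_weighted_pct(l_mw, l_w),
        test=test, flagged=flagged)


def onset_association_frame(results: list[OnsetAssociation]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "group": r.group, "n": r.n_group,
            "early_n": r.early_n, "early_maternal": r.early_maternal,
            "late_n": r.late_n, "late_maternal": r.late_maternal,
            "not_applicable_n": r.not_applicable_n,
            "early_maternal_pct": r.early_maternal_pct,
            "late_maternal_pct": r.late_maternal_pct,
            "chi2": r.test.statistic if r.test else np.nan,
            "p": r.test.p_value if r.test else np.nan,
            "flag": r.flagged})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------


@dataclass
class RegionalComparison:
    """Per-region meningitis proportional mortality vs surveillance shares."""

    table: pd.DataFrame
    spearman_cases_eava: float
    spearman_pvalue: float

    SMALL_DENOMINATOR = 20


def regional_meningitis(records: Iterable[VARecord],
                        eava_assignments: Mapping[str, CauseAssignment] | Iterable,
                        surveillance: SurveillanceTable,
                        pcva_causes: Mapping[str, str] | None = None,
                        meningitis_cause: str = "meningitis") -> RegionalComparison:
    """Compare VA meningitis geography with surveillance geography.

    Per region: meningitis-specific proportional mortality = weighted
    share of that region's VA child deaths attributed to meningitis
    (EAVA primary and, if supplied, PCVA underlying); surveillance
    share = the region's percent of national cases (and deaths where
    reported).  Regions with VA deaths but no surveillance row are
    flagged; VA denominators under 20 deaths are flagged as unstable.
    """
    records = list(records)
    if not isinstance(eava_assignments, Mapping):
        eava_assignments = {a.death_id: a for a in eava_assignments}

    cases = surveillance.regional_totals("cases_notified")
    deaths = (surveillance.regional_totals("deaths")
              if "deaths" in surveillance.frame.columns else None)
    cases_pct = 100 * cases / cases.sum()
    deaths_pct = 100 * deaths / deaths.sum() if deaths is not None and deaths.sum() > 0 else None

    rows = []
    for region, grp in pd.DataFrame({
            "region": [r.region for r in records],
            "death_id": [r.death_id for r in records],
            "weight": [r.survey_weight for r in records]}).groupby("region"):
        w_all = grp["weight"].sum()
        w_men = sum(w for i, w in zip(grp["death_id"], grp["weight"])
                    if eava_assignments[i].primary == meningitis_cause)
        row = {
            "region": region,
            "child_deaths": len(grp),
            "eava_meningitis": sum(1 for i in grp["death_id"]
                                   if eava_assignments[i].primary == meningitis_cause),
            "eava_proportional_mortality": 100 * w_men / w_all if w_all else np.nan,
            "surveillance_cases_pct": float(cases_pct.get(region, np.nan)),
            "surveillance_deaths_pct": (float(deaths_pct.get(region, np.nan))
                                        if deaths_pct is not None else np.nan),
            "flag": "",
        }
        if pcva_causes is not None:
            n_p = sum(1 for i in grp["death_id"]
                      if pcva_causes.get(i) == meningitis_cause)
            w_p = sum(w for i, w in zip(grp["death_id"], grp["weight"])
                      if pcva_causes.get(i) == meningitis_cause)
            row["pcva_meningitis"] = n_p
            row["pcva_proportional_mortality"] = 100 * w_p / w_all if w_all else np.nan
        flags = []
        if region not in cases.index:
            flags.append("no surveillance data")
        if len(grp) < RegionalComparison.SMALL_DENOMINATOR:
            flags.append("small denominator")
        row["flag"] = "; ".join(flags)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("region").sort_index()

    matched = table.dropna(subset=["surveillance_cases_pct"])
    if len(matched) >= 3 and matched["eava_proportional_mortality"].nunique() > 1:
        rho, p = sps.spearmanr(matched["surveillance_cases_pct"],
                               matched["eava_proportional_mortality"])
    else:
        rho, p = np.nan, np.nan
    return RegionalComparison(table, float(rho), float(p))


def plot_regional_comparison(comp: RegionalComparison, path: str) -> None:
    """Paired bar chart of surveillance shares and VA proportional
    mortality per region (figure export; CSV backing table is
    ``comp.table``)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = comp.table
    x = np.arange(len(t))
    series = [("surveillance_cases_pct", "Surveillance cases (% of national)"),
              ("surveillance_deaths_pct", "Surveillance deaths (% of national)"),
              ("eava_proportional_mortality", "EAVA meningitis proportional mortality (%)")]
    if "pcva_proportional_mortality" in t.columns:
        series.append(("pcva_proportional_mortality",
                       "PCVA meningitis proportional mortality (%)"))
    width = 0.8 / len(series)
    fig, ax = plt.subplots(figsize=(10, 4.5))
    for k, (col, label) in enumerate(series):
        ax.bar(x + k * width, t[col].fillna(0), width, label=label)
    ax.set_xticks(x + 0.4 - width / 2)
    ax.set_xticklabels(t.index, rotation=30, ha="right")
    ax.set_ylabel("percent")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
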