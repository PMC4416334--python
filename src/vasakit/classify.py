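"""Hierarchical expert-algorithm cause assignment.

The classifier evaluates every cause rule for a record, then walks the
age group's hierarchy (a total order): the top-ranked firing cause is
the *primary* cause, every other firing cause flagged co-morbid-capable
is a *co-morbid* cause, and a record satisfying no rule is
*unspecified*.  A possible-tier rule can only fire when its probable
counterpart does not, so the possible tiers claim deaths from the
unspecified group without ever double-counting a cause.

The *reporting* cause merges a possible-tier primary into its probable
counterpart, which is how final cause-of-death distributions are
tabulated.  The *combined algorithmic cause* set (primary plus
co-morbid, possible merged) feeds the agreement analysis against the
physician's combined certificate causes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .records import NEONATE, VARecord
from .rules import UNSPECIFIED, CauseRule, Hierarchy, RuleSet


class AgeGroupMismatch(ValueError):
    pass


@dataclass
class CauseAssignment:
    """EAVA output for one death."""

    death_id: str
    eligible: list[str]              # all firing causes, hierarchy order
    primary: str                     # top-ranked eligible cause or unspecified
    comorbid: list[str]              # lower-ranked eligible, comorbid-capable
    reporting_cause: str             # primary with possible merged into probable
    ruleset_id: str = ""

    @property
    def combined(self) -> frozenset[str]:
        """Combined 'algorithmic cause' set: primary plus co-morbid causes."""
        if self.primary == UNSPECIFIED:
            return frozenset({UNSPECIFIED})
        return frozenset({self.primary, *self.comorbid})

    def combined_reporting(self, ruleset: RuleSet) -> frozenset[str]:
        """Combined set with possible tiers merged into their probable causes."""
        return frozenset(_merge_possible(c, ruleset) for c in self.combined)


def _merge_possible(cause: str, ruleset: RuleSet) -> str:
    rule = ruleset.rules.get(cause)
    if rule is not None and rule.tier == "possible":
        return rule.counterpart  # type: ignore[return-value]
    return cause


def evaluate_rule(rule: CauseRule, record: VARecord) -> bool:
    """Evaluate one cause rule on one record (pure; missing signs fail)."""
    if rule.age_group != record.age_group:
        raise AgeGroupMismatch(
            f"rule {rule.cause} is for {rule.age_group}, record "
            f"{record.death_id} is {record.age_group}")
    return rule.expr(record)


def eligible_causes(record: VARecord, ruleset: RuleSet) -> list[str]:
    """Causes whose rules fire, in hierarchy order, with the
    possible-tier suppression (a possible cause is eligible only when
    its probable counterpart is not)."""
    fired = {c for c, rule in ruleset.rules.items() if rule.expr(record)}
    eligible = []
    for cause in ruleset.hierarchy.order:
        if cause not in fired:
            continue
        rule = ruleset.rules[cause]
        if rule.tier == "possible" and rule.counterpart in fired:
            continue
        eligible.append(cause)
    return eligible


def select_primary(eligible: Iterable[str], hierarchy: Hierarchy) -> str:
    """Minimum-rank cause of a (possibly empty) eligible set."""
    best = None
    for cause in eligible:
        if best is None or hierarchy.rank(cause) < hierarchy.rank(best):
            best = cause
    return best if best is not None else UNSPECIFIED


def classify(record: VARecord, ruleset: RuleSet) -> CauseAssignment:
    """Assign primary and co-morbid causes to one death.

    Deterministic: a pure function of the record and rule set.
    """
    if ruleset.age_group != record.age_group:
        raise AgeGroupMismatch(
            f"rule set covers {ruleset.age_group}, record {record.death_id} "
            f"is {record.age_group}")
    eligible = eligible_causes(record, ruleset)
    primary = select_primary(eligible, ruleset.hierarchy)
    comorbid = [c for c in eligible
                if c != primary and ruleset.hierarchy.comorbid_ok.get(c, True)]
    return CauseAssignment(
        death_id=record.death_id,
        eligible=eligible,
        primary=primary,
        comorbid=comorbid,
        reporting_cause=_merge_possible(primary, ruleset),
        ruleset_id=ruleset.ruleset_id,
    )


def classify_cohort(records: Iterable[VARecord], ruleset: RuleSet) -> list[CauseAssignment]:
    return [classify(r, ruleset) for r in records]


def maternal_infection(record: VARecord, rule: CauseRule) -> bool:
    """Apply the maternal infection-before-or-during-delivery algorithm.

    Only meaningful for neonatal deaths; all-missing maternal sections
    yield False (missingness never creates a diagnosis).
    """
    if record.age_group != NEONATE:
        raise AgeGroupMismatch(
            f"maternal infection algorithm applies to neonates; record "
            f"{record.death_id} is {record.age_group}")
    return rule.expr(record)


EARLY, LATE, NOT_APPLICABLE = "early", "late", "not_applicable"


def early_onset(record: VARecord, cutoff_day: int = 2) -> str:
    """Early- vs late-onset illness for a neonate.

    Early means illness onset before day *cutoff_day* of life (default:
    onset < 2 days); a missing onset day is ``not_applicable``.
    """
    if record.age_group != NEONATE:
        raise AgeGroupMismatch(
            f"onset classification applies to neonates; record "
            f"{record.death_id} is {record.age_group}")
    day = record.illness_onset_day
    if day is None:
        return NOT_APPLICABLE
    return EARLY if day < cutoff_day else LATE
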