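"""Declarative expert-algorithm (EAVA) cause-of-death rules.

A rule set is a YAML (or JSON-equivalent) document holding, per age
group: the sign vocabulary, the cause hierarchy (a total order; rank 1
at the top), one boolean rule per cause built from sign predicates, an
optional maternal-condition rule, and optional per-cause minimal
diagnostic criteria used to audit physician certificates.

Predicates are conservative about missing data: a predicate on a sign
whose answer is missing is *false*, so missingness can never create a
diagnosis.  This mirrors the specificity-first design of expert
algorithms.

Expression grammar (YAML)::

    expr:
      all: [ <expr>, ... ]      # conjunction
      any: [ <expr>, ... ]      # disjunction
      not: <expr>               # negation
      # leaves:
      {sign: fever, min_duration: 2}          # child sign, >= 2 days
      {sign: fever_during_labor, scope: maternal}
      {pregnancy_months_lt: 8}
      {onset_day_lt: 2}                       # illness onset day of life
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Mapping

import yaml

from .records import VARecord

UNSPECIFIED = "unspecified"

_LEAF_KEYS = {"sign", "presence", "min_duration", "max_duration", "scope",
              "onset_order_le", "pregnancy_months_lt", "pregnancy_months_ge",
              "onset_day_lt", "onset_day_ge"}


class RuleConfigError(ValueError):
    """Raised at load time for malformed rule configuration."""


@dataclass(frozen=True)
class Predicate:
    """One leaf test against a record."""

    sign: str | None = None
    presence: str = "yes"
    min_duration: float | None = None
    max_duration: float | None = None
    scope: str = "child"  # child | maternal
    onset_order_le: int | None = None
    pregnancy_months_lt: float | None = None
    pregnancy_months_ge: float | None = None
    onset_day_lt: int | None = None
    onset_day_ge: int | None = None

    def __call__(self, record: VARecord) -> bool:
        if self.pregnancy_months_lt is not None or self.pregnancy_months_ge is not None:
            months = record.pregnancy_duration
            if months is None:
                return False
            if self.pregnancy_months_lt is not None and not months < self.pregnancy_months_lt:
                return False
            if self.pregnancy_months_ge is not None and not months >= self.pregnancy_months_ge:
                return False
            return True
        if self.onset_day_lt is not None or self.onset_day_ge is not None:
            day = record.illness_onset_day
            if day is None:
                return False
            if self.onset_day_lt is not None and not day < self.onset_day_lt:
                return False
            if self.onset_day_ge is not None and not day >= self.onset_day_ge:
                return False
            return True
        assert self.sign is not None
        sd = (record.maternal_sign(self.sign) if self.scope == "maternal"
              else record.sign(self.sign))
        if sd.present != self.presence:
            return False  # missing answers never satisfy a predicate
        if self.min_duration is not None and (sd.duration is None
                                              or sd.duration < self.min_duration):
            return False
        if self.max_duration is not None and (sd.duration is None
                                              or sd.duration > self.max_duration):
            return False
        if self.onset_order_le is not None and (sd.onset_order is None
                                                or sd.onset_order > self.onset_order_le):
            return False
        return True


Expr = Callable[[VARecord], bool]


def compile_expr(node, vocabulary: set[str], maternal_vocabulary: set[str],
                 path: str = "expr") -> Expr:
    """Compile a YAML expression node to a predicate closure, validating
    every referenced sign key against the vocabulary (configuration
    errors surface at load time, never during evaluation)."""
    if not isinstance(node, Mapping) or not node:
        raise RuleConfigError(f"{path}: expected a non-empty mapping, got {node!r}")
    if "all" in node:
        subs = [compile_expr(s, vocabulary, maternal_vocabulary, f"{path}.all[{i}]")
                for i, s in enumerate(node["all"])]
        if not subs:
            raise RuleConfigError(f"{path}: empty 'all'")
        return lambda r: all(s(r) for s in subs)
    if "any" in node:
        subs = [compile_expr(s, vocabulary, maternal_vocabulary, f"{path}.any[{i}]")
                for i, s in enumerate(node["any"])]
        if not subs:
            raise RuleConfigError(f"{path}: empty 'any'")
        return lambda r: any(s(r) for s in subs)
    if "not" in node:
        sub = compile_expr(node["not"], vocabulary, maternal_vocabulary, f"{path}.not")
        return lambda r: not sub(r)
    extra = set(node) - _LEAF_KEYS
    if extra:
        raise RuleConfigError(f"{path}: unknown keys {sorted(extra)}")
    pred = Predicate(**{k: v for k, v in node.items()})
    if pred.sign is not None:
        vocab = maternal_vocabulary if pred.scope == "maternal" else vocabulary
        if pred.sign not in vocab:
            raise RuleConfigError(f"{path}: sign {pred.sign!r} not in "
                                  f"{pred.scope} vocabulary")
    for thr in (pred.min_duration, pred.max_duration):
        if thr is not None and thr <= 0:
            raise RuleConfigError(f"{path}: nonpositive duration threshold {thr}")
    return pred


@dataclass
class CauseRule:
    """One cause's boolean sign/symptom algorithm."""

    cause: str
    age_group: str
    tier: str  # probable | possible
    expr: Expr
    expr_source: dict = field(default_factory=dict, repr=False)
    counterpart: str | None = None  # probable counterpart of a possible rule

    def __post_init__(self) -> None:
        if self.tier not in ("probable", "possible"):
            raise RuleConfigError(f"rule {self.cause}: bad tier {self.tier!r}")
        if self.tier == "possible" and not self.counterpart:
            raise RuleConfigError(
                f"possible rule {self.cause} must name its probable counterpart")


@dataclass
class Hierarchy:
    """Total order over causes for one age group; rank 1 = top.

    ``comorbid_ok`` flags causes that may be reported as co-morbid when a
    higher-ranked cause takes primary.
    """

    age_group: str
    order: list[str]
    comorbid_ok: dict[str, bool]

    def __post_init__(self) -> None:
        if len(set(self.order)) != len(self.order):
            raise RuleConfigError("hierarchy contains duplicate causes")

    def rank(self, cause: str) -> int:
        return self.order.index(cause) + 1


@dataclass
class RuleSet:
    """A versioned bundle of rules + hierarchy for one age group."""

    ruleset_id: str
    version: str
    age_group: str
    vocabulary: list[str]
    maternal_vocabulary: list[str]
    rules: dict[str, CauseRule]
    hierarchy: Hierarchy
    maternal_rule: CauseRule | None = None
    minimum_criteria: dict[str, Expr] = field(default_factory=dict)

    def rule(self, cause: str) -> CauseRule:
        return self.rules[cause]


def _check_hierarchy(rules: dict[str, CauseRule], hierarchy: Hierarchy) -> None:
    for cause in rules:
        if cause not in hierarchy.order:
            raise RuleConfigError(f"rule cause {cause!r} absent from hierarchy")
    for cause in hierarchy.order:
        if cause not in rules:
            raise RuleConfigError(f"hierarchy cause {cause!r} has no rule")
    for rule in rules.values():
        if rule.tier == "possible":
            if rule.counterpart not in hierarchy.order:
                raise RuleConfigError(
                    f"{rule.cause}: counterpart {rule.counterpart!r} not in hierarchy")
            if hierarchy.rank(rule.cause) <= hierarchy.rank(rule.counterpart):
                raise RuleConfigError(
                    f"possible rule {rule.cause} must rank below its probable "
                    f"counterpart {rule.counterpart}")


def load_ruleset(source: str | Path | Mapping) -> RuleSet:
    """Load and schema-validate a rule set from YAML/JSON file or mapping."""
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        doc = yaml.safe_load(Path(source).read_text())
    for key in ("ruleset_id", "age_group", "vocabulary", "hierarchy", "rules"):
        if key not in doc:
            raise RuleConfigError(f"rule set missing top-level key {key!r}")
    age_group = doc["age_group"]
    vocab = set(doc["vocabulary"])
    m_vocab = set(doc.get("maternal_vocabulary", []))

    order, comorbid_ok = [], {}
    for entry in doc["hierarchy"]:
        if isinstance(entry, str):
            entry = {"cause": entry}
        order.append(entry["cause"])
        comorbid_ok[entry["cause"]] = bool(entry.get("comorbid", True))
    hierarchy = Hierarchy(age_group, order, comorbid_ok)

    rules: dict[str, CauseRule] = {}
    for spec in doc["rules"]:
        cause = spec["cause"]
        if cause in rules:
            raise RuleConfigError(f"duplicate rule for cause {cause!r}")
        expr = compile_expr(spec["expr"], vocab, m_vocab, f"rules[{cause}].expr")
        rules[cause] = CauseRule(
            cause=cause, age_group=age_group,
            tier=spec.get("tier", "probable"), expr=expr,
            expr_source=spec["expr"], counterpart=spec.get("counterpart"))
    _check_hierarchy(rules, hierarchy)

    maternal_rule = None
    if doc.get("maternal_rule"):
        ms = doc["maternal_rule"]
        maternal_rule = CauseRule(
            cause=ms.get("cause", "maternal_infection"), age_group=age_group,
            tier="probable", expr_source=ms["expr"],
            expr=compile_expr(ms["expr"], vocab, m_vocab, "maternal_rule.expr"))

    minimum_criteria = {
        cause: compile_expr(node, vocab, m_vocab, f"minimum_criteria[{cause}]")
        for cause, node in (doc.get("minimum_criteria") or {}).items()}

    return RuleSet(
        ruleset_id=doc["ruleset_id"], version=str(doc.get("version", "0")),
        age_group=age_group, vocabulary=sorted(vocab),
        maternal_vocabulary=sorted(m_vocab), rules=rules, hierarchy=hierarchy,
        maternal_rule=maternal_rule, minimum_criteria=minimum_criteria)


def default_ruleset(age_group: str) -> RuleSet:
    """The packaged default rule set for ``neonate`` or ``child``."""
    name = f"{age_group}_rules.yaml"
    with resources.files("vasakit.data").joinpath(name).open() as fh:
        return load_ruleset(yaml.safe_load(fh))
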