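"""Rule evaluation and hierarchical classification."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vasakit.classify import (AgeGroupMismatch, classify, early_onset,
                              eligible_causes, evaluate_rule,
                              maternal_infection, select_primary)
from vasakit.rules import RuleConfigError, load_ruleset

from .conftest import TOY_DOC, make_record, toy_record
from .oracles import classify_oracle, eval_expr_oracle


class TestRuleEvaluation:
    def test_neonatal_meningitis_needs_lethargy_or_unconsciousness(self, neonate_ruleset):
        rule = neonate_ruleset.rule("meningitis")
        # bulging fontanelle + lethargy satisfies the algorithm
        rec = make_record(signs={"bulging_fontanelle": True, "lethargy": True})
        assert evaluate_rule(rule, rec)
        # the minimal physician floor alone (fontanelle only) does not
        rec2 = make_record(signs={"bulging_fontanelle": True})
        assert not evaluate_rule(rule, rec2)

    def test_all_missing_record_fires_no_rule(self, neonate_ruleset, child_ruleset):
        for ruleset, group in ((neonate_ruleset, "neonate"), (child_ruleset, "child")):
            rec = make_record(age_group=group, age=5 if group == "neonate" else 12)
            assert all(not rule.expr(rec) for rule in ruleset.rules.values())

    def test_missing_is_not_no_under_negation(self, child_ruleset):
        # malaria requires NOT rash: a missing rash answer passes the
        # negation (absence of evidence), a positive rash fails it
        rule = child_ruleset.rule("malaria")
        base = {"fever": True, "chills": True}
        assert evaluate_rule(rule, make_record(age_group="child", age=12, signs=base))
        assert not evaluate_rule(rule, make_record(
            age_group="child", age=12, signs={**base, "rash": True}))

    def test_duration_threshold(self, child_ruleset):
        rule = child_ruleset.rule("pertussis")
        long = make_record(age_group="child", age=12,
                           signs={"cough": (True, 21), "whooping_cough": True})
        short = make_record(age_group="child", age=12,
                            signs={"cough": (True, 5), "whooping_cough": True})
        assert evaluate_rule(rule, long)
        assert not evaluate_rule(rule, short)

    def test_age_group_mismatch_raises(self, neonate_ruleset):
        child = make_record(age_group="child", age=12)
        with pytest.raises(AgeGroupMismatch):
            evaluate_rule(neonate_ruleset.rule("sepsis"), child)

    def test_unknown_sign_is_a_load_time_error(self):
        doc = dict(TOY_DOC, rules=[{"cause": "alpha",
                                    "expr": {"sign": "nonexistent"}}],
                   hierarchy=[{"cause": "alpha"}])
        with pytest.raises(RuleConfigError, match="nonexistent"):
            load_ruleset(doc)

    @settings(max_examples=300, deadline=None)
    @given(st.tuples(*[st.booleans()] * 12))
    def test_matches_truth_table_oracle(self, toy_ruleset, bits):
        rec = toy_record(bits)
        for cause, rule in toy_ruleset.rules.items():
            assert rule.expr(rec) == eval_expr_oracle(rule.expr_source, rec), cause


class TestClassification:
    def test_meningitis_primary_with_comorbid_sepsis(self, neonate_ruleset):
        # a neonate with meningitis would most likely also have sepsis:
        # the hierarchy selects meningitis on top and sepsis co-morbid
        rec = make_record(signs={
            "bulging_fontanelle": True, "lethargy": True,
            "fever": True, "stopped_suckling": True})
        a = classify(rec, neonate_ruleset)
        assert set(a.eligible) == {"meningitis", "sepsis"}
        assert a.primary == "meningitis"
        assert a.comorbid == ["sepsis"]

    def test_empty_eligible_set_is_unspecified(self, neonate_ruleset):
        a = classify(make_record(), neonate_ruleset)
        assert a.primary == "unspecified"
        assert a.comorbid == []
        assert a.combined == frozenset({"unspecified"})

    def test_preterm_alone_is_primary_despite_bottom_rank(self, neonate_ruleset):
        rec = make_record(pregnancy_duration=7.0)
        a = classify(rec, neonate_ruleset)
        assert a.eligible == ["preterm_delivery"]
        assert a.primary == "preterm_delivery"

    def test_preterm_demoted_to_comorbid_when_sepsis_present(self, neonate_ruleset):
        rec = make_record(pregnancy_duration=7.0,
                          signs={"fever": True, "lethargy": True})
        a = classify(rec, neonate_ruleset)
        assert a.primary == "sepsis"
        assert "preterm_delivery" in a.comorbid

    def test_random_eligibility_sets_match_argmin_rank_oracle(self, toy_ruleset, rng):
        causes = toy_ruleset.hierarchy.order
        for _ in range(1000):
            k = int(rng.integers(0, len(causes) + 1))
            eligible = list(rng.choice(causes, size=k, replace=False))
            got = select_primary(eligible, toy_ruleset.hierarchy)
            want = (min(eligible, key=toy_ruleset.hierarchy.rank)
                    if eligible else "unspecified")
            assert got == want

    def test_deterministic_and_order_independent(self, child_ruleset, rng):
        from vasakit.simulate import GeneratorConfig, generate
        records, _, _ = generate(GeneratorConfig(seed=9, n_neonates=0,
                                                 n_children=50))
        first = [classify(r, child_ruleset) for r in records]
        again = [classify(r, child_ruleset) for r in reversed(records)]
        assert {a.death_id: a.primary for a in first} == \
            {a.death_id: a.primary for a in again}

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.booleans()] * 12))
    def test_possible_and_probable_never_coexist(self, toy_ruleset, bits):
        a = classify(toy_record(bits), toy_ruleset)
        assert not {"zeta", "possible_zeta"} <= a.combined

    @settings(max_examples=200, deadline=None)
    @given(st.tuples(*[st.booleans()] * 12), st.sampled_from(list(TOY_DOC["rules"])))
    def test_hierarchy_monotonicity(self, toy_ruleset, bits, extra_rule):
        """Forcing one more cause eligible never demotes the primary."""
        rec = toy_record(bits)
        base = classify(rec, toy_ruleset)
        extra = extra_rule["cause"]
        eligible = set(eligible_causes(rec, toy_ruleset)) | {extra}
        new_primary = select_primary(eligible, toy_ruleset.hierarchy)
        h = toy_ruleset.hierarchy
        if base.primary != "unspecified":
            assert h.rank(new_primary) <= h.rank(base.primary)

    def test_reporting_merge_conserves_counts(self, toy_ruleset):
        """count(probable X) + count(possible X) == count(reporting X)."""
        records = [toy_record(bits, death_id=str(i))
                   for i, bits in enumerate(itertools.product([0, 1], repeat=12))]
        assigns = [classify(r, toy_ruleset) for r in records]
        n_prob = sum(a.primary == "zeta" for a in assigns)
        n_poss = sum(a.primary == "possible_zeta" for a in assigns)
        n_rep = sum(a.reporting_cause == "zeta" for a in assigns)
        assert n_poss > 0  # the possible tier actually claims deaths
        assert n_prob + n_poss == n_rep

    def test_exhaustive_agreement_with_bruteforce_oracle(self, toy_ruleset):
        for bits in itertools.product([0, 1], repeat=12):
            rec = toy_record(bits)
            a = classify(rec, toy_ruleset)
            primary, comorbid = classify_oracle(rec, toy_ruleset)
            assert a.primary == primary, bits
            assert a.comorbid == comorbid, bits


class TestMaternalAndOnset:
    def test_maternal_infection_rule(self, neonate_ruleset):
        rule = neonate_ruleset.maternal_rule
        hit = make_record(maternal={"fever_during_labor": True})
        miss = make_record(maternal={"fever_during_labor": "missing",
                                     "foul_smelling_discharge": "missing"})
        assert maternal_infection(hit, rule)
        assert not maternal_infection(miss, rule)
        with pytest.raises(AgeGroupMismatch):
            maternal_infection(make_record(age_group="child", age=12), rule)

    @pytest.mark.parametrize("day,expected", [
        (0, "early"), (1, "early"), (2, "late"), (20, "late"),
        (None, "not_applicable")])
    def test_early_onset_cutoff(self, day, expected):
        rec = make_record(age=21, illness_onset_day=day)
        assert early_onset(rec) == expected

    def test_early_onset_rejects_children(self):
        with pytest.raises(AgeGroupMismatch):
            early_onset(make_record(age_group="child", age=12))


class TestRulesetValidation:
    def test_possible_must_rank_below_probable(self):
        doc = dict(TOY_DOC)
        doc["hierarchy"] = [{"cause": "possible_zeta"}, {"cause": "zeta"}] + [
            h for h in TOY_DOC["hierarchy"]
            if h["cause"] not in ("zeta", "possible_zeta")]
        with pytest.raises(RuleConfigError, match="below its probable"):
            load_ruleset(doc)

    def test_default_rulesets_well_formed(self, neonate_ruleset, child_ruleset):
        assert neonate_ruleset.hierarchy.order[-1] == "preterm_delivery"
        for rs in (neonate_ruleset, child_ruleset):
            for rule in rs.rules.values():
                if rule.tier == "possible":
                    assert rs.hierarchy.rank(rule.cause) > \
                        rs.hierarchy.rank(rule.counterpart)
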