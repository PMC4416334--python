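import numpy as np
import pytest
from scipy.stats import chi2_contingency, fisher_exact

from vasakit.records import VARecord
from vasakit.stats import (agreement_table, cohen_kappa, kappa_grade,
                           rank_comparison, two_prop_chi2, weighted_csmf)

from .oracles import kappa_oracle, pearson_chi2_oracle


def _cohort(weights, causes):
    records = [VARecord(death_id=f"d{i}", age_group="neonate", age_at_death=1,
                        survey_weight=w) for i, w in enumerate(weights)]
    assignments = {f"d{i}": c for i, c in enumerate(causes)}
    return records, assignments


class TestWeightedCSMF:
    def test_equal_weights_match_count_ratio(self):
        # 26 of 453 deaths from diarrhea -> 5.7%
        causes = ["diarrhea"] * 26 + ["other"] * 427
        records, assignments = _cohort([1.0] * 453, causes)
        dist = weighted_csmf(records, assignments)
        assert dist.count("diarrhea") == 26
        assert round(dist.percent("diarrhea"), 1) == 5.7
        assert dist.percent("diarrhea") == pytest.approx(100 * 26 / 453)

    def test_single_cause_is_100_percent(self):
        records, assignments = _cohort([1.0] * 10, ["sepsis"] * 10)
        dist = weighted_csmf(records, assignments)
        assert dist.percent("sepsis") == pytest.approx(100.0)
        assert dist.table.loc["sepsis", "ci_high"] == pytest.approx(100.0)

    def test_random_weights_match_summation_oracle(self, rng):
        for _ in range(20):
            n = 50
            w = rng.uniform(0.1, 5.0, size=n)
            causes = rng.choice(["a", "b", "c"], size=n)
            records, assignments = _cohort(w, causes)
            dist = weighted_csmf(records, assignments)
            for cause in "abc":
                want = 100 * w[causes == cause].sum() / w.sum()
                assert dist.percent(cause) == pytest.approx(want, abs=1e-12)
            assert dist.table["percent"].sum() == pytest.approx(100.0)

    def test_ci_contains_point_estimate(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 80))
            records, assignments = _cohort(
                rng.uniform(0.2, 3.0, size=n), rng.choice(["x", "y"], size=n))
            dist = weighted_csmf(records, assignments)
            t = dist.table
            assert ((t["ci_low"] <= t["percent"] + 1e-9)
                    & (t["percent"] <= t["ci_high"] + 1e-9)).all()
            assert (t["ci_low"] >= 0).all() and (t["ci_high"] <= 100).all()

    def test_missing_assignment_names_death(self):
        records, assignments = _cohort([1.0, 1.0], ["a", "b"])
        del assignments["d1"]
        with pytest.raises(KeyError, match="d1"):
            weighted_csmf(records, assignments)


class TestTwoPropChi2:
    def test_neonatal_tetanus_example(self):
        assert round(two_prop_chi2(18, 453, 2, 453).statistic, 1) == 13.1

    def test_child_diarrhea_example(self):
        assert round(two_prop_chi2(121, 620, 14, 620).statistic, 1) == 95.2

    def test_identical_proportions_give_zero(self):
        res = two_prop_chi2(7, 50, 7, 50)
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_degenerate_pooled_proportion(self):
        assert two_prop_chi2(0, 10, 0, 20).statistic == 0.0
        assert two_prop_chi2(10, 10, 20, 20).p_value == 1.0

    def test_matches_textbook_pearson_oracle(self, rng):
        for _ in range(200):
            n1, n2 = rng.integers(2, 200, size=2)
            x1 = int(rng.integers(0, n1 + 1))
            x2 = int(rng.integers(0, n2 + 1))
            got = two_prop_chi2(x1, int(n1), x2, int(n2))
            want = pearson_chi2_oracle(x1, int(n1), x2, int(n2))
            assert got.statistic == pytest.approx(want, abs=1e-10)

    def test_agrees_with_scipy_contingency(self):
        res = two_prop_chi2(30, 100, 10, 120)
        ref = chi2_contingency([[30, 70], [10, 110]], correction=False)
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_symmetric_in_groups(self):
        a = two_prop_chi2(18, 453, 2, 453).statistic
        b = two_prop_chi2(2, 453, 18, 453).statistic
        assert a == pytest.approx(b)

    def test_doubling_counts_doubles_statistic(self):
        base = two_prop_chi2(18, 453, 2, 453).statistic
        dbl = two_prop_chi2(36, 906, 4, 906).statistic
        assert dbl == pytest.approx(2 * base)

    def test_mid_p_flagged_and_below_fisher(self, rng):
        for _ in range(50):
            n1, n2 = rng.integers(5, 60, size=2)
            x1 = int(rng.integers(0, n1 + 1))
            x2 = int(rng.integers(0, n2 + 1))
            res = two_prop_chi2(x1, int(n1), x2, int(n2), mid_p=True)
            assert res.method == "mid-p exact"
            _, fisher_p = fisher_exact([[x1, n1 - x1], [x2, n2 - x2]])
            assert res.p_value <= fisher_p + 1e-9


class TestKappa:
    def test_dysentery_example(self):
        assert round(cohen_kappa(58, 18, 0, 544).kappa, 2) == 0.85

    def test_birth_asphyxia_example(self):
        assert round(cohen_kappa(84, 19, 29, 321).kappa, 2) == 0.71

    def test_perfect_agreement(self):
        res = cohen_kappa(50, 0, 0, 50)
        assert res.kappa == pytest.approx(1.0)
        assert res.grade == "excellent"

    def test_matches_direct_formula_oracle(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 200, size=4)
            if (a + b + c + d) == 0:
                continue
            try:
                got = cohen_kappa(int(a), int(b), int(c), int(d))
            except ValueError:
                continue  # degenerate margins
            want = kappa_oracle(int(a), int(b), int(c), int(d))
            assert got.kappa == pytest.approx(want, abs=1e-12)
            assert got.ci_low <= got.kappa <= got.ci_high

    def test_kappa_one_iff_no_disagreement(self, rng):
        assert cohen_kappa(13, 0, 0, 7).kappa == pytest.approx(1.0)
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 50, size=4))
            assert cohen_kappa(a, b, c, d).kappa < 1.0

    def test_relabel_invariance(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 100, size=4))
            assert cohen_kappa(a, b, c, d).kappa == \
                pytest.approx(cohen_kappa(d, c, b, a).kappa)

    @pytest.mark.parametrize("kappa,grade", [
        (0.81, "excellent"), (0.80, "good"), (0.61, "good"), (0.60, "moderate"),
        (0.41, "moderate"), (0.40, "fair"), (0.21, "fair"), (0.20, "poor"),
        (-0.1, "poor")])
    def test_grade_boundaries_strictly_greater(self, kappa, grade):
        assert kappa_grade(kappa) == grade


class TestAgreementTable:
    def test_identical_sets_have_no_discordance(self):
        sets = {f"d{i}": frozenset({"x"}) if i < 4 else frozenset()
                for i in range(10)}
        a, b, c, d = agreement_table(sets, sets, "x")
        assert (a, b, c, d) == (4, 0, 0, 6)

    def test_disjoint_sets_have_no_joint_positives(self):
        s1 = {f"d{i}": frozenset({"x"}) for i in range(5)}
        s2 = {f"d{i}": frozenset({"y"}) for i in range(5)}
        a, b, c, d = agreement_table(s1, s2, "x")
        assert a == 0 and b == 5 and c == 0 and d == 0

    def test_random_pairs_match_counting_oracle(self, rng):
        for _ in range(30):
            ids = [f"d{i}" for i in range(40)]
            s1 = {i: frozenset(rng.choice(["x", "y", "z"],
                                          size=int(rng.integers(0, 3)),
                                          replace=False)) for i in ids}
            s2 = {i: frozenset(rng.choice(["x", "y", "z"],
                                          size=int(rng.integers(0, 3)),
                                          replace=False)) for i in ids}
            a, b, c, d = agreement_table(s1, s2, "x")
            want_a = sum("x" in s1[i] and "x" in s2[i] for i in ids)
            want_b = sum("x" in s1[i] and "x" not in s2[i] for i in ids)
            want_c = sum("x" not in s1[i] and "x" in s2[i] for i in ids)
            assert (a, b, c, d) == (want_a, want_b, want_c, 40 - want_a - want_b - want_c)

    def test_mismatched_universes_error(self):
        with pytest.raises(ValueError, match="universes"):
            agreement_table({"d1": frozenset()}, {"d2": frozenset()}, "x")


class TestRankComparison:
    @staticmethod
    def _dist(pcts):
        records, assignments = _cohort(
            [1.0] * 100, [c for c, p in pcts.items() for _ in range(p)])
        return weighted_csmf(records, assignments)

    def test_identical_distributions_rank_equal(self):
        d = self._dist({"a": 50, "b": 30, "c": 20})
        table = rank_comparison(d, d)
        assert (table["rank_diff"] == 0).all()

    def test_reversed_two_cause_distribution(self):
        d1 = self._dist({"a": 70, "b": 30})
        d2 = self._dist({"a": 30, "b": 70})
        table = rank_comparison(d1, d2)
        assert table.loc["a", "rank_diff"] == -1
        assert table.loc["b", "rank_diff"] == 1

    def test_unspecified_left_aside(self):
        d = self._dist({"a": 50, "unspecified": 50})
        assert "unspecified" not in rank_comparison(d, d).index

    def test_random_distributions_match_sort_oracle(self, rng):
        for _ in range(20):
            counts = rng.multinomial(100, [0.25, 0.25, 0.25, 0.25])
            d = self._dist(dict(zip("abcd", counts)))
            table = rank_comparison(d, d)
            pcts = {c: d.percent(c) for c in table.index}
            distinct = sorted(set(pcts.values()), reverse=True)
            for cause in table.index:
                assert table.loc[cause, "rank_1"] == \
                    distinct.index(pcts[cause]) + 1
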