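import numpy as np
import pytest

from vasakit.records import SignData, VARecord
from vasakit.rules import default_ruleset, load_ruleset


@pytest.fixture(scope="session")
def neonate_ruleset():
    return default_ruleset("neonate")


@pytest.fixture(scope="session")
def child_ruleset():
    return default_ruleset("child")


def make_record(death_id="d0", age_group="neonate", age=3, signs=None,
                maternal=None, **kw):
    """Terse record builder: signs maps key -> True/False/'missing' or
    (True, duration)."""

    def coerce(m):
        out = {}
        for k, v in (m or {}).items():
            if isinstance(v, tuple):
                out[k] = SignData("yes", float(v[1]))
            elif v == "missing":
                out[k] = SignData("missing")
            else:
                out[k] = SignData("yes" if v else "no")
        return out

    return VARecord(death_id=death_id, age_group=age_group, age_at_death=age,
                    signs=coerce(signs), maternal_signs=coerce(maternal), **kw)


# ---------------------------------------------------------------------------
# a 12-sign toy rule set, small enough to enumerate every possible record


TOY_DOC = {
    "ruleset_id": "toy-12",
    "version": "1",
    "age_group": "child",
    "vocabulary": [f"s{i}" for i in range(12)],
    "maternal_vocabulary": [],
    "hierarchy": [
        {"cause": "alpha"}, {"cause": "beta"}, {"cause": "gamma"},
        {"cause": "delta", "comorbid": False}, {"cause": "epsilon"},
        {"cause": "zeta"}, {"cause": "possible_zeta"}, {"cause": "eta"},
    ],
    "rules": [
        {"cause": "alpha", "expr": {"all": [{"sign": "s0"}, {"sign": "s1"}]}},
        {"cause": "beta", "expr": {"any": [
            {"all": [{"sign": "s2"}, {"sign": "s3"}]},
            {"all": [{"sign": "s4"}, {"not": {"sign": "s5"}}]}]}},
        {"cause": "gamma", "expr": {"all": [
            {"sign": "s5"},
            {"any": [{"sign": "s6"}, {"sign": "s7"}]}]}},
        {"cause": "delta", "expr": {"all": [
            {"sign": "s8"}, {"not": {"any": [{"sign": "s0"}, {"sign": "s9"}]}}]}},
        {"cause": "epsilon", "expr": {"any": [{"sign": "s9"}, {"sign": "s10"}]}},
        {"cause": "zeta", "expr": {"all": [{"sign": "s11"}, {"sign": "s6"}]}},
        {"cause": "possible_zeta", "tier": "possible", "counterpart": "zeta",
         "expr": {"all": [{"sign": "s11"}]}},
        {"cause": "eta", "expr": {"all": [
            {"sign": "s7"}, {"sign": "s3"}, {"not": {"sign": "s11"}}]}},
    ],
}


@pytest.fixture(scope="session")
def toy_ruleset():
    return load_ruleset(TOY_DOC)


def toy_record(bits, death_id="t"):
    """Record over the toy vocabulary from a 12-tuple of 0/1."""
    signs = {f"s{i}": SignData("yes" if b else "no") for i, b in enumerate(bits)}
    return VARecord(death_id=death_id, age_group="child", age_at_death=12,
                    signs=signs)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260922)
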