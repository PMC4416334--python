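"""Synthetic VA cohorts with known truth.

The generator emulates the structure of a two-stage cluster mortality
survey: neonatal and child deaths with cluster survey weights, region
labels, cause-specific sign/symptom profiles, co-morbidity couplings,
illness-onset timing, a maternal-infection model, and physician death
certificates produced from the truth plus configurable physician
behaviour.  Every stage of the pipeline can therefore be tested
end-to-end without any external data.

Sign profiles are conditional-independence Bernoulli given the true
cause, with explicit couplings for the co-morbidity pairs the
hierarchy logic must handle (a meningitis death also shows the sepsis
signature; malaria and pneumonia presentations overlap).  Certificates
are generated from truth plus behaviour noise — *not* by re-running
the rules — so algorithm-vs-physician agreement statistics have
nontrivial, tunable kappa.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .certificates import CertLine, DeathCertificate
from .classify import CauseAssignment
from .records import CHILD, NEONATE, SignData, VARecord
from .rules import UNSPECIFIED, RuleSet


@dataclass(frozen=True)
class SyntheticTruth:
    death_id: str
    true_cause: str
    comorbid: tuple[str, ...]
    maternal_infection: bool
    onset_day: int | None


@dataclass
class CauseProfile:
    """Sign signature of one cause: P(sign present | cause), mean
    durations (days) for duration-bearing signs, and the probability
    that illness onset falls before day 2 of life (neonates)."""

    signs: dict[str, float]
    durations: dict[str, float] = field(default_factory=dict)
    p_early_onset: float = 0.35


# Default cause mix: a realistic high-mortality, malaria-endemic profile
# (dominant severe infections and asphyxia among neonates; malaria,
# diarrhoeal disease and meningitis among children).  Round numbers by
# design — the generator is not fitted to any observed distribution.
DEFAULT_NEONATE_CSMF: dict[str, float] = {
    "sepsis": 0.30, "birth_injury_asphyxia": 0.20, "pneumonia": 0.12,
    "preterm_delivery": 0.08, "diarrhea": 0.06, "meningitis": 0.05,
    "neonatal_tetanus": 0.04, "congenital_malformation": 0.03,
    "sudden_unexplained_death": 0.02, "neonatal_jaundice": 0.02,
    "hemorrhagic_disease": 0.02, UNSPECIFIED: 0.06,
}

DEFAULT_CHILD_CSMF: dict[str, float] = {
    "malaria": 0.28, "diarrhea": 0.19, "meningitis": 0.15, "pneumonia": 0.12,
    "dysentery": 0.06, "aids": 0.03, "malnutrition": 0.03, "measles": 0.02,
    "injury": 0.02, "pertussis": 0.01, "hemorrhagic_fever": 0.01,
    "other_infections": 0.03, UNSPECIFIED: 0.05,
}

#: 8 regions of Niger with weights proportional to the deaths each
#: contributed in the source survey frame.
DEFAULT_REGIONS: dict[str, float] = {
    "Agadez": 29, "Diffa": 86, "Dosso": 197, "Maradi": 173,
    "Tahoua": 155, "Tillaberi": 179, "Zinder": 227, "Niamey": 27,
}

DEFAULT_NEONATE_PROFILES: dict[str, CauseProfile] = {
    "neonatal_tetanus": CauseProfile(
        {"suckled_normally_first_days": 0.95, "stopped_suckling": 0.95,
         "convulsions": 0.7, "spasms": 0.8, "arched_back": 0.5, "fever": 0.4},
        p_early_onset=0.05),
    "congenital_malformation": CauseProfile(
        {"visible_malformation": 0.95}, p_early_onset=0.9),
    "birth_injury_asphyxia": CauseProfile(
        {"not_cried_at_birth": 0.8, "not_breathed_at_birth": 0.6,
         "resuscitated": 0.3, "bruises_or_birth_injury": 0.1,
         "fever": 0.5, "lethargy": 0.7, "fast_breathing": 0.4,
         "chest_indrawing": 0.2},
        durations={"fast_breathing": 1.5}, p_early_onset=0.97),
    "meningitis": CauseProfile(
        {"bulging_fontanelle": 0.85, "convulsions": 0.6, "lethargy": 0.9,
         "unconscious": 0.4, "fever": 0.9, "stopped_suckling": 0.7,
         "fast_breathing": 0.45, "chest_indrawing": 0.35},
        durations={"fast_breathing": 3.0}, p_early_onset=0.4),
    "diarrhea": CauseProfile(
        {"loose_stools": 0.97, "frequent_stools": 0.9, "fever": 0.6,
         "lethargy": 0.5, "vomit_everything": 0.3},
        durations={"loose_stools": 3.0}, p_early_onset=0.15),
    "pneumonia": CauseProfile(
        {"fast_breathing": 0.9, "difficult_breathing": 0.7,
         "chest_indrawing": 0.8, "grunting": 0.5, "fever": 0.75,
         "lethargy": 0.5, "stopped_suckling": 0.5},
        durations={"fast_breathing": 3.0, "difficult_breathing": 3.0},
        p_early_onset=0.4),
    "sepsis": CauseProfile(
        {"fever": 0.85, "hypothermia": 0.15, "lethargy": 0.75,
         "stopped_suckling": 0.7, "vomit_everything": 0.3,
         "convulsions": 0.2},
        p_early_onset=0.4),
    "neonatal_jaundice": CauseProfile(
        {"yellow_skin": 0.95, "yellow_palms_eyes": 0.85, "lethargy": 0.6},
        p_early_onset=0.5),
    "hemorrhagic_disease": CauseProfile(
        {"bleeding_anywhere": 0.95, "lethargy": 0.5}, p_early_onset=0.6),
    "sudden_unexplained_death": CauseProfile(
        {"appeared_healthy_then_died_suddenly": 0.95}, p_early_onset=0.2),
    "preterm_delivery": CauseProfile(
        {"fast_breathing": 0.5, "chest_indrawing": 0.45}, p_early_onset=0.9),
    UNSPECIFIED: CauseProfile({}, p_early_onset=0.3),
}

DEFAULT_CHILD_PROFILES: dict[str, CauseProfile] = {
    "injury": CauseProfile({"injury_event": 0.95}),
    "aids": CauseProfile(
        {"loose_stools": 0.8, "visible_wasting": 0.8, "oral_thrush": 0.6,
         "swollen_glands": 0.4, "fever": 0.6},
        durations={"loose_stools": 45.0, "fever": 40.0}),
    "malnutrition": CauseProfile(
        {"visible_wasting": 0.85, "swollen_feet": 0.35, "loose_stools": 0.4,
         "frequent_stools": 0.3, "fever": 0.3},
        durations={"loose_stools": 5.0}),
    "measles": CauseProfile(
        {"rash": 0.95, "fever": 0.95, "red_eyes": 0.7, "runny_nose": 0.6,
         "cough": 0.7, "loose_stools": 0.3, "frequent_stools": 0.2},
        durations={"fever": 5.0, "cough": 4.0, "loose_stools": 3.0}),
    "meningitis": CauseProfile(
        {"stiff_neck": 0.8, "bulging_fontanelle": 0.45, "fever": 0.95,
         "convulsions": 0.7, "lethargy": 0.7, "unconscious": 0.5,
         "loose_stools": 0.3, "frequent_stools": 0.25, "cough": 0.3,
         "fast_breathing": 0.3},
        durations={"fever": 3.0, "cough": 3.0, "loose_stools": 2.0,
                   "fast_breathing": 3.0}),
    "dysentery": CauseProfile(
        {"loose_stools": 0.97, "blood_in_stool": 0.95, "frequent_stools": 0.8,
         "fever": 0.5},
        durations={"loose_stools": 4.0, "fever": 2.0}),
    "diarrhea": CauseProfile(
        {"loose_stools": 0.97, "frequent_stools": 0.9, "fever": 0.5,
         "lethargy": 0.4, "cough": 0.15},
        durations={"loose_stools": 4.0, "fever": 2.0, "cough": 2.0}),
    "pertussis": CauseProfile(
        {"cough": 0.97, "whooping_cough": 0.85, "vomit_after_cough": 0.6,
         "fever": 0.3},
        durations={"cough": 21.0, "fever": 3.0}),
    "pneumonia": CauseProfile(
        {"cough": 0.9, "fast_breathing": 0.85, "difficult_breathing": 0.7,
         "chest_indrawing": 0.75, "grunting": 0.4, "fever": 0.8,
         "chills": 0.2},
        durations={"cough": 5.0, "fast_breathing": 4.0,
                   "difficult_breathing": 3.0, "fever": 4.0}),
    "malaria": CauseProfile(
        {"fever": 0.97, "chills": 0.8, "pallor": 0.5, "convulsions": 0.3,
         "lethargy": 0.4, "vomit_after_cough": 0.0, "cough": 0.25,
         "fast_breathing": 0.2},
        durations={"fever": 3.0, "cough": 2.0, "fast_breathing": 2.0}),
    "hemorrhagic_fever": CauseProfile(
        {"fever": 0.95, "bleeding_anywhere": 0.9, "pallor": 0.5},
        durations={"fever": 4.0}),
    "other_infections": CauseProfile(
        {"fever": 0.9, "ear_discharge": 0.4, "skin_pustules": 0.4,
         "abdominal_swelling": 0.3},
        durations={"fever": 5.0}),
    UNSPECIFIED: CauseProfile({}),
}

#: P(signature of B is overlaid | true cause A): the co-morbidity pairs
#: the hierarchy must disentangle.
DEFAULT_NEONATE_COMORBIDITY: dict[str, dict[str, float]] = {
    "meningitis": {"sepsis": 0.9},
    "birth_injury_asphyxia": {"sepsis": 0.5, "pneumonia": 0.3},
    "diarrhea": {"sepsis": 0.6},
    "pneumonia": {"sepsis": 0.6},
    "sepsis": {"preterm_delivery": 0.1},
}

DEFAULT_CHILD_COMORBIDITY: dict[str, dict[str, float]] = {
    "meningitis": {"diarrhea": 0.3, "pneumonia": 0.3},
    "malaria": {"pneumonia": 0.2, "diarrhea": 0.1},
    "diarrhea": {"pneumonia": 0.2},
    "aids": {"diarrhea": 0.4, "pneumonia": 0.4},
}


class ConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort.

    Defaults emulate the study conditions: 453 neonatal and 620 child
    deaths from a two-stage cluster survey over 8 regions, a 15%
    baseline maternal-infection rate with no built-in association
    (odds multiplier 1), 5% item missingness and moderate cluster
    weight dispersion.
    """

    seed: int = 0
    n_neonates: int = 453
    n_children: int = 620
    neonate_csmf: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NEONATE_CSMF))
    child_csmf: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CHILD_CSMF))
    neonate_profiles: dict[str, CauseProfile] = field(
        default_factory=lambda: dict(DEFAULT_NEONATE_PROFILES))
    child_profiles: dict[str, CauseProfile] = field(
        default_factory=lambda: dict(DEFAULT_CHILD_PROFILES))
    neonate_comorbidity: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_NEONATE_COMORBIDITY.items()})
    child_comorbidity: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CHILD_COMORBIDITY.items()})
    background_sign_rate: float = 0.02
    missingness_rate: float = 0.05
    n_clusters: int = 80
    weight_dispersion: float = 0.3    # sd of log cluster weight; 0 = equal weights
    regions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REGIONS))
    maternal_baseline: float = 0.15
    maternal_odds_multiplier: float = 1.0   # >1 injects the early-onset association
    preterm_pregnancy_rate: float = 0.07    # P(pregnancy < 8 months | other cause)
    # physician behaviour
    p_correct_underlying: float = 0.75
    p_chain: float = 0.4             # P(add a direct cause above the underlying)
    p_part2_comorbid: float = 0.6    # P(each true co-morbid appears in part 2)
    p_floor_diagnosis: float = 0.25  # P(add a minimal-criteria-floor diagnosis)
    p_unspecified_cert: float = 0.6  # P(physician also finds nothing | truth unspecified)
    p_maternal_cert: float = 0.4     # P(certify a maternal cause when applicable)

    def validate(self) -> None:
        for name, csmf in (("neonate_csmf", self.neonate_csmf),
                           ("child_csmf", self.child_csmf)):
            total = sum(csmf.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} sums to {total}, not 1")
            if any(p < 0 for p in csmf.values()):
                raise ConfigError(f"{name} has negative probabilities")
        for rate in (self.background_sign_rate, self.missingness_rate,
                     self.maternal_baseline, self.p_correct_underlying,
                     self.p_chain, self.p_part2_comorbid,
                     self.p_floor_diagnosis, self.p_unspecified_cert,
                     self.p_maternal_cert, self.preterm_pregnancy_rate):
            if not 0 <= rate <= 1:
                raise ConfigError(f"probability {rate} outside [0, 1]")
        if self.maternal_odds_multiplier < 0:
            raise ConfigError("maternal odds multiplier must be >= 0")
        if self.n_neonates < 0 or self.n_children < 0 or self.n_clusters <= 0:
            raise ConfigError("sizes must be positive")
        for grp, csmf, profiles in (("neonate", self.neonate_csmf, self.neonate_profiles),
                                    ("child", self.child_csmf, self.child_profiles)):
            missing = [c for c in csmf if c not in profiles]
            if missing:
                raise ConfigError(f"{grp} causes without sign profiles: {missing}")

    def with_odds_multiplier(self, m: float) -> "GeneratorConfig":
        if m < 1:
            raise ConfigError("odds multiplier must be >= 1")
        return dataclasses.replace(self, maternal_odds_multiplier=m)


def inject_maternal_association(config: GeneratorConfig, m: float) -> GeneratorConfig:
    """Config variant where early-onset severe-infection deaths carry
    maternal infection at odds multiplied by *m* (m = 1: no association)."""
    return config.with_odds_multiplier(m)


SEVERE = ("meningitis", "pneumonia", "sepsis")

# signature signs the physician guide treats as duration-bearing
_DURATION_SIGNS = {"fast_breathing", "difficult_breathing", "cough",
                   "loose_stools", "fever"}


def _maternal_prob(base: float, m: float) -> float:
    # odds-scale tilt: p' = mb / (1 - b + mb)
    return m * base / (1 - base + m * base)


def _draw_sign_map(rng: np.random.Generator, vocab: Sequence[str],
                   probs: Mapping[str, float], durations: Mapping[str, float],
                   missingness: float, background: float) -> dict[str, SignData]:
    out: dict[str, SignData] = {}
    for sign in vocab:
        p = probs.get(sign, background)
        if rng.random() < missingness:
            out[sign] = SignData("missing")
            continue
        if rng.random() < p:
            dur = None
            if sign in _DURATION_SIGNS:
                mean = durations.get(sign, 2.0)
                dur = float(max(1, rng.poisson(mean)))
            out[sign] = SignData("yes", dur)
        else:
            out[sign] = SignData("no")
    return out


def _combined_profile(cause: str, profiles: Mapping[str, CauseProfile],
                      comorbidity: Mapping[str, Mapping[str, float]],
                      rng: np.random.Generator) -> tuple[dict, dict, tuple[str, ...]]:
    base = profiles[cause]
    probs = dict(base.signs)
    durs = dict(base.durations)
    overlaid: list[str] = []
    for other, p in comorbidity.get(cause, {}).items():
        if rng.random() < p:
            overlaid.append(other)
            op = profiles[other]
            for s, q in op.signs.items():
                probs[s] = max(probs.get(s, 0.0), q)
            for s, d in op.durations.items():
                durs.setdefault(s, d)
    return probs, durs, tuple(overlaid)


def generate(config: GeneratorConfig, neonate_ruleset: RuleSet | None = None,
             child_ruleset: RuleSet | None = None
             ) -> tuple[list[VARecord], list[DeathCertificate], list[SyntheticTruth]]:
    """Draw a full synthetic cohort: interview records, physician
    certificates and the underlying truth.  Reproducible given
    ``config.seed``."""
    from .rules import default_ruleset

    config.validate()
    rng = np.random.default_rng(config.seed)
    if neonate_ruleset is None:
        neonate_ruleset = default_ruleset(NEONATE)
    if child_ruleset is None:
        child_ruleset = default_ruleset(CHILD)

    regions = list(config.regions)
    region_p = np.array([config.regions[r] for r in regions], dtype=float)
    region_p /= region_p.sum()
    cluster_region = rng.choice(len(regions), size=config.n_clusters, p=region_p)
    if config.weight_dispersion > 0:
        cluster_w = np.exp(rng.normal(0.0, config.weight_dispersion,
                                      config.n_clusters))
    else:
        cluster_w = np.ones(config.n_clusters)

    records: list[VARecord] = []
    certs: list[DeathCertificate] = []
    truths: list[SyntheticTruth] = []

    for age_group, n, csmf, profiles, comorb, ruleset in (
            (NEONATE, config.n_neonates, config.neonate_csmf,
             config.neonate_profiles, config.neonate_comorbidity, neonate_ruleset),
            (CHILD, config.n_children, config.child_csmf,
             config.child_profiles, config.child_comorbidity, child_ruleset)):
        causes = list(csmf)
        p = np.array([csmf[c] for c in causes], dtype=float)
        p /= p.sum()
        drawn = rng.choice(len(causes), size=n, p=p)
        clusters = rng.integers(0, config.n_clusters, size=n)
        for i in range(n):
            cause = causes[drawn[i]]
            death_id = f"{age_group[0]}{i:05d}"
            cl = int(clusters[i])
            rec, truth = _draw_death(rng, config, death_id, age_group, cause,
                                     profiles, comorb, ruleset,
                                     region=regions[cluster_region[cl]],
                                     cluster_id=f"c{cl:03d}",
                                     weight=float(cluster_w[cl]))
            cert = _draw_certificate(rng, config, truth, rec, ruleset, causes)
            records.append(rec)
            certs.append(cert)
            truths.append(truth)
    return records, certs, truths


def _draw_death(rng, config: GeneratorConfig, death_id: str, age_group: str,
                cause: str, profiles, comorbidity, ruleset: RuleSet,
                region: str, cluster_id: str, weight: float
                ) -> tuple[VARecord, SyntheticTruth]:
    probs, durs, overlaid = _combined_profile(cause, profiles, comorbidity, rng)
    signs = _draw_sign_map(rng, ruleset.vocabulary, probs, durs,
                           config.missingness_rate, config.background_sign_rate)

    onset_day: int | None = None
    pregnancy = None
    maternal_signs: dict[str, SignData] = {}
    m_truth = False
    if age_group == NEONATE:
        profile = profiles[cause]
        early = rng.random() < profile.p_early_onset
        onset_day = int(rng.integers(0, 2)) if early else int(rng.integers(2, 21))
        age = onset_day + int(rng.integers(0, 7))
        age = min(age, 27)
        # pregnancy duration: truly short for preterm deaths
        if cause == "preterm_delivery":
            pregnancy = float(rng.choice([6.0, 6.5, 7.0, 7.5]))
        else:
            pregnancy = (float(rng.choice([7.0, 7.5]))
                         if rng.random() < config.preterm_pregnancy_rate
                         else float(rng.choice([9.0, 9.5, 10.0])))
        base = config.maternal_baseline
        if cause in SEVERE and onset_day < 2:
            pm = _maternal_prob(base, config.maternal_odds_multiplier)
        else:
            pm = base
        m_truth = rng.random() < pm
        maternal_signs = _draw_maternal_signs(rng, config, ruleset, m_truth)
    else:
        age = int(rng.integers(1, 60))

    rec = VARecord(
        death_id=death_id, age_group=age_group, age_at_death=age,
        sex="female" if rng.random() < 0.49 else "male",
        region=region, cluster_id=cluster_id, survey_weight=weight,
        signs=signs, pregnancy_duration=pregnancy,
        maternal_signs=maternal_signs, illness_onset_day=onset_day)
    truth = SyntheticTruth(death_id, cause, overlaid, m_truth, onset_day)
    return rec, truth


def _draw_maternal_signs(rng, config: GeneratorConfig, ruleset: RuleSet,
                         infected: bool) -> dict[str, SignData]:
    out = {}
    for sign in ruleset.maternal_vocabulary:
        if rng.random() < config.missingness_rate:
            out[sign] = SignData("missing")
            continue
        p = 0.75 if infected else 0.02
        out[sign] = SignData("yes" if rng.random() < p else "no")
    return out


# simple physician confusion map: what an imperfect reader certifies instead
_CONFUSION = {
    "meningitis": "sepsis", "diarrhea": "sepsis", "pneumonia": "sepsis",
    "sepsis": "pneumonia", "neonatal_tetanus": "sepsis",
    "malaria": "pneumonia", "dysentery": "diarrhea",
    "measles": "malaria", "pertussis": "pneumonia",
}


def _draw_certificate(rng, config: GeneratorConfig, truth: SyntheticTruth,
                      record: VARecord, ruleset: RuleSet,
                      causes: Sequence[str]) -> DeathCertificate:
    if truth.true_cause == UNSPECIFIED:
        if rng.random() < config.p_unspecified_cert:
            underlying = UNSPECIFIED
        else:
            underlying = str(rng.choice([c for c in causes if c != UNSPECIFIED]))
    elif rng.random() < config.p_correct_underlying:
        underlying = truth.true_cause
    else:
        underlying = _CONFUSION.get(truth.true_cause)
        if underlying is None:
            pool = [c for c in causes if c not in (truth.true_cause, UNSPECIFIED)]
            underlying = str(rng.choice(pool)) if pool else UNSPECIFIED

    part1 = []
    if (config.p_chain and truth.comorbid and underlying != UNSPECIFIED
            and rng.random() < config.p_chain):
        direct = truth.comorbid[0]
        if direct != underlying:
            part1.append(CertLine(direct))
    part1.append(CertLine(underlying))

    part2 = {c for c in truth.comorbid
             if c != underlying and rng.random() < config.p_part2_comorbid}
    if rng.random() < config.p_floor_diagnosis:
        floor_hits = [c for c, crit in ruleset.minimum_criteria.items()
                      if c != underlying and c not in part2 and crit(record)]
        if floor_hits:
            part2.add(str(rng.choice(floor_hits)))

    part2_m: set[str] = set()
    if record.age_group == NEONATE and len(part1) < 4:
        if truth.true_cause == "birth_injury_asphyxia" and rng.random() < config.p_maternal_cert:
            part1.append(CertLine("obstructed_labor", maternal=True))
        elif truth.maternal_infection and rng.random() < config.p_maternal_cert:
            part1.append(CertLine("maternal_infection", maternal=True))
    return DeathCertificate(truth.death_id, part1, part2, part2_m)


def truth_assignments(truths: Sequence[SyntheticTruth]) -> dict[str, CauseAssignment]:
    """Recast generator truth as cause assignments (for oracle comparisons)."""
    out = {}
    for t in truths:
        eligible = ([] if t.true_cause == UNSPECIFIED
                    else [t.true_cause, *t.comorbid])
        out[t.death_id] = CauseAssignment(
            death_id=t.death_id, eligible=eligible, primary=t.true_cause,
            comorbid=list(t.comorbid), reporting_cause=t.true_cause,
            ruleset_id="truth")
    return out


# ---------------------------------------------------------------------------
# deterministic configuration for parameter-recovery experiments


def recovery_config(csmf: Mapping[str, float] | None = None,
                    n: int = 5000, seed: int = 0) -> GeneratorConfig:
    """Noise-free child cohort for CSMF parameter recovery: deterministic
    sign profiles (probabilities 0/1), no missingness, no background
    signs, no co-morbidity couplings, equal weights.

    Default CSMF is (0.4, 0.3, 0.2, 0.1) over malaria, diarrhea,
    pneumonia and meningitis; the default child rule set then recovers
    the configured CSMF up to binomial sampling error.
    """
    if csmf is None:
        csmf = {"malaria": 0.4, "diarrhea": 0.3, "pneumonia": 0.2,
                "meningitis": 0.1}
    profiles = {
        "malaria": CauseProfile({"fever": 1.0, "chills": 1.0},
                                durations={"fever": 3.0}),
        "diarrhea": CauseProfile({"loose_stools": 1.0, "frequent_stools": 1.0},
                                 durations={"loose_stools": 4.0}),
        "pneumonia": CauseProfile(
            {"cough": 1.0, "fast_breathing": 1.0, "chest_indrawing": 1.0},
            durations={"cough": 5.0, "fast_breathing": 4.0}),
        "meningitis": CauseProfile(
            {"stiff_neck": 1.0, "fever": 1.0, "convulsions": 1.0},
            durations={"fever": 3.0}),
        UNSPECIFIED: CauseProfile({}),
    }
    csmf = dict(csmf)
    if UNSPECIFIED not in csmf:
        csmf[UNSPECIFIED] = max(0.0, 1.0 - sum(csmf.values()))
        if csmf[UNSPECIFIED] == 0.0:
            del csmf[UNSPECIFIED]
    return GeneratorConfig(
        seed=seed, n_neonates=0, n_children=n,
        child_csmf=csmf, child_profiles=profiles, child_comorbidity={},
        background_sign_rate=0.0, missingness_rate=0.0,
        weight_dispersion=0.0)


def null_calibration(config: GeneratorConfig, n_replicates: int = 1000,
                     alpha: float = 0.05, seed: int = 0) -> float:
    """Monte-Carlo rejection rate of the severe-infection onset
    association test across replicate cohorts drawn under *config*.

    With ``maternal_odds_multiplier = 1`` this estimates the test's
    type-I error; with a large multiplier, its power.  Each replicate
    draws causes, onset days and maternal-infection flags from the
    generator's neonatal model and runs the early-vs-late two-proportion
    chi-square on the severe-infection group.
    """
    from .stats import two_prop_chi2 as chi2

    config.validate()
    rng = np.random.default_rng(seed)
    causes = list(config.neonate_csmf)
    p = np.array([config.neonate_csmf[c] for c in causes])
    p /= p.sum()
    p_early = np.array([config.neonate_profiles[c].p_early_onset for c in causes])
    severe = np.array([c in SEVERE for c in causes])
    base = config.maternal_baseline
    p_m_shift = _maternal_prob(base, config.maternal_odds_multiplier)

    n = config.n_neonates
    rejections = 0
    valid = 0
    for _ in range(n_replicates):
        idx = rng.choice(len(causes), size=n, p=p)
        early = rng.random(n) < p_early[idx]
        sev = severe[idx]
        pm = np.where(sev & early, p_m_shift, base)
        maternal = rng.random(n) < pm
        e = sev & early
        l = sev & ~early
        n1, n2 = int(e.sum()), int(l.sum())
        if n1 == 0 or n2 == 0:
            continue
        res = chi2(int(maternal[e].sum()), n1, int(maternal[l].sum()), n2)
        valid += 1
        if res.p_value < alpha:
            rejections += 1
    return rejections / valid if valid else float("nan")
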