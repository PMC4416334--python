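"""Verbal-autopsy interview records: data model, validation and file I/O.

A verbal autopsy (VA) record holds one death's interview responses: the
demographic and survey-design fields, the tri-state sign/symptom answers
(yes / no / missing — missingness is *not* collapsed into "no"), sign
durations and onset-order ranks, and for neonates the maternal illness
items and pregnancy duration.

Files are plain CSV (UTF-8, comma, header required) or JSON.  The CSV
layout is flat: one column per scalar field, then ``sign__<key>``,
``dur__<key>``, ``ord__<key>`` triples per child sign and
``msign__<key>`` / ``mdur__<key>`` pairs per maternal sign.  The JSON
mirror is a list of objects with nested ``signs`` / ``maternal_signs``
mappings.  Tri-states are coded ``y`` / ``n`` / empty.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

NEONATE = "neonate"
CHILD = "child"
AGE_GROUPS = (NEONATE, CHILD)

#: inclusive age windows: days for neonates, months for children
AGE_WINDOWS = {NEONATE: (0, 27), CHILD: (1, 59)}

PRESENT_CODES = {"y": "yes", "yes": "yes", "1": "yes",
                 "n": "no", "no": "no", "0": "no",
                 "": "missing", "missing": "missing", ".": "missing"}


@dataclass(frozen=True)
class SignData:
    """One sign/symptom answer: tri-state presence, duration (days), onset rank.

    ``duration`` and ``onset_order`` are only meaningful when
    ``present == "yes"``; validation flags duration-without-presence.
    """

    present: str = "missing"  # yes | no | missing
    duration: float | None = None
    onset_order: int | None = None

    def __post_init__(self) -> None:
        if self.present not in ("yes", "no", "missing"):
            raise ValueError(f"invalid tri-state {self.present!r}")


MISSING_SIGN = SignData()


@dataclass
class VARecord:
    """One death's verbal-autopsy interview."""

    death_id: str
    age_group: str
    age_at_death: int  # days (neonate) or months (child); units differ by group
    sex: str = "unknown"
    region: str = ""
    cluster_id: str = ""
    survey_weight: float = 1.0
    signs: dict[str, SignData] = field(default_factory=dict)
    pregnancy_duration: float | None = None  # months
    maternal_signs: dict[str, SignData] = field(default_factory=dict)
    illness_onset_day: int | None = None

    def sign(self, key: str) -> SignData:
        return self.signs.get(key, MISSING_SIGN)

    def maternal_sign(self, key: str) -> SignData:
        return self.maternal_signs.get(key, MISSING_SIGN)


@dataclass
class Violation:
    death_id: str
    field: str
    message: str


@dataclass
class ValidationReport:
    n_records: int
    violations: list[Violation]

    @property
    def ok(self) -> bool:
        return not self.violations

    def summary(self) -> str:
        head = f"{self.n_records} records, {len(self.violations)} violations"
        lines = [f"  {v.death_id}: {v.field}: {v.message}" for v in self.violations]
        return "\n".join([head] + lines)


@dataclass
class SurveillanceTable:
    """Regional disease-surveillance counts (cases notified, CSF samples,
    positive cultures, deaths), one row per (region, year)."""

    frame: pd.DataFrame

    COLUMNS = ("region", "year", "cases_notified", "csf_samples_received",
               "positive_cultures", "deaths")

    def __post_init__(self) -> None:
        missing = [c for c in ("region", "year", "cases_notified") if c not in self.frame.columns]
        if missing:
            raise ValueError(f"surveillance table missing columns: {missing}")
        f = self.frame
        for col in ("cases_notified", "csf_samples_received", "positive_cultures", "deaths"):
            if col in f.columns and (f[col].dropna() < 0).any():
                raise ValueError(f"negative counts in {col}")
        both = f.dropna(subset=["csf_samples_received"]) if "csf_samples_received" in f else None
        if both is not None and (both["csf_samples_received"] > both["cases_notified"]).any():
            raise ValueError("csf_samples_received exceeds cases_notified")
        if {"positive_cultures", "csf_samples_received"} <= set(f.columns):
            b = f.dropna(subset=["positive_cultures", "csf_samples_received"])
            if (b["positive_cultures"] > b["csf_samples_received"]).any():
                raise ValueError("positive_cultures exceeds csf_samples_received")

    @classmethod
    def read_csv(cls, path: str | Path) -> "SurveillanceTable":
        return cls(pd.read_csv(path))

    def regional_totals(self, column: str = "cases_notified") -> pd.Series:
        return self.frame.groupby("region")[column].sum()


# ---------------------------------------------------------------------------
# parsing helpers

def _parse_tristate(raw, death_id: str, col: str) -> str:
    key = str(raw).strip().lower() if raw is not None else ""
    if key in ("nan", "none"):
        key = ""
    if key not in PRESENT_CODES:
        raise RecordParseError(death_id, col, f"unrecognised tri-state code {raw!r}")
    return PRESENT_CODES[key]


def _parse_optional_float(raw):
    if raw is None or (isinstance(raw, str) and not raw.strip()):
        return None
    v = float(raw)
    return None if pd.isna(v) else v


class RecordParseError(ValueError):
    def __init__(self, death_id: str, field: str, message: str):
        self.death_id, self.field = death_id, field
        super().__init__(f"record {death_id!r}, field {field!r}: {message}")


def _record_from_flat(row: Mapping, vocabulary: Sequence[str] | None,
                      unknown: set[str]) -> VARecord:
    death_id = str(row.get("death_id", "?"))
    signs: dict[str, SignData] = {}
    maternal: dict[str, SignData] = {}
    for col, raw in row.items():
        if col.startswith("sign__") or col.startswith("msign__"):
            if isinstance(raw, str) and raw.strip() == "-":
                continue  # "-" marks a question not asked of this record
            is_m = col.startswith("msign__")
            key = col.split("__", 1)[1]
            if vocabulary is not None and key not in vocabulary:
                unknown.add(key)
            present = _parse_tristate(raw, death_id, col)
            dur_col = ("mdur__" if is_m else "dur__") + key
            ord_col = "ord__" + key
            dur = _parse_optional_float(row.get(dur_col))
            rank = _parse_optional_float(row.get(ord_col))
            sd = SignData(present, dur, int(rank) if rank is not None else None)
            (maternal if is_m else signs)[key] = sd
    try:
        age = int(float(row["age_at_death"]))
        weight = float(row.get("survey_weight", 1.0))
    except (KeyError, ValueError) as exc:
        raise RecordParseError(death_id, "age_at_death/survey_weight", str(exc))
    onset = _parse_optional_float(row.get("illness_onset_day"))
    return VARecord(
        death_id=death_id,
        age_group=str(row["age_group"]).strip().lower(),
        age_at_death=age,
        sex=str(row.get("sex", "unknown")),
        region=str(row.get("region", "")),
        cluster_id=str(row.get("cluster_id", "")),
        survey_weight=weight,
        signs=signs,
        pregnancy_duration=_parse_optional_float(row.get("pregnancy_duration")),
        maternal_signs=maternal,
        illness_onset_day=int(onset) if onset is not None else None,
    )


def read_records(path: str | Path, vocabulary: Sequence[str] | None = None) -> list[VARecord]:
    """Read VA records from CSV or JSON.

    Unknown sign keys (not in *vocabulary*) raise a warning listing the
    keys; malformed rows raise :class:`RecordParseError` naming row and
    field.  Tri-state coding is preserved: an empty cell is *missing*,
    never "no".
    """
    path = Path(path)
    unknown: set[str] = set()
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        records = [_record_from_json(obj, vocabulary, unknown) for obj in payload]
    else:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        records = [_record_from_flat(row, vocabulary, unknown)
                   for row in df.to_dict(orient="records")]
    if unknown:
        warnings.warn(f"unknown sign keys (kept, flagged): {sorted(unknown)}",
                      stacklevel=2)
    return records


def _record_from_json(obj: Mapping, vocabulary, unknown: set[str]) -> VARecord:
    death_id = str(obj.get("death_id", "?"))

    def parse_map(m: Mapping | None) -> dict[str, SignData]:
        out = {}
        for key, sd in (m or {}).items():
            if vocabulary is not None and key not in vocabulary:
                unknown.add(key)
            out[key] = SignData(
                _parse_tristate(sd.get("present", ""), death_id, key),
                sd.get("duration"),
                sd.get("onset_order"),
            )
        return out

    return VARecord(
        death_id=death_id,
        age_group=obj["age_group"],
        age_at_death=int(obj["age_at_death"]),
        sex=obj.get("sex", "unknown"),
        region=obj.get("region", ""),
        cluster_id=str(obj.get("cluster_id", "")),
        survey_weight=float(obj.get("survey_weight", 1.0)),
        signs=parse_map(obj.get("signs")),
        pregnancy_duration=obj.get("pregnancy_duration"),
        maternal_signs=parse_map(obj.get("maternal_signs")),
        illness_onset_day=obj.get("illness_onset_day"),
    )


_TRI_OUT = {"yes": "y", "no": "n", "missing": ""}


def write_records(records: Iterable[VARecord], path: str | Path) -> None:
    """Write records to CSV or JSON (by extension); inverse of read_records."""
    path = Path(path)
    records = list(records)
    if path.suffix.lower() == ".json":
        payload = []
        for r in records:
            payload.append({
                "death_id": r.death_id, "age_group": r.age_group,
                "age_at_death": r.age_at_death, "sex": r.sex,
                "region": r.region, "cluster_id": r.cluster_id,
                "survey_weight": r.survey_weight,
                "pregnancy_duration": r.pregnancy_duration,
                "illness_onset_day": r.illness_onset_day,
                "signs": {k: {"present": s.present, "duration": s.duration,
                              "onset_order": s.onset_order}
                          for k, s in sorted(r.signs.items())},
                "maternal_signs": {k: {"present": s.present, "duration": s.duration,
                                       "onset_order": s.onset_order}
                                   for k, s in sorted(r.maternal_signs.items())},
            })
        path.write_text(json.dumps(payload, indent=1))
        return

    sign_keys = sorted({k for r in records for k in r.signs})
    m_keys = sorted({k for r in records for k in r.maternal_signs})
    rows = []
    for r in records:
        row: dict[str, object] = {
            "death_id": r.death_id, "age_group": r.age_group,
            "age_at_death": r.age_at_death, "sex": r.sex, "region": r.region,
            "cluster_id": r.cluster_id, "survey_weight": r.survey_weight,
            "pregnancy_duration": "" if r.pregnancy_duration is None else r.pregnancy_duration,
            "illness_onset_day": "" if r.illness_onset_day is None else r.illness_onset_day,
        }
        for k in sign_keys:
            if k not in r.signs:
                row["sign__" + k] = "-"   # question not asked of this record
                row["dur__" + k] = ""
                row["ord__" + k] = ""
                continue
            s = r.signs[k]
            row["sign__" + k] = _TRI_OUT[s.present]
            row["dur__" + k] = "" if s.duration is None else s.duration
            row["ord__" + k] = "" if s.onset_order is None else s.onset_order
        for k in m_keys:
            if k not in r.maternal_signs:
                row["msign__" + k] = "-"
                row["mdur__" + k] = ""
                continue
            s = r.maternal_signs[k]
            row["msign__" + k] = _TRI_OUT[s.present]
            row["mdur__" + k] = "" if s.duration is None else s.duration
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def validate_cohort(records: Iterable[VARecord]) -> ValidationReport:
    """Check cohort-level invariants and report (never raise) violations.

    Checks: age inside the age-group window (0-27 days for neonates,
    1-59 months for children), positive survey weight, no duration
    recorded for a sign that is not present, tri-state codes valid.
    """
    violations: list[Violation] = []
    n = 0
    for r in records:
        n += 1
        if r.age_group not in AGE_GROUPS:
            violations.append(Violation(r.death_id, "age_group",
                                        f"unknown age group {r.age_group!r}"))
        else:
            lo, hi = AGE_WINDOWS[r.age_group]
            if not lo <= r.age_at_death <= hi:
                unit = "days" if r.age_group == NEONATE else "months"
                violations.append(Violation(
                    r.death_id, "age_at_death",
                    f"{r.age_at_death} {unit} outside [{lo}, {hi}] for {r.age_group}"))
        if not r.survey_weight > 0:
            violations.append(Violation(r.death_id, "survey_weight",
                                        f"nonpositive weight {r.survey_weight}"))
        for scope, mapping in (("sign", r.signs), ("maternal_sign", r.maternal_signs)):
            for key, s in mapping.items():
                if s.duration is not None and s.present != "yes":
                    violations.append(Violation(
                        r.death_id, f"{scope}:{key}",
                        f"duration {s.duration} recorded but present={s.present}"))
    return ValidationReport(n, violations)
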