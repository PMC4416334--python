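"""Physician-certified VA (PCVA) death certificates.

A certificate carries part 1, the causal chain on lines 1a-1d (1a the
direct cause, each lower line the antecedent of the one above), and
part 2, the contributing causes.  For neonatal deaths the physician may
also certify maternal causes; maternal part-1 entries always sit below
every child entry.  The underlying cause of death is the lowest child
entry of part 1 and the underlying maternal cause the lowest maternal
entry.

The combined 'physician cause' set — the deduplicated union of all
direct, antecedent and contributing child causes — feeds the agreement
analysis against the combined algorithmic causes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .records import VARecord
from .rules import RuleSet

PART1_LINES = ("1a", "1b", "1c", "1d")


class CertificateError(ValueError):
    pass


@dataclass(frozen=True)
class CertLine:
    cause: str
    maternal: bool = False


@dataclass
class DeathCertificate:
    """Part-1 causal chain (ordered, 1a first) plus part-2 contributors."""

    death_id: str
    part1: list[CertLine]
    part2_child: set[str] = field(default_factory=set)
    part2_maternal: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.part1 or not self.part1[0].cause:
            raise CertificateError(f"{self.death_id}: line 1a must be completed")
        if len(self.part1) > len(PART1_LINES):
            raise CertificateError(f"{self.death_id}: more than 4 part-1 lines")
        seen_maternal = False
        for line in self.part1:
            if line.maternal:
                seen_maternal = True
            elif seen_maternal:
                raise CertificateError(
                    f"{self.death_id}: maternal part-1 entry above a child entry")

    @property
    def child_lines(self) -> list[CertLine]:
        return [ln for ln in self.part1 if not ln.maternal]

    @property
    def maternal_lines(self) -> list[CertLine]:
        return [ln for ln in self.part1 if ln.maternal]


@dataclass
class PhysicianAssignment:
    """Extracted causes for one certificate."""

    death_id: str
    underlying: str
    chain: list[str]                  # part-1 child causes, 1a downward
    contributing: set[str]
    underlying_maternal: str | None = None
    contributing_maternal: set[str] = field(default_factory=set)

    @property
    def combined(self) -> frozenset[str]:
        """Combined 'physician cause' set: direct + antecedent + contributing."""
        return frozenset(self.chain) | frozenset(self.contributing)


def underlying_cause(cert: DeathCertificate) -> tuple[str, str | None]:
    """The underlying (child) cause and, if certified, the underlying
    maternal cause: each the *lowest* entry of its kind in part 1."""
    child = cert.child_lines
    if not child:
        raise CertificateError(f"{cert.death_id}: no child cause in part 1")
    maternal = cert.maternal_lines
    return child[-1].cause, maternal[-1].cause if maternal else None


def combined_physician_cause(cert: DeathCertificate) -> frozenset[str]:
    """Deduplicated union of part-1 child causes and part-2 child
    contributors (order-invariant, idempotent)."""
    return frozenset(ln.cause for ln in cert.child_lines) | frozenset(cert.part2_child)


def extract_assignment(cert: DeathCertificate) -> PhysicianAssignment:
    under, under_m = underlying_cause(cert)
    return PhysicianAssignment(
        death_id=cert.death_id,
        underlying=under,
        chain=[ln.cause for ln in cert.child_lines],
        contributing=set(cert.part2_child),
        underlying_maternal=under_m,
        contributing_maternal=set(cert.part2_maternal),
    )


# ---------------------------------------------------------------------------
# minimal-diagnostic-criteria audit


@dataclass
class CauseAudit:
    death_id: str
    cause: str
    status: str  # satisfied | not_satisfied | uncheckable


@dataclass
class AuditReport:
    audits: list[CauseAudit]

    def counts(self) -> pd.DataFrame:
        """Per-cause counts of satisfied / not_satisfied / uncheckable."""
        df = pd.DataFrame([(a.cause, a.status) for a in self.audits],
                          columns=["cause", "status"])
        if df.empty:
            return pd.DataFrame(columns=["satisfied", "not_satisfied", "uncheckable"])
        return (df.groupby(["cause", "status"]).size().unstack(fill_value=0)
                .reindex(columns=["satisfied", "not_satisfied", "uncheckable"],
                         fill_value=0))


def audit_minimum_criteria(certs: Iterable[DeathCertificate],
                           records: Iterable[VARecord],
                           ruleset: RuleSet) -> AuditReport:
    """Check every certified cause against its configured minimal
    diagnostic floor on the matching interview record.

    Causes without configured criteria are reported ``uncheckable``.
    """
    by_id = {r.death_id: r for r in records}
    audits: list[CauseAudit] = []
    for cert in certs:
        record = by_id.get(cert.death_id)
        if record is None:
            raise CertificateError(
                f"certificate {cert.death_id} has no matching record")
        for cause in sorted(combined_physician_cause(cert)):
            crit = ruleset.minimum_criteria.get(cause)
            if crit is None:
                status = "uncheckable"
            else:
                status = "satisfied" if crit(record) else "not_satisfied"
            audits.append(CauseAudit(cert.death_id, cause, status))
    return AuditReport(audits)


# ---------------------------------------------------------------------------
# file I/O — CSV with explicit line labels, or JSON mirror


def read_certificates(path: str | Path) -> list[DeathCertificate]:
    """Read certificates from CSV (columns: death_id, line, cause,
    maternal) or JSON ({death_id, part1: [{cause, maternal}], part2_child,
    part2_maternal})."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        return [_cert_from_json(obj) for obj in payload]
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    certs = []
    for death_id, grp in df.groupby("death_id", sort=False):
        part1, p2c, p2m = [], set(), set()
        grp = grp.assign(_order=grp["line"].map(
            {ln: i for i, ln in enumerate(PART1_LINES)}).fillna(99))
        for _, row in grp.sort_values("_order", kind="stable").iterrows():
            maternal = str(row.get("maternal", "")).strip().lower() in ("1", "y", "yes", "true")
            if row["line"] in PART1_LINES:
                part1.append(CertLine(row["cause"], maternal))
            elif row["line"] == "2":
                (p2m if maternal else p2c).add(row["cause"])
            else:
                raise CertificateError(
                    f"{death_id}: unknown certificate line {row['line']!r}")
        certs.append(DeathCertificate(str(death_id), part1, p2c, p2m))
    return certs


def _cert_from_json(obj: Mapping) -> DeathCertificate:
    part1 = [CertLine(ln["cause"], bool(ln.get("maternal", False)))
             for ln in obj["part1"]]
    return DeathCertificate(str(obj["death_id"]), part1,
                            set(obj.get("part2_child", [])),
                            set(obj.get("part2_maternal", [])))


def write_certificates(certs: Iterable[DeathCertificate], path: str | Path) -> None:
    path = Path(path)
    certs = list(certs)
    if path.suffix.lower() == ".json":
        payload = [{
            "death_id": c.death_id,
            "part1": [{"cause": ln.cause, "maternal": ln.maternal} for ln in c.part1],
            "part2_child": sorted(c.part2_child),
            "part2_maternal": sorted(c.part2_maternal),
        } for c in certs]
        path.write_text(json.dumps(payload, indent=1))
        return
    rows = []
    for c in certs:
        for i, ln in enumerate(c.part1):
            rows.append({"death_id": c.death_id, "line": PART1_LINES[i],
                         "cause": ln.cause, "maternal": int(ln.maternal)})
        for cause in sorted(c.part2_child):
            rows.append({"death_id": c.death_id, "line": "2", "cause": cause,
                         "maternal": 0})
        for cause in sorted(c.part2_maternal):
            rows.append({"death_id": c.death_id, "line": "2", "cause": cause,
                         "maternal": 1})
    pd.DataFrame(rows).to_csv(path, index=False)
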