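"""End-to-end run orchestration: classify → tabulate → compare → plausibility.

``run`` consumes a :class:`RunConfig`, executes every stage whose
inputs are present, writes tidy CSV tables (cause distributions,
EAVA-vs-PCVA comparison, agreement, onset association, regional
meningitis) plus a JSON manifest with the rule-set version, seed,
cohort counts and a content hash per output file.  Stages whose inputs
are missing are skipped with a warning recorded in the manifest, and
repeated runs on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .certificates import extract_assignment, read_certificates
from .classify import classify_cohort, maternal_infection
from .records import CHILD, NEONATE, SurveillanceTable, read_records, validate_cohort
from .rules import UNSPECIFIED, default_ruleset, load_ruleset
from .plausibility import onset_association, onset_association_frame, regional_meningitis
from .stats import agreement_table, cohen_kappa, rank_comparison, two_prop_chi2, weighted_csmf

log = logging.getLogger("vasakit")


@dataclass
class RunConfig:
    records_path: str
    out_dir: str
    certificates_path: str | None = None
    surveillance_path: str | None = None
    neonate_ruleset_path: str | None = None
    child_ruleset_path: str | None = None
    seed: int = 0
    fmt: str = "csv"  # csv | json
    make_figures: bool = False


@dataclass
class RunResult:
    manifest: dict
    outputs: dict[str, Path] = field(default_factory=dict)


def _write(df: pd.DataFrame, path: Path, fmt: str) -> None:
    if fmt == "json":
        path = path.with_suffix(".json")
        path.write_text(df.to_json(orient="table", indent=1))
    else:
        df.to_csv(path)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run(config: RunConfig) -> RunResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"vasakit_version": __version__, "seed": config.seed,
                      "warnings": [], "stages": [], "files": {}}

    rulesets = {
        NEONATE: (load_ruleset(config.neonate_ruleset_path)
                  if config.neonate_ruleset_path else default_ruleset(NEONATE)),
        CHILD: (load_ruleset(config.child_ruleset_path)
                if config.child_ruleset_path else default_ruleset(CHILD)),
    }
    manifest["rulesets"] = {g: f"{rs.ruleset_id}@{rs.version}"
                            for g, rs in rulesets.items()}

    records = read_records(config.records_path)
    report = validate_cohort(records)
    manifest["n_records"] = report.n_records
    manifest["n_validation_violations"] = len(report.violations)
    if not report.ok:
        manifest["warnings"].append(report.summary())

    by_group = {g: [r for r in records if r.age_group == g]
                for g in (NEONATE, CHILD)}
    manifest["counts"] = {g: len(rs) for g, rs in by_group.items()}

    outputs: dict[str, Path] = {}

    def emit(name: str, df: pd.DataFrame) -> None:
        path = out / f"{name}.{config.fmt}"
        _write(df, path, config.fmt)
        actual = path if config.fmt == "csv" else path.with_suffix(".json")
        outputs[name] = actual

    # --- classify + tabulate ------------------------------------------------
    assignments: dict[str, dict] = {}
    dists = {}
    for group, recs in by_group.items():
        if not recs:
            manifest["warnings"].append(f"no {group} records; tables skipped")
            continue
        ruleset = rulesets[group]
        assigned = classify_cohort(recs, ruleset)
        assignments[group] = {a.death_id: a for a in assigned}
        rows = pd.DataFrame(
            [{"death_id": a.death_id, "primary": a.primary,
              "reporting_cause": a.reporting_cause,
              "comorbid": ";".join(a.comorbid), "ruleset": a.ruleset_id}
             for a in assigned]).set_index("death_id")
        emit(f"eava_assignments_{group}", rows)
        dist = weighted_csmf(recs, assignments[group],
                             cause_of=lambda a: a.reporting_cause)
        dists[group] = dist
        emit(f"cause_distribution_eava_{group}", dist.table)
        manifest["stages"].append(f"classify:{group}")

    # --- PCVA + comparison --------------------------------------------------
    if config.certificates_path:
        certs = read_certificates(config.certificates_path)
        phys = {c.death_id: extract_assignment(c) for c in certs}
        for group, recs in by_group.items():
            if not recs or group not in assignments:
                continue
            sub = [r for r in recs if r.death_id in phys]
            skipped = len(recs) - len(sub)
            if skipped:
                manifest["warnings"].append(
                    f"{skipped} {group} records without certificates")
            if not sub:
                continue
            ruleset = rulesets[group]
            pdist = weighted_csmf(sub, {i: phys[i].underlying for i in phys
                                        if i in {r.death_id for r in sub}})
            emit(f"cause_distribution_pcva_{group}", pdist.table)
            edist = dists[group]
            causes = [c for c in edist.table.index if c != UNSPECIFIED]
            comp_rows = []
            n1 = edist.n_total
            n2 = pdist.n_total
            for cause in causes:
                x1 = edist.count(cause)
                x2 = pdist.count(cause) if cause in pdist.table.index else 0
                t = two_prop_chi2(x1, n1, x2, n2, label=cause)
                comp_rows.append({"cause": cause,
                                  "eava_pct": edist.percent(cause),
                                  "pcva_pct": (pdist.percent(cause)
                                               if cause in pdist.table.index else 0.0),
                                  "chi2": t.statistic, "p": t.p_value})
            emit(f"comparison_{group}", pd.DataFrame(comp_rows).set_index("cause"))
            emit(f"rank_comparison_{group}", rank_comparison(edist, pdist))

            ids = [r.death_id for r in sub]
            sets1 = {i: assignments[group][i].combined_reporting(ruleset) for i in ids}
            sets2 = {i: phys[i].combined for i in ids}
            agree_rows = []
            all_causes = sorted({c for s in sets1.values() for c in s}
                                | {c for s in sets2.values() for c in s})
            for cause in all_causes:
                a, b, c_, d = agreement_table(sets1, sets2, cause)
                try:
                    res = cohen_kappa(a, b, c_, d)
                    agree_rows.append({"cause": cause, "a": a, "b": b, "c": c_,
                                       "d": d, "kappa": res.kappa,
                                       "ci_low": res.ci_low, "ci_high": res.ci_high,
                                       "grade": res.grade})
                except ValueError:
                    manifest["warnings"].append(f"degenerate kappa table for {cause}")
            emit(f"agreement_{group}", pd.DataFrame(agree_rows).set_index("cause"))
            manifest["stages"].append(f"compare:{group}")
    else:
        manifest["warnings"].append(
            "no certificates supplied; comparison stages skipped")

    # --- plausibility -------------------------------------------------------
    neo = by_group[NEONATE]
    if neo and NEONATE in assignments:
        ruleset = rulesets[NEONATE]
        if ruleset.maternal_rule is not None:
            flags = {r.death_id: maternal_infection(r, ruleset.maternal_rule)
                     for r in neo}
            assoc = onset_association(neo, assignments[NEONATE], flags)
            emit("onset_association", onset_association_frame(assoc).set_index("group"))
            manifest["stages"].append("plausibility:onset")
    if config.surveillance_path and CHILD in assignments:
        surv = SurveillanceTable.read_csv(config.surveillance_path)
        comp = regional_meningitis(by_group[CHILD], assignments[CHILD], surv)
        emit("regional_meningitis", comp.table)
        manifest["spearman_cases_eava"] = comp.spearman_cases_eava
        if config.make_figures:
            from .plausibility import plot_regional_comparison
            fig_path = out / "regional_meningitis.png"
            plot_regional_comparison(comp, str(fig_path))
            outputs["regional_meningitis_figure"] = fig_path
        manifest["stages"].append("plausibility:regional")
    elif not config.surveillance_path:
        manifest["warnings"].append(
            "no surveillance table supplied; regional stage skipped")

    manifest["files"] = {name: {"path": str(p), "sha256": _sha256(p)}
                         for name, p in outputs.items()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return RunResult(manifest, outputs)
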