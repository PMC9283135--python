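"""End-to-end study replication: adjust, classify, adjudicate, tabulate, ROC.

`run_study` executes, per normative dataset: demographic adjustment ->
impaired/normal classification -> impairment rates; then PSCI adjudication
on the follow-up assessments; baseline comparisons between followed and
drop-out patients; adjusted-score comparisons by outcome group; accuracy
of the ES=0 normality thresholds against PSCI; and the ROC analysis with
the screening-adequate optimal cut-off. `write_report` persists the
result as a CSV bundle plus a Markdown summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.stats

from . import __version__
from .adjudication import FollowUpAssessment, PsciDiagnosis, adjudicate, outcome_table
from .diagnostics import (
    ContingencyTable2x2,
    GroupComparison,
    LogisticRiskFit,
    accuracy_indices,
    build_contingency,
    compare_groups,
    fit_logistic,
    format_p,
    pearson_chi2,
    proportion,
)
from .io import read_baseline_csv, read_followup_csvs, validate_inputs
from .norms import NORMATIVE_DATASETS, PatientRecord, adjust_cohort
from .roc import CutpointResult, RocCurve, roc_points, select_optimal, threshold_table

__all__ = ["DatasetResult", "StudyReport", "run_study", "run_study_from_csv", "write_report"]

logger = logging.getLogger(__name__)

ALL_DATASETS = ("conti", "santangelo", "aiello")


@dataclass
class DatasetResult:
    """Everything the study computes under one normative dataset."""

    dataset: str
    n_scored: int
    n_impaired: int
    impairment_pct: float
    table: ContingencyTable2x2 | None = None
    chi2_p: float | None = None
    accuracy_pct: dict | None = None
    psci_comparison: GroupComparison | None = None
    anova_f: float | None = None
    anova_p: float | None = None
    group_means: dict | None = None
    logistic: LogisticRiskFit | None = None
    curve: RocCurve | None = None
    optimal: CutpointResult | None = None


@dataclass
class StudyReport:
    n_baseline: int
    n_followed: int
    n_dropout: int
    cohort_summary: pd.DataFrame
    outcome_counts: dict
    datasets: dict[str, DatasetResult]
    metadata: dict = field(default_factory=dict)


def _cohort_summary(
    followed: list[PatientRecord], dropouts: list[PatientRecord]
) -> pd.DataFrame:
    """Followed vs drop-out baseline comparison (the attrition-bias check)."""
    rows = []

    def add(variable: str, get, kind: str) -> None:
        a = [get(r) for r in followed if get(r) is not None]
        b = [get(r) for r in dropouts if get(r) is not None]
        if not a or not b:
            return
        cmp = compare_groups(a, b, variable=variable, kind=kind)
        rows.append({"variable": variable, "followup": cmp.summary_a,
                     "dropout": cmp.summary_b, "p": cmp.p, "p_rendered": format_p(cmp.p)})

    add("age_years", lambda r: r.age, "t")
    add("female", lambda r: float(r.sex == "female"), "chi2")
    add("education_years", lambda r: r.education_years, "t")
    add("nihss", lambda r: r.nihss, "t")
    add("moca_raw", lambda r: r.moca_raw, "t")
    for name in ALL_DATASETS:
        a = adjust_cohort(followed, name) if any(r.moca_raw is not None for r in followed) else []
        b = adjust_cohort(dropouts, name) if any(r.moca_raw is not None for r in dropouts) else []
        if a and b:
            cmp = compare_groups(
                [float(s.performance == "impaired") for s in a],
                [float(s.performance == "impaired") for s in b],
                variable=f"impaired_{name}", kind="chi2",
            )
            rows.append({"variable": f"impaired_{name}", "followup": cmp.summary_a,
                         "dropout": cmp.summary_b, "p": cmp.p, "p_rendered": format_p(cmp.p)})
    return pd.DataFrame(rows, columns=["variable", "followup", "dropout", "p", "p_rendered"])


def run_study(
    records: Sequence[PatientRecord],
    assessments: Sequence[FollowUpAssessment],
    datasets: Sequence[str] = ALL_DATASETS,
    exclude_tia: bool = False,
    min_education: float = 1.0,
    metadata: dict | None = None,
) -> StudyReport:
    """Run the full analysis on an in-memory cohort.

    Patients without a baseline MoCA stay in the cohort description but are
    excluded from every score analysis (logged). With ``exclude_tia`` the
    TIA subgroup is removed from every denominator.
    """
    records = list(records)
    if not records:
        raise ValueError("empty cohort")
    if exclude_tia:
        n_tia = sum(r.event_type == "TIA" for r in records)
        records = [r for r in records if r.event_type != "TIA"]
        logger.info("excluded %d TIA patients", n_tia)
        if not records:
            raise ValueError("no patients left after TIA exclusion")
    if all(r.moca_raw is None for r in records):
        raise ValueError("no patient has a baseline MoCA score")

    diagnoses = {a.patient_id: adjudicate(a) for a in assessments}
    ids = {r.id for r in records}
    diagnoses = {pid: d for pid, d in diagnoses.items() if pid in ids}
    followed = [r for r in records if r.followed_up]
    dropouts = [r for r in records if not r.followed_up]
    if not diagnoses:
        raise ValueError("no followed-up patient has an adjudicated outcome")
    counts = outcome_table(list(diagnoses.values()))

    results: dict[str, DatasetResult] = {}
    for name in datasets:
        scores = adjust_cohort(records, name, min_education=min_education)
        n_imp = sum(s.performance == "impaired" for s in scores)
        res = DatasetResult(
            dataset=name, n_scored=len(scores), n_impaired=n_imp,
            impairment_pct=proportion(n_imp, len(scores), 1),
        )

        # analysis set: followed-up, scored, adjudicated
        pairs = [(s, diagnoses[s.patient_id]) for s in scores if s.patient_id in diagnoses]
        if len(pairs) >= 4:
            perfs = [s.performance for s, _ in pairs]
            outcomes = [d.psci for _, d in pairs]
            values = [s.value for s, _ in pairs]
            if any(outcomes) and not all(outcomes):
                res.table = build_contingency(perfs, outcomes)
                try:
                    _, res.chi2_p = pearson_chi2(res.table)
                except ValueError:
                    res.chi2_p = None
                res.accuracy_pct = accuracy_indices(res.table).as_percents()
                res.psci_comparison = compare_groups(
                    [v for v, o in zip(values, outcomes) if not o],
                    [v for v, o in zip(values, outcomes) if o],
                    variable=f"adjusted_{name}", kind="t",
                )
                groups = {
                    cat: [s.value for s, d in pairs if d.category == cat]
                    for cat in ("none", "mci", "dementia")
                }
                res.group_means = {
                    cat: (float(np.mean(v)), float(np.std(v, ddof=1)) if len(v) > 1 else 0.0)
                    for cat, v in groups.items() if v
                }
                if all(len(v) >= 2 for v in groups.values()):
                    f, p = scipy.stats.f_oneway(*groups.values())
                    res.anova_f, res.anova_p = float(f), float(p)
                if len(pairs) >= 10:
                    res.logistic = fit_logistic(values, outcomes)
                res.curve = roc_points(values, outcomes, dataset=name)
                res.optimal = select_optimal(res.curve)
        results[name] = res

    meta = dict(metadata or {})
    meta.setdefault("package_version", __version__)
    meta["n_records"] = len(records)
    meta["exclude_tia"] = exclude_tia
    meta["datasets"] = list(datasets)
    meta["config_hash"] = hashlib.sha256(
        json.dumps(meta, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]

    return StudyReport(
        n_baseline=len(records),
        n_followed=len(followed),
        n_dropout=len(dropouts),
        cohort_summary=_cohort_summary(followed, dropouts) if followed and dropouts
        else pd.DataFrame(),
        outcome_counts=counts,
        datasets=results,
        metadata=meta,
    )


def run_study_from_csv(
    baseline_csv: str | Path,
    followup_csv: str | Path,
    functional_csv: str | Path,
    **kwargs,
) -> StudyReport:
    """Validate and load the three CSVs, then run the study."""
    report = validate_inputs(baseline_csv, followup_csv, functional_csv)
    for w in report.warnings:
        logger.warning("%s row %s [%s]: %s", w.file, w.row, w.column, w.message)
    if not report.ok:
        msgs = "\n  ".join(
            f"{e.file} row {e.row} [{e.column}]: {e.message}" for e in report.errors
        )
        raise ValueError(f"input validation failed:\n  {msgs}")
    records = read_baseline_csv(baseline_csv)
    assessments = read_followup_csvs(followup_csv, functional_csv)
    return run_study(records, assessments, **kwargs)


def write_report(report: StudyReport, outdir: str | Path) -> None:
    """Persist the study report as CSV tables, a Markdown summary and meta.json."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)

    report.cohort_summary.to_csv(out / "table2.csv", index=False, encoding="utf-8")

    t3_rows, t4_rows = [], []
    for name, res in report.datasets.items():
        if res.group_means:
            row = {"dataset": name}
            for cat in ("none", "mci", "dementia"):
                if cat in res.group_means:
                    m, sd = res.group_means[cat]
                    row[cat] = f"{m:.1f} ± {sd:.1f}"
            if res.psci_comparison:
                row["p_psci_vs_no"] = format_p(res.psci_comparison.p)
            if res.anova_p is not None:
                row["p_anova"] = format_p(res.anova_p)
            t3_rows.append(row)
        if res.table is not None:
            acc = res.accuracy_pct or {}
            t4_rows.append({
                "dataset": name, "tp": res.table.tp, "fp": res.table.fp,
                "fn": res.table.fn, "tn": res.table.tn,
                "p": format_p(res.chi2_p) if res.chi2_p is not None else "",
                "se_pct": acc.get("sensitivity"), "sp_pct": acc.get("specificity"),
                "ppv_pct": acc.get("ppv"), "npv_pct": acc.get("npv"),
            })
        if res.curve is not None:
            threshold_table(res.curve).to_csv(out / f"table5_{name}.csv",
                                              index=False, encoding="utf-8")
            pd.DataFrame([{
                "threshold": p.threshold, "sensitivity": p.sensitivity,
                "specificity": p.specificity,
            } for p in res.curve.points]).to_csv(out / f"roc_{name}.csv",
                                                 index=False, encoding="utf-8")
    pd.DataFrame(t3_rows).to_csv(out / "table3.csv", index=False, encoding="utf-8")
    pd.DataFrame(t4_rows).to_csv(out / "table4.csv", index=False, encoding="utf-8")

    (out / "meta.json").write_text(
        json.dumps(report.metadata, indent=2, sort_keys=True, default=str), "utf-8"
    )

    lines = [
        "# Study report",
        "",
        f"Baseline cohort n = {report.n_baseline}; followed up n = {report.n_followed} "
        f"({proportion(report.n_followed, report.n_baseline):.0f}%); "
        f"drop-outs n = {report.n_dropout}.",
        "",
        f"Outcome among followed: {report.outcome_counts['none']} no PSCI, "
        f"{report.outcome_counts['mci']} MCI, {report.outcome_counts['dementia']} dementia.",
        "",
        "| dataset | impaired at baseline | Se% | Sp% | PPV% | NPV% | AUC | optimal cut-off | Se/Sp at cut-off | adequate |",
        "|---|---|---|---|---|---|---|---|---|---|",
    ]
    for name, res in report.datasets.items():
        acc = res.accuracy_pct or {}
        cells = [
            name,
            f"{res.n_impaired}/{res.n_scored} ({res.impairment_pct}%)",
            acc.get("sensitivity", ""), acc.get("specificity", ""),
            acc.get("ppv", ""), acc.get("npv", ""),
        ]
        if res.curve is not None and res.optimal is not None:
            opt = res.optimal
            cells += [f"{res.curve.auc:.3f}", f"{opt.threshold:.2f}",
                      f"{100 * opt.sensitivity:.0f}/{100 * opt.specificity:.0f}",
                      str(opt.adequate)]
        else:
            cells += ["", "", "", ""]
        lines.append("| " + " | ".join(str(c) for c in cells) + " |")
    (out / "report.md").write_text("\n".join(lines) + "\n", "utf-8")
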