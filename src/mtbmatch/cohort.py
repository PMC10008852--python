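"""Cohort-level aggregation of per-case virtual-MTB reports.

Two totals are first-class throughout: *cataloged* recommendations (every
annotated option, including those later struck by the RNA-based
exclusion) and *active* recommendations (after exclusion).  Evidence-tier
and basket distributions are reported over both sets, because published
tallies mix the two conventions.  Medians use the mean-of-central-pair
convention for even-length lists.
"""

from __future__ import annotations

import dataclasses
import json
import statistics
from pathlib import Path
from typing import Sequence

from .engine import CaseReport
from .evidence import Basket, EscatTier, EvidenceLevelNCT


@dataclasses.dataclass
class CohortSummary:
    n_cases: int
    total_recommendations_active: int
    total_cataloged: int
    per_case_counts: list            # active recommendations per case
    per_case_mms: list               # defined scores only
    n_mms_undefined: int
    counts_by_nct: dict              # cataloged
    counts_by_nct_active: dict
    counts_by_escat: dict            # cataloged (pre-exclusion)
    counts_by_escat_active: dict
    counts_by_basket: dict           # cataloged (pre-exclusion)
    counts_by_basket_active: dict
    counts_by_drug: dict             # active, per drug label
    n_mms_ge_50: int
    mms_median: float
    mms_min: int
    mms_max: int
    median_recommendations: float
    recommendations_range: tuple

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["recommendations_range"] = list(self.recommendations_range)
        return payload


def _median(values: Sequence[float]) -> float:
    """Mean of the central pair for even n."""
    return float(statistics.median(values))


def _zero_counts(enum_cls) -> dict:
    return {member.value: 0 for member in enum_cls}


def summarize_cohort(reports: Sequence[CaseReport]) -> CohortSummary:
    """Aggregate case reports into the cohort summary.

    Distributions include zero-count categories so downstream tables are
    stable across cohorts; the result is invariant to case order.
    """
    if not reports:
        raise ValueError("summarize_cohort requires at least one report")
    reports = sorted(reports, key=lambda r: str(r.case_id))
    by_nct = _zero_counts(EvidenceLevelNCT)
    by_nct_active = _zero_counts(EvidenceLevelNCT)
    by_escat = _zero_counts(EscatTier)
    by_escat_active = _zero_counts(EscatTier)
    by_basket = _zero_counts(Basket)
    by_basket_active = _zero_counts(Basket)
    by_drug: dict = {}
    per_case_counts = []
    mms_values = []
    n_undefined = 0
    total_cataloged = 0
    for report in reports:
        per_case_counts.append(len(report.active_recommendations))
        if report.mms is None:
            n_undefined += 1
        else:
            mms_values.append(report.mms)
        for rec in report.recommendations:
            total_cataloged += 1
            by_nct[rec.nct_level.value] += 1
            by_escat[rec.escat_tier.value] += 1
            by_basket[rec.basket.value] += 1
            if not rec.excluded:
                by_nct_active[rec.nct_level.value] += 1
                by_escat_active[rec.escat_tier.value] += 1
                by_basket_active[rec.basket.value] += 1
                by_drug[rec.drug_label] = by_drug.get(rec.drug_label, 0) + 1
    mms_dist = mms_distribution(reports)
    return CohortSummary(
        n_cases=len(reports),
        total_recommendations_active=sum(per_case_counts),
        total_cataloged=total_cataloged,
        per_case_counts=per_case_counts,
        per_case_mms=mms_values,
        n_mms_undefined=n_undefined,
        counts_by_nct=by_nct,
        counts_by_nct_active=by_nct_active,
        counts_by_escat=by_escat,
        counts_by_escat_active=by_escat_active,
        counts_by_basket=by_basket,
        counts_by_basket_active=by_basket_active,
        counts_by_drug=dict(sorted(by_drug.items())),
        n_mms_ge_50=mms_dist[3],
        mms_median=mms_dist[0],
        mms_min=mms_dist[1],
        mms_max=mms_dist[2],
        median_recommendations=_median(per_case_counts),
        recommendations_range=(min(per_case_counts), max(per_case_counts)),
    )


def mms_distribution(reports: Sequence[CaseReport]) -> tuple:
    """(median, min, max, count >= 50) over defined matching scores.

    Reports with an undefined score are excluded with a warning count;
    the >= 50 threshold is inclusive.
    """
    values = [r.mms for r in reports if r.mms is not None]
    if not values:
        raise ValueError("no defined matching scores in cohort")
    return (_median(values), min(values), max(values),
            sum(1 for v in values if v >= 50))


def write_cohort_report(summary: CohortSummary, path,
                        fmt: str = "JSON",
                        reports: Sequence[CaseReport] = ()) -> Path:
    """Deterministic serialization (sorted JSON keys or a markdown table)."""
    path = Path(path)
    if fmt.upper() == "JSON":
        path.write_text(json.dumps(summary.to_dict(), indent=2,
                                   sort_keys=True) + "\n")
    elif fmt.upper() == "MD":
        lines = ["# Cohort summary — virtual MTB recommendations", ""]
        lines.append(f"Cases: {summary.n_cases}; active recommendations: "
                     f"{summary.total_recommendations_active} "
                     f"(cataloged: {summary.total_cataloged}); median per "
                     f"case: {summary.median_recommendations:g} (range "
                     f"{summary.recommendations_range[0]}-"
                     f"{summary.recommendations_range[1]})")
        lines.append(f"mMS: median {summary.mms_median:g}%, range "
                     f"{summary.mms_min}-{summary.mms_max}%, "
                     f">=50% in {summary.n_mms_ge_50} cases")
        lines.append("")
        if reports:
            lines.append("| Case | Target | Drug | NCT/DKTK | ESCAT | "
                         "Approval | Basket | mMS | Status |")
            lines.append("|---|---|---|---|---|---|---|---|---|")
            for report in sorted(reports, key=lambda r: str(r.case_id)):
                first = True
                for rec in report.recommendations:
                    mms = (f"{report.mms}%" if report.mms is not None
                           else "undefined") if first else ""
                    case_cell = report.case_id if first else ""
                    status = ("excluded: " + rec.exclusion_reason
                              if rec.excluded else "active")
                    lines.append(
                        f"| {case_cell} | {rec.target_id} | {rec.drug_label} "
                        f"| {rec.nct_level.value} | {rec.escat_tier.value} | "
                        f"{'/'.join(sorted(a.value for a in rec.approval))} | "
                        f"{rec.basket.value} | {mms} | {status} |")
                    first = False
        nonzero = {k: v for k, v in summary.counts_by_escat.items() if v}
        lines += ["", "Cataloged ESCAT distribution: "
                  + ", ".join(f"{k}={v}" for k, v in sorted(nonzero.items()))]
        nonzero = {k: v for k, v in summary.counts_by_basket.items() if v}
        lines += ["Cataloged basket distribution: "
                  + ", ".join(f"{k}={v}" for k, v in sorted(nonzero.items()))]
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path
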