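"""End-to-end pipeline over on-disk case bundles.

A *case bundle* is a directory holding ``variants.tsv`` (or ``.vcf``),
``ihc.tsv`` (marker/status pairs), optional ``catalog.tsv`` (96-context
counts), optional ``biomarkers.json`` (precomputed panel overriding the
catalog), and optional ``clinical.json`` (pass-through fields, optional
MSI score, optional audit (x, y) for the matching score).  A cohort
directory contains one bundle per case plus an optional shared
``expression.tsv``.  Outputs are deterministic: per-case ``report.json``
and ``report.md`` plus a cohort ``summary.json``/``summary.md``.
"""

from __future__ import annotations

import csv
import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .biomarkers import BiomarkerPanel, MutationCatalog
from .cohort import CohortSummary, summarize_cohort, write_cohort_report
from .config import PipelineConfig
from .engine import (
    CaseProfile,
    CaseReport,
    IHCPanel,
    MatchingScoreInput,
    run_case,
)
from .kb import KnowledgeBase, load_knowledge_base
from .transcriptome import ExpressionMatrix
from .variants import read_variants, write_variants_tsv

logger = logging.getLogger(__name__)


def write_bundle(profile: CaseProfile, directory) -> Path:
    """Serialize one case profile as a bundle directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_variants_tsv(profile.variants, directory / "variants.tsv")
    with (directory / "ihc.tsv").open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["marker", "status"])
        for marker, status in profile.ihc.statuses:
            writer.writerow([marker, status.value])
    clinical = dict(profile.clinical)
    clinical["case_id"] = profile.case_id
    if profile.msi_score is not None:
        clinical["msi_score"] = profile.msi_score
    if profile.mms_audit is not None:
        clinical["mms_audit"] = {"x": profile.mms_audit.x,
                                 "y": profile.mms_audit.y,
                                 "note": profile.mms_audit_note}
    (directory / "clinical.json").write_text(
        json.dumps(clinical, indent=2, sort_keys=True) + "\n")
    if profile.biomarkers is not None:
        (directory / "biomarkers.json").write_text(
            json.dumps(dataclasses.asdict(profile.biomarkers),
                       indent=2, sort_keys=True) + "\n")
    if profile.catalog is not None:
        profile.catalog.to_series().to_csv(
            directory / "catalog.tsv", sep="\t")
    return directory


def read_bundle(directory) -> CaseProfile:
    directory = Path(directory)
    variants_path = directory / "variants.tsv"
    if not variants_path.exists():
        vcfs = sorted(directory.glob("*.vcf"))
        if not vcfs:
            raise FileNotFoundError(f"no variants file in {directory}")
        variants_path = vcfs[0]
    variants = read_variants(variants_path)
    ihc_map = {}
    with (directory / "ihc.tsv").open(newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            ihc_map[row["marker"]] = row["status"]
    clinical = {}
    clinical_path = directory / "clinical.json"
    if clinical_path.exists():
        clinical = json.loads(clinical_path.read_text())
    case_id = str(clinical.pop("case_id", directory.name))
    msi_score = clinical.pop("msi_score", None)
    audit = clinical.pop("mms_audit", None)
    mms_audit = None
    mms_note = ""
    if audit:
        mms_audit = MatchingScoreInput(x=int(audit["x"]), y=int(audit["y"]))
        mms_note = audit.get("note", "")
    biomarkers = None
    bm_path = directory / "biomarkers.json"
    if bm_path.exists():
        biomarkers = BiomarkerPanel(**json.loads(bm_path.read_text()))
    catalog = None
    cat_path = directory / "catalog.tsv"
    if cat_path.exists():
        series = pd.read_csv(cat_path, sep="\t", index_col=0).iloc[:, 0]
        catalog = MutationCatalog.from_series(series)
    return CaseProfile(
        case_id=case_id, variants=variants,
        ihc=IHCPanel.from_dict(ihc_map),
        biomarkers=biomarkers, catalog=catalog, msi_score=msi_score,
        clinical=clinical, mms_audit=mms_audit, mms_audit_note=mms_note,
    )


def run_pipeline(cases_dir,
                 kb_path,
                 out_dir=None,
                 config: Optional[PipelineConfig] = None) -> tuple:
    """Chain filter -> biomarkers -> expression check -> recommend -> cohort.

    Returns (reports, summary).  A single malformed bundle is skipped
    with an error report; a missing knowledge base is fatal.  Outputs
    are identical across reruns with identical inputs.
    """
    config = config or PipelineConfig()
    cases_dir = Path(cases_dir)
    kb = load_knowledge_base(kb_path)
    expression = None
    expr_path = cases_dir / "expression.tsv"
    if expr_path.exists():
        expression = ExpressionMatrix.read_tsv(expr_path)
    bundle_dirs = sorted(
        d for d in cases_dir.iterdir()
        if d.is_dir() and ((d / "variants.tsv").exists()
                           or list(d.glob("*.vcf"))))
    if not bundle_dirs:
        raise FileNotFoundError(f"no cases found under {cases_dir}")
    reports = []
    failures = []
    for bundle_dir in bundle_dirs:
        try:
            profile = read_bundle(bundle_dir)
            report = run_case(profile, kb, config, expression)
        except Exception as exc:  # malformed case: skip, keep going
            logger.error("case %s failed: %s", bundle_dir.name, exc)
            failures.append({"case": bundle_dir.name, "error": str(exc)})
            continue
        logger.info(
            "case %s: parsed=%d filtered=%d cataloged=%d active=%d excluded=%d",
            report.case_id, report.n_variants_input,
            report.n_variants_filtered, len(report.recommendations),
            len(report.active_recommendations), len(report.exclusions))
        reports.append(report)
    if not reports:
        raise RuntimeError("all cases failed")
    summary = summarize_cohort(reports)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for report in reports:
            case_dir = out_dir / f"case_{report.case_id}"
            case_dir.mkdir(exist_ok=True)
            (case_dir / "report.json").write_text(report.to_json() + "\n")
            (case_dir / "report.md").write_text(report.to_markdown())
        write_cohort_report(summary, out_dir / "summary.json", "JSON")
        write_cohort_report(summary, out_dir / "summary.md", "MD", reports)
        manifest = {
            "n_cases": len(reports),
            "failures": failures,
            "config": config.to_dict(),
            "kb": str(kb_path),
            "kb_entries": len(kb.entries),
        }
        (out_dir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return reports, summary


def run_profiles(profiles: Sequence[CaseProfile],
                 kb: KnowledgeBase,
                 config: Optional[PipelineConfig] = None,
                 expression: Optional[ExpressionMatrix] = None
                 ) -> tuple:
    """In-memory variant of :func:`run_pipeline`."""
    config = config or PipelineConfig()
    reports = [run_case(p, kb, config, expression) for p in profiles]
    return reports, summarize_cohort(reports)
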