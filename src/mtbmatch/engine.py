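"""The virtual-MTB recommendation engine.

Per-case decision procedure: derive therapeutic vulnerabilities from
filtered and classified mutations, positive IHC markers and genomic
biomarker flags; apply the exclusion rules (CDK4/6 inhibitors withheld
in TP53-mutant disease, no immunotherapy from an SBS26 mismatch-repair
signature alone, RNA-inconclusive candidates dropped); match each kept
vulnerability against the knowledge base, preferring the highest
NCT/DKTK evidence level; and compute the modified matching score

    mMS (%) = x / y * 100

with x = targetable vulnerabilities (a drug combination against one
aberration counts once) and y = characteristic and significant
alterations (targetable plus un-targetable at VAF >= 5%, variants of
unknown significance excluded, non-mutation vulnerabilities included),
reported as a round-half-up integer percent.

Recommendations come in two flavours: *cataloged* options (everything
annotated, including those later struck by the RNA-based exclusion) and
*active* options (cataloged minus RNA-based exclusions).  Cohort tallies
use both, because the evidence-tier distribution is taken over the
cataloged set while headline totals count active options only.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from typing import Optional, Sequence

from .biomarkers import BiomarkerPanel, biomarker_panel
from .config import PipelineConfig
from .evidence import (
    ApprovalStatus,
    Basket,
    EscatTier,
    EvidenceLevelNCT,
    approval_sort_key,
)
from .kb import GeneRole, KnowledgeBase, TargetModality, lookup
from .transcriptome import (
    Conclusiveness,
    ConclusivenessCall,
    ExpressionMatrix,
    conclusiveness_check,
)
from .variants import (
    ClassifiedVariant,
    FilterResult,
    Functionality,
    VariantGeneRole,
    VariantRecord,
    classify_variant,
    filter_somatic_variants,
)

# machine-readable exclusion reason codes
REASON_TP53_RESISTANCE = "TP53_RESISTANCE"
REASON_SBS26 = "SBS26_BIOLOGICAL_RATIONALE"
REASON_RNA_INCONCLUSIVE = "RNA_INCONCLUSIVE"


class IHCStatus(enum.Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"
    UNTESTED = "UNTESTED"


IHC_MARKERS = ("CD19", "CD30", "CD38", "CD79B")


@dataclasses.dataclass(frozen=True)
class IHCPanel:
    """Statuses of the four B-cell surface markers assessed by IHC."""

    statuses: tuple  # ordered (marker, IHCStatus) pairs

    @classmethod
    def from_dict(cls, mapping: dict) -> "IHCPanel":
        statuses = []
        for marker, status in mapping.items():
            if marker not in IHC_MARKERS:
                raise ValueError(f"unknown IHC marker {marker!r}")
            statuses.append((marker, IHCStatus(status) if
                             not isinstance(status, IHCStatus) else status))
        present = dict(statuses)
        full = tuple((m, present.get(m, IHCStatus.UNTESTED))
                     for m in IHC_MARKERS)
        return cls(statuses=full)

    def status(self, marker: str) -> IHCStatus:
        return dict(self.statuses)[marker]

    @property
    def positive_markers(self) -> list:
        return [m for m, s in self.statuses if s is IHCStatus.POSITIVE]

    def to_dict(self) -> dict:
        return {m: s.value for m, s in self.statuses}


@dataclasses.dataclass(frozen=True)
class TherapeuticVulnerability:
    source: TargetModality
    target_id: str
    supporting_variant: Optional[ClassifiedVariant] = None
    conclusiveness: Optional[ConclusivenessCall] = None
    flagged_for_exclusion: bool = False
    flag_reason: str = ""


@dataclasses.dataclass(frozen=True)
class MatchingScoreInput:
    x: int  # targetable vulnerabilities (combination = one)
    y: int  # characteristic and significant alterations

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError("x and y must be non-negative")
        if self.x > self.y:
            raise ValueError(f"x ({self.x}) cannot exceed y ({self.y})")


class UndefinedScoreError(ValueError):
    """mMS is undefined: no characteristic and significant alterations."""


def compute_mms(score_input: MatchingScoreInput) -> int:
    """Modified matching score as a round-half-up integer percent."""
    if score_input.y == 0:
        raise UndefinedScoreError(
            "mMS undefined: no characteristic and significant alterations")
    # round half up, immune to binary-float ties
    return int((200 * score_input.x + score_input.y) // (2 * score_input.y))


@dataclasses.dataclass(frozen=True)
class Recommendation:
    case_id: str
    target_id: str
    source: TargetModality
    drugs: tuple
    nct_level: EvidenceLevelNCT
    escat_tier: EscatTier
    approval: frozenset
    basket: Basket
    rationale: tuple
    alternatives: tuple = ()
    excluded: bool = False
    exclusion_reason: str = ""
    below_report_level: bool = False

    @property
    def drug_label(self) -> str:
        return " + ".join(self.drugs)

    @classmethod
    def from_dict(cls, payload: dict) -> "Recommendation":
        return cls(
            case_id=payload["case_id"],
            target_id=payload["target_id"],
            source=TargetModality(payload["source"]),
            drugs=tuple(payload["drugs"]),
            nct_level=EvidenceLevelNCT(payload["nct_level"]),
            escat_tier=EscatTier(payload["escat_tier"]),
            approval=frozenset(ApprovalStatus(a)
                               for a in payload["approval"]),
            basket=Basket(payload["basket"]),
            rationale=tuple(payload.get("rationale", ())),
            alternatives=tuple(payload.get("alternatives", ())),
            excluded=payload.get("excluded", False),
            exclusion_reason=payload.get("exclusion_reason", ""),
            below_report_level=payload.get("below_report_level", False),
        )

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "target_id": self.target_id,
            "source": self.source.value,
            "drugs": list(self.drugs),
            "nct_level": self.nct_level.value,
            "escat_tier": self.escat_tier.value,
            "approval": sorted(a.value for a in self.approval),
            "basket": self.basket.value,
            "rationale": list(self.rationale),
            "alternatives": list(self.alternatives),
            "excluded": self.excluded,
            "exclusion_reason": self.exclusion_reason,
            "below_report_level": self.below_report_level,
        }


@dataclasses.dataclass
class CaseProfile:
    """One patient's inputs to the virtual board."""

    case_id: str
    variants: list                      # raw VariantRecord list
    ihc: IHCPanel
    biomarkers: Optional[BiomarkerPanel] = None
    catalog: Optional[object] = None    # MutationCatalog
    msi_score: Optional[float] = None
    clinical: dict = dataclasses.field(default_factory=dict)
    mms_audit: Optional[MatchingScoreInput] = None
    mms_audit_note: str = ""


@dataclasses.dataclass
class CaseReport:
    """Self-contained per-case output of the virtual board."""

    case_id: str
    recommendations: list               # cataloged, sorted
    mms: Optional[int]
    mms_input: Optional[MatchingScoreInput]
    mms_source: str                     # "audit" | "computed" | "undefined"
    biomarkers: BiomarkerPanel
    exclusions: list                    # dicts with target/reason/detail
    filter_rejections: dict
    n_variants_input: int
    n_variants_filtered: int
    clinical: dict = dataclasses.field(default_factory=dict)

    @property
    def active_recommendations(self) -> list:
        return [r for r in self.recommendations if not r.excluded]

    @classmethod
    def from_dict(cls, payload: dict) -> "CaseReport":
        mms_x, mms_y = payload.get("mms_x"), payload.get("mms_y")
        return cls(
            case_id=payload["case_id"],
            recommendations=[Recommendation.from_dict(r)
                             for r in payload["recommendations"]],
            mms=payload.get("mms"),
            mms_input=(MatchingScoreInput(mms_x, mms_y)
                       if mms_x is not None else None),
            mms_source=payload.get("mms_source", "computed"),
            biomarkers=BiomarkerPanel(**payload["biomarkers"]),
            exclusions=list(payload.get("exclusions", [])),
            filter_rejections=dict(payload.get("filter_rejections", {})),
            n_variants_input=payload.get("n_variants_input", 0),
            n_variants_filtered=payload.get("n_variants_filtered", 0),
            clinical=dict(payload.get("clinical", {})),
        )

    def to_dict(self) -> dict:
        return {
            "case_id": self.case_id,
            "recommendations": [r.to_dict() for r in self.recommendations],
            "n_cataloged": len(self.recommendations),
            "n_active": len(self.active_recommendations),
            "mms": self.mms,
            "mms_x": self.mms_input.x if self.mms_input else None,
            "mms_y": self.mms_input.y if self.mms_input else None,
            "mms_source": self.mms_source,
            "biomarkers": dataclasses.asdict(self.biomarkers),
            "exclusions": self.exclusions,
            "filter_rejections": self.filter_rejections,
            "n_variants_input": self.n_variants_input,
            "n_variants_filtered": self.n_variants_filtered,
            "clinical": self.clinical,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def to_markdown(self) -> str:
        lines = [f"# Case {self.case_id} — virtual MTB report", ""]
        lines.append("| Target | Drug | NCT/DKTK | ESCAT | Approval | Basket | Status |")
        lines.append("|---|---|---|---|---|---|---|")
        for r in self.recommendations:
            status = "excluded: " + r.exclusion_reason if r.excluded else "active"
            lines.append(
                f"| {r.target_id} | {r.drug_label} | {r.nct_level.value} | "
                f"{r.escat_tier.value} | "
                f"{'/'.join(sorted(a.value for a in r.approval))} | "
                f"{r.basket.value} | {status} |")
        mms_str = f"{self.mms}%" if self.mms is not None else "undefined"
        if self.mms_input:
            mms_str += f" (x={self.mms_input.x}, y={self.mms_input.y}, {self.mms_source})"
        lines += ["", f"Modified matching score: {mms_str}", ""]
        b = self.biomarkers
        lines.append(
            f"Biomarkers: TMB {b.tmb:.2f} mut/Mb"
            f" ({'high' if b.tmb_high else 'not high'});"
            f" BRCAness {b.brcaness_fraction:.2f}"
            f" ({'positive' if b.brcaness_positive else 'negative'});"
            f" MSI {'untested' if b.msi_untested else ('high' if b.msi_high else 'stable')};"
            f" SBS26 predominant: {'yes' if b.mmrd_predominant else 'no'}")
        if self.exclusions:
            lines += ["", "Exclusions:"]
            for e in self.exclusions:
                lines.append(f"- {e['target']}: {e['reason']} — {e['detail']}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# vulnerability derivation

_ROLE_MAP = {
    VariantGeneRole.ONCOGENE: GeneRole.ONCOGENE,
    VariantGeneRole.TSG: GeneRole.TSG,
}


def derive_vulnerabilities(case: CaseProfile,
                           classified: Sequence[ClassifiedVariant],
                           panel: BiomarkerPanel,
                           kb: KnowledgeBase,
                           config: PipelineConfig,
                           expression: Optional[ExpressionMatrix] = None
                           ) -> list:
    """One vulnerability per KB-matchable non-VUS mutation, per positive
    IHC marker with a KB entry, and per set biomarker flag.

    Mutations whose expression check is INCONCLUSIVE (oncogene
    under- / suppressor over-expressed) are emitted flagged for
    exclusion so they stay visible in the cataloged option set.
    """
    vulns: list = []
    for cv in classified:
        if cv.is_vus or cv.functionality is Functionality.NEUTRAL:
            continue
        vaf = cv.variant.effective_vaf
        if vaf is None or vaf < config.filter.min_vaf:
            continue
        if not lookup(kb, cv.variant.gene, TargetModality.MUTATION):
            continue
        call = None
        role = _ROLE_MAP.get(cv.variant.gene_role)
        if role is not None:
            call = conclusiveness_check(cv.variant.gene, role,
                                        case.case_id, expression)
        flagged = call is not None and call.call is Conclusiveness.INCONCLUSIVE
        vulns.append(TherapeuticVulnerability(
            source=TargetModality.MUTATION,
            target_id=cv.variant.gene,
            supporting_variant=cv,
            conclusiveness=call,
            flagged_for_exclusion=flagged,
            flag_reason=REASON_RNA_INCONCLUSIVE if flagged else "",
        ))
    for marker in case.ihc.positive_markers:
        if lookup(kb, marker, TargetModality.IHC):
            vulns.append(TherapeuticVulnerability(
                source=TargetModality.IHC, target_id=marker))
    if panel.tmb_high and lookup(kb, "TMB", TargetModality.TMB_HIGH):
        vulns.append(TherapeuticVulnerability(
            source=TargetModality.TMB_HIGH, target_id="TMB"))
    if panel.msi_high and lookup(kb, "MSI", TargetModality.MSI_HIGH):
        vulns.append(TherapeuticVulnerability(
            source=TargetModality.MSI_HIGH, target_id="MSI"))
    if panel.brcaness_positive and lookup(kb, "BRCANESS",
                                          TargetModality.BRCANESS):
        vulns.append(TherapeuticVulnerability(
            source=TargetModality.BRCANESS, target_id="BRCANESS"))
    return vulns


def apply_exclusion_rules(vulns: Sequence[TherapeuticVulnerability],
                          kb: KnowledgeBase,
                          case: CaseProfile,
                          panel: BiomarkerPanel) -> tuple:
    """Split vulnerabilities into kept and excluded-with-reason.

    RNA-inconclusive mutation candidates are excluded (they remain in the
    cataloged recommendation set, marked excluded).  A predominant SBS26
    mismatch-repair-deficiency signature never yields an immunotherapy
    vulnerability on its own — the rationale is biological (m3/m4 class)
    and below the board's evidence bar; it is logged as an exclusion.
    """
    kept: list = []
    excluded: list = []
    for v in vulns:
        if v.flagged_for_exclusion:
            excluded.append({
                "target": v.target_id,
                "reason": v.flag_reason,
                "detail": "expression check inconclusive for candidate driver",
                "vulnerability": v,
            })
        else:
            kept.append(v)
    if panel.mmrd_predominant and not (panel.tmb_high or panel.msi_high):
        excluded.append({
            "target": "SBS26",
            "reason": REASON_SBS26,
            "detail": ("immunotherapy rationale from MMR-deficiency "
                       "signature alone is biological (m3/m4) evidence; "
                       "not recommended"),
            "vulnerability": None,
        })
    return kept, excluded


# ---------------------------------------------------------------------------
# matching

def _triggered_exclusion_classes(kb: KnowledgeBase,
                                 mutated_genes: set) -> dict:
    """drug class -> triggering gene, for resistance rules fired by the case."""
    triggered = {}
    for rule in kb.exclusion_entries:
        if rule.target_id in mutated_genes:
            triggered[rule.excluded_drug_class] = rule.target_id
    return triggered


def recommend(case: CaseProfile,
              kb: KnowledgeBase,
              config: PipelineConfig,
              vulns_kept: Sequence[TherapeuticVulnerability],
              vulns_excluded: Sequence[dict],
              mutated_genes: set) -> tuple:
    """Match vulnerabilities against the KB and emit recommendations.

    For each vulnerability the highest-evidence eligible entry becomes
    the recommendation (ties: full approval before fast-track, then
    ESCAT tier, then drug name); remaining entries are retained as
    alternatives in the rationale.  Entries of a drug class under a
    triggered resistance rule are dropped with a reason.  RNA-excluded
    vulnerabilities are cataloged with ``excluded=True``.

    Returns (recommendations sorted by evidence, exclusion log entries
    for suppressed KB entries or unmatchable vulnerabilities).
    """
    triggered = _triggered_exclusion_classes(kb, mutated_genes)
    recommendations: list = []
    log: list = []

    catalog_items = [(v, False, "") for v in vulns_kept]
    for entry in vulns_excluded:
        v = entry.get("vulnerability")
        if v is not None:
            catalog_items.append((v, True, entry["reason"]))

    for v, is_excluded, reason in catalog_items:
        entries = lookup(kb, v.target_id, v.source)
        eligible = []
        for e in entries:
            if not e.approval_eligible:
                log.append({"target": v.target_id,
                            "reason": "NOT_APPROVAL_ELIGIBLE",
                            "detail": e.drug_label})
                continue
            if e.drug_class and e.drug_class in triggered:
                trigger = triggered[e.drug_class]
                log.append({"target": v.target_id,
                            "reason": f"{trigger}_RESISTANCE",
                            "detail": f"{e.drug_label} ({e.drug_class}) "
                                      f"withheld: {trigger} alteration "
                                      "confers resistance"})
                continue
            eligible.append(e)
        if not eligible:
            log.append({"target": v.target_id,
                        "reason": "NO_ELIGIBLE_KB_ENTRY",
                        "detail": f"vulnerability {v.source.value} not matched"})
            continue
        eligible.sort(key=lambda e: (-e.nct_level.rank,
                                     approval_sort_key(e.approval),
                                     -e.escat_tier.rank,
                                     e.drug_label))
        best, alternatives = eligible[0], eligible[1:]
        rationale = [f"{v.source.value} vulnerability {v.target_id}"]
        if v.supporting_variant is not None:
            sv = v.supporting_variant
            rationale.append(
                f"supporting variant {sv.variant.gene} "
                f"{sv.variant.effect.value} VAF {sv.variant.effective_vaf:.2f} "
                f"({sv.functionality.value}/{sv.mechanism.value})")
        if v.conclusiveness is not None:
            rationale.append(
                f"expression check: {v.conclusiveness.call.value}")
        if alternatives:
            rationale.append(
                "alternatives ranked below by evidence: "
                + ", ".join(f"{a.drug_label} ({a.nct_level.value})"
                            for a in alternatives))
        rationale.append(
            f"selected {best.drug_label}: highest NCT/DKTK level "
            f"{best.nct_level.value} (ESCAT {best.escat_tier.value})")
        recommendations.append(Recommendation(
            case_id=case.case_id,
            target_id=v.target_id,
            source=v.source,
            drugs=best.drugs,
            nct_level=best.nct_level,
            escat_tier=best.escat_tier,
            approval=best.approval,
            basket=best.basket,
            rationale=tuple(rationale),
            alternatives=tuple(a.drug_label for a in alternatives),
            excluded=is_excluded,
            exclusion_reason=reason,
            below_report_level=best.nct_level.rank
            < config.min_report_level.rank,
        ))
    recommendations.sort(key=lambda r: (-r.nct_level.rank,
                                        -r.escat_tier.rank, r.target_id))
    return recommendations, log


# ---------------------------------------------------------------------------
# matching score from derived quantities

def matching_score_input(recommendations: Sequence[Recommendation],
                         classified: Sequence[ClassifiedVariant],
                         min_vaf: float) -> MatchingScoreInput:
    """Derive (x, y) from the cataloged options and the variant list.

    x counts unique targeted aberrations over the cataloged set (a
    combination against one aberration is a single entry, so it counts
    once by construction); y adds un-targeted characteristic and
    significant alterations (non-VUS, non-neutral, VAF >= 5%).
    """
    targeted = {(r.source, r.target_id) for r in recommendations}
    x = len(targeted)
    targeted_genes = {t for s, t in targeted if s is TargetModality.MUTATION}
    untargeted = 0
    counted = set()
    for cv in classified:
        if cv.is_vus or cv.functionality is Functionality.NEUTRAL:
            continue
        vaf = cv.variant.effective_vaf
        if vaf is None or vaf < min_vaf:
            continue
        key = (cv.variant.gene, cv.variant.chrom, cv.variant.pos)
        if cv.variant.gene in targeted_genes or key in counted:
            continue
        counted.add(key)
        untargeted += 1
    return MatchingScoreInput(x=x, y=x + untargeted)


# ---------------------------------------------------------------------------
# per-case orchestration

def run_case(case: CaseProfile,
             kb: KnowledgeBase,
             config: PipelineConfig = PipelineConfig(),
             expression: Optional[ExpressionMatrix] = None) -> CaseReport:
    """Execute the full per-case procedure and assemble the report."""
    filt: FilterResult = filter_somatic_variants(case.variants, config.filter)
    classified = [classify_variant(v, config.filter) for v in filt.kept]
    if case.biomarkers is not None:
        panel = case.biomarkers
    else:
        panel = biomarker_panel(
            classified,
            exome_size_mb=config.exome_size_mb,
            tmb_high_cutoff=config.tmb_high_cutoff,
            catalog=case.catalog,
            msi_score=case.msi_score,
            msi_threshold=config.msi_threshold,
            brcaness_cutoff=config.brcaness_cutoff,
        )
    vulns = derive_vulnerabilities(case, classified, panel, kb, config,
                                   expression)
    kept, excluded = apply_exclusion_rules(vulns, kb, case, panel)
    mutated_genes = {cv.variant.gene for cv in classified if not cv.is_vus}
    recommendations, match_log = recommend(case, kb, config, kept,
                                           excluded, mutated_genes)
    exclusion_entries = [
        {"target": e["target"], "reason": e["reason"], "detail": e["detail"]}
        for e in excluded
    ] + [e for e in match_log if e["reason"].endswith("_RESISTANCE")]

    if case.mms_audit is not None:
        mms_input = case.mms_audit
        mms_source = "audit"
    else:
        mms_input = matching_score_input(recommendations, classified,
                                         config.filter.min_vaf)
        mms_source = "computed"
    try:
        mms = compute_mms(mms_input)
    except UndefinedScoreError:
        mms, mms_input, mms_source = None, None, "undefined"

    return assemble_case_output(case, recommendations, mms, mms_input,
                                mms_source, panel, exclusion_entries,
                                filt, classified)


def assemble_case_output(case: CaseProfile,
                         recommendations: list,
                         mms: Optional[int],
                         mms_input: Optional[MatchingScoreInput],
                         mms_source: str,
                         panel: BiomarkerPanel,
                         exclusions: list,
                         filter_result: FilterResult,
                         classified: list) -> CaseReport:
    return CaseReport(
        case_id=case.case_id,
        recommendations=recommendations,
        mms=mms,
        mms_input=mms_input,
        mms_source=mms_source,
        biomarkers=panel,
        exclusions=exclusions,
        filter_rejections=dict(filter_result.rejected),
        n_variants_input=len(case.variants),
        n_variants_filtered=len(filter_result.kept),
        clinical=dict(case.clinical),
    )
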