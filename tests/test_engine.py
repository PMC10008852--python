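"""Recommendation engine: matching score, exclusion rules, KB matching."""

import dataclasses
import random

import pytest
from hypothesis import given, settings, strategies as st

from mtbmatch.biomarkers import BiomarkerPanel
from mtbmatch.config import PipelineConfig
from mtbmatch.engine import (
    CaseProfile,
    IHCPanel,
    IHCStatus,
    MatchingScoreInput,
    REASON_RNA_INCONCLUSIVE,
    REASON_SBS26,
    UndefinedScoreError,
    compute_mms,
    run_case,
)
from mtbmatch.evidence import EvidenceLevelNCT
from mtbmatch.fixture import build_paper_fixture, derive_xy_candidates
from mtbmatch.kb import TargetModality, lookup
from mtbmatch.variants import Effect, VariantGeneRole
from tests.test_variants import make_variant

ALL_NEGATIVE_IHC = IHCPanel.from_dict(
    {m: IHCStatus.NEGATIVE for m in ("CD19", "CD30", "CD38", "CD79B")})

QUIET_PANEL = BiomarkerPanel(tmb=4.0, msi_untested=True)


def make_case(case_id="T", variants=(), ihc=ALL_NEGATIVE_IHC,
              panel=QUIET_PANEL, **kwargs):
    return CaseProfile(case_id=case_id, variants=list(variants), ihc=ihc,
                       biomarkers=panel, **kwargs)


# ---------------------------------------------------------------------------
# modified matching score

@pytest.mark.parametrize("x,y,expected", [
    (3, 3, 100), (0, 5, 0),
    (4, 9, 44), (3, 7, 43), (3, 14, 21),     # round-half-up behaviour
    (3, 8, 38), (4, 7, 57), (5, 7, 71),      # .5 rounds up: 37.5 -> 38
    (1, 2, 50), (1, 3, 33),
])
def test_compute_mms_round_half_up(x, y, expected):
    assert compute_mms(MatchingScoreInput(x, y)) == expected


def test_mms_undefined_without_alterations():
    with pytest.raises(UndefinedScoreError):
        compute_mms(MatchingScoreInput(0, 0))


def test_mms_input_invariants():
    with pytest.raises(ValueError):
        MatchingScoreInput(5, 3)
    with pytest.raises(ValueError):
        MatchingScoreInput(-1, 3)


@settings(max_examples=200, deadline=None)
@given(st.integers(0, 50), st.integers(0, 50))
def test_mms_matches_decimal_oracle(x, extra):
    from decimal import Decimal, ROUND_HALF_UP

    y = x + extra
    if y == 0:
        return
    oracle = int((Decimal(100 * x) / Decimal(y))
                 .quantize(Decimal(1), rounding=ROUND_HALF_UP))
    assert compute_mms(MatchingScoreInput(x, y)) == oracle


@settings(max_examples=100, deadline=None)
@given(st.integers(0, 30), st.integers(0, 30))
def test_mms_monotonicity(x, extra):
    y = x + extra
    if y == 0:
        return
    score = compute_mms(MatchingScoreInput(x, y))
    # another targetable vulnerability never lowers the score
    assert compute_mms(MatchingScoreInput(x + 1, y + 1)) >= score
    # another un-targetable significant alteration never raises it
    assert compute_mms(MatchingScoreInput(x, y + 1)) <= score


def test_published_scores_have_consistent_xy_pairs():
    """The stored (x, y) pairs are among the brute-force candidates for
    each printed percent."""
    fixtures, _, _ = build_paper_fixture()
    for f in fixtures:
        assert (f.x, f.y) in derive_xy_candidates(f.mms_printed)
        assert compute_mms(MatchingScoreInput(f.x, f.y)) == f.mms_printed


# ---------------------------------------------------------------------------
# derivation + exclusion rules

def test_case30_style_derivation(kb_paper):
    case = make_case(
        case_id="30",
        variants=[make_variant(gene="TP53", effect=Effect.NONSENSE,
                               gene_role=VariantGeneRole.TSG)],
        ihc=IHCPanel.from_dict({"CD38": "POSITIVE", "CD19": "POSITIVE",
                                "CD30": "NEGATIVE", "CD79B": "NEGATIVE"}))
    report = run_case(case, kb_paper)
    targets = {r.target_id for r in report.recommendations}
    assert targets == {"CD38", "CD19", "TP53"}
    assert len(report.active_recommendations) == 3


def test_empty_case_has_no_recommendations(kb_paper):
    report = run_case(make_case(), kb_paper)
    assert report.recommendations == []
    assert report.mms is None and report.mms_source == "undefined"


def test_tp53_resistance_rule_suppresses_cdk46(kb_paper):
    case = make_case(variants=[make_variant(
        gene="TP53", effect=Effect.NONSENSE,
        gene_role=VariantGeneRole.TSG)])
    report = run_case(case, kb_paper)
    tp53 = [r for r in report.recommendations if r.target_id == "TP53"]
    assert len(tp53) == 1
    assert tp53[0].drugs == ("Eprenetapopt", "Pembrolizumab")
    assert "Palbociclib" not in " ".join(tp53[0].alternatives)
    reasons = {e["reason"] for e in report.exclusions}
    assert "TP53_RESISTANCE" in reasons


def test_sbs26_alone_yields_no_immunotherapy(kb_paper):
    panel = BiomarkerPanel(tmb=4.0, mmrd_predominant=True, msi_untested=True)
    report = run_case(make_case(panel=panel), kb_paper)
    assert report.recommendations == []
    assert any(e["reason"] == REASON_SBS26 for e in report.exclusions)


def test_tmb_high_yields_immunotherapy(kb_paper):
    panel = BiomarkerPanel(tmb=12.0, tmb_high=True, msi_untested=True)
    report = run_case(make_case(panel=panel), kb_paper)
    assert [r.target_id for r in report.recommendations] == ["TMB"]
    assert report.recommendations[0].drugs == ("Pembrolizumab",)


def test_ros1_checkpoint_rationale_is_retained(kb_paper):
    """Immune-escape rationale for ROS1 alterations survives the SBS26 rule."""
    panel = BiomarkerPanel(tmb=4.0, mmrd_predominant=True, msi_untested=True)
    case = make_case(variants=[make_variant(
        gene="ROS1", effect=Effect.MISSENSE, cadd_phred=30.0,
        gene_role=VariantGeneRole.ONCOGENE)], panel=panel)
    report = run_case(case, kb_paper)
    assert [r.target_id for r in report.active_recommendations] == ["ROS1"]
    assert report.active_recommendations[0].drugs == ("Pembrolizumab",)


def test_rna_inconclusive_candidate_cataloged_but_excluded(kb_paper):
    fixtures, profiles, expression = build_paper_fixture(kb_paper)
    case4 = next(p for p in profiles if p.case_id == "4")
    report = run_case(case4, kb_paper, expression=expression)
    assert len(report.recommendations) == 3
    assert len(report.active_recommendations) == 2
    kit = [r for r in report.recommendations if r.target_id == "KIT"]
    assert kit[0].excluded
    assert kit[0].exclusion_reason == REASON_RNA_INCONCLUSIVE
    assert kit[0].drugs == ("Ripretinib",)
    assert any(e["target"] == "KIT" for e in report.exclusions)


def test_vus_and_neutral_variants_never_become_targets(kb_paper):
    vus = make_variant(gene="TP53", effect=Effect.MISSENSE,
                       cadd_phred=5.0, recurrence_flag=False,
                       gene_role=VariantGeneRole.TSG)
    benign = make_variant(gene="KIT", known_benign_flag=True,
                          gene_role=VariantGeneRole.ONCOGENE, pos=2000)
    report = run_case(make_case(variants=[vus, benign]), kb_paper)
    assert report.recommendations == []


def test_highest_evidence_agent_preferred(kb_minimal):
    case = make_case(ihc=IHCPanel.from_dict({"CD38": "POSITIVE"}))
    report = run_case(case, kb_minimal)
    assert len(report.recommendations) == 1
    rec = report.recommendations[0]
    assert rec.drugs == ("Daratumumab",)
    assert rec.nct_level is EvidenceLevelNCT.m1C
    assert rec.alternatives == ("Isatuximab",)


def test_untested_ihc_never_yields_vulnerability(kb_minimal):
    case = make_case(ihc=IHCPanel.from_dict({"CD38": "UNTESTED"}))
    assert run_case(case, kb_minimal).recommendations == []


def test_combination_counts_once_in_computed_score(kb_paper):
    """Replacing a single agent by a combination leaves x unchanged."""
    erbb2 = make_variant(gene="ERBB2", effect=Effect.MISSENSE,
                         cadd_phred=30.0,
                         gene_role=VariantGeneRole.ONCOGENE)
    report = run_case(make_case(variants=[erbb2]), kb_paper)
    assert report.mms_input.x == 1           # 3-drug combination, one target
    assert report.mms == 100
    tet2 = make_variant(gene="TET2", effect=Effect.FRAMESHIFT, pos=3000,
                        gene_role=VariantGeneRole.TSG)
    single = run_case(make_case(variants=[tet2]), kb_paper)
    assert single.mms_input.x == 1


# ---------------------------------------------------------------------------
# oracle equivalence on random small cases

KB_GENES = {
    "STAT3": VariantGeneRole.ONCOGENE, "NF1": VariantGeneRole.TSG,
    "ERBB2": VariantGeneRole.ONCOGENE, "PIK3CD": VariantGeneRole.ONCOGENE,
    "TP53": VariantGeneRole.TSG, "KIT": VariantGeneRole.ONCOGENE,
    "ROS1": VariantGeneRole.ONCOGENE, "TET2": VariantGeneRole.TSG,
    "OFFKB1": VariantGeneRole.UNKNOWN, "OFFKB2": VariantGeneRole.UNKNOWN,
}


def brute_force_expected_targets(kb, variants, ihc_positive):
    """Independent matcher: enumerate every KB entry against the case."""
    expected = set()
    for marker in ihc_positive:
        for entry in kb.therapeutic_entries:
            if entry.target_id == marker and \
                    entry.target_modality is TargetModality.IHC:
                expected.add((TargetModality.IHC, marker))
    for v in variants:
        depth_ok = v.depth is None or v.depth >= 8
        vaf = v.effective_vaf
        if not depth_ok or vaf is None or vaf < 0.05 or v.known_benign_flag:
            continue
        deleterious = v.cadd_phred is not None and v.cadd_phred > 20
        truncating = v.effect in (Effect.NONSENSE, Effect.FRAMESHIFT)
        inconclusive = not (v.recurrence_flag and (deleterious or truncating))
        if inconclusive and not v.recurrence_flag:
            continue  # VUS
        for entry in kb.therapeutic_entries:
            if entry.target_id == v.gene and \
                    entry.target_modality is TargetModality.MUTATION:
                expected.add((TargetModality.MUTATION, v.gene))
    return expected


@settings(max_examples=60, deadline=None)
@given(st.data())
def test_recommended_targets_match_brute_force_oracle(kb_paper, data):
    genes = data.draw(st.lists(st.sampled_from(sorted(KB_GENES)),
                               max_size=6, unique=True))
    variants = []
    for i, gene in enumerate(genes):
        variants.append(make_variant(
            gene=gene, pos=1000 + i,
            gene_role=KB_GENES[gene],
            effect=data.draw(st.sampled_from(list(Effect))),
            cadd_phred=data.draw(st.none() | st.floats(0, 40)),
            recurrence_flag=data.draw(st.booleans()),
            known_benign_flag=data.draw(st.booleans()),
            ref_reads=60, alt_reads=40, vaf=0.4,
        ))
    positive = data.draw(st.lists(
        st.sampled_from(["CD19", "CD30", "CD38", "CD79B"]),
        max_size=4, unique=True))
    ihc = IHCPanel.from_dict({m: ("POSITIVE" if m in positive else "NEGATIVE")
                              for m in ("CD19", "CD30", "CD38", "CD79B")})
    report = run_case(make_case(variants=variants, ihc=ihc), kb_paper)
    got = {(r.source, r.target_id) for r in report.recommendations}
    assert got == brute_force_expected_targets(kb_paper, variants, positive)


# ---------------------------------------------------------------------------
# determinism

def test_reports_are_byte_identical_across_runs(kb_paper):
    fixtures, profiles, expression = build_paper_fixture(kb_paper)

    def render():
        out = []
        for p in profiles:
            r = run_case(p, kb_paper, PipelineConfig(), expression)
            out.append(r.to_json() + r.to_markdown())
        return "".join(out)

    assert render() == render()
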