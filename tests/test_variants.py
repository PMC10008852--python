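"""Variant parsing, the filter rules and the classification rule table."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from mtbmatch.variants import (
    ClassifiedVariant,
    Effect,
    FilterConfig,
    Functionality,
    Mechanism,
    TRUNCATING_EFFECTS,
    VariantGeneRole,
    VariantRecord,
    classify_variant,
    filter_somatic_variants,
    mutation_type_summary,
    read_variants,
    write_variants_tsv,
)


def make_variant(**kwargs):
    base = dict(chrom="1", pos=1000, ref="C", alt="T", gene="TP53",
                effect=Effect.MISSENSE, ref_reads=60, alt_reads=40,
                vaf=0.40, cadd_phred=25.0, recurrence_flag=True,
                gene_role=VariantGeneRole.TSG)
    base.update(kwargs)
    return VariantRecord(**base)


# ---------------------------------------------------------------------------
# parsing

VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=17>
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene">
##INFO=<ID=EFFECT,Number=1,Type=String,Description="Effect">
##INFO=<ID=CADD,Number=1,Type=Float,Description="CADD phred">
##INFO=<ID=AF_1000G,Number=1,Type=Float,Description="1000G AF">
##INFO=<ID=AF_GNOMAD,Number=1,Type=Float,Description="gnomAD AF">
##INFO=<ID=AF_EXAC,Number=1,Type=Float,Description="ExAC AF">
##INFO=<ID=RECURRENT,Number=0,Type=Flag,Description="Hotspot">
##INFO=<ID=ROLE,Number=1,Type=String,Description="Gene role">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tTUMOR
17\t7578406\t.\tC\tT\t.\t.\tGENE=TP53;EFFECT=NONSENSE;CADD=35.0;AF_GNOMAD=0.0;RECURRENT;ROLE=TSG\tAD\t60,40
17\t7578407\t.\tG\tA\t.\t.\tGENE=TP53;EFFECT=MISSENSE\tAD\t90,10
"""


def test_read_vcf_computes_vaf_and_keeps_missing_missing(tmp_path):
    path = tmp_path / "case.vcf"
    path.write_text(VCF_TEXT)
    records = read_variants(path, dialect="VCF")
    assert len(records) == 2
    first, second = records
    assert first.vaf == pytest.approx(0.40)
    assert first.gene == "TP53" and first.recurrence_flag
    assert first.cadd_phred == pytest.approx(35.0)
    # missing annotations stay missing, never zero
    assert second.cadd_phred is None
    assert second.pop_af_gnomad is None


def test_tsv_round_trip_and_missing_columns(tmp_path):
    records = [make_variant(), make_variant(pos=2000, cadd_phred=None)]
    path = tmp_path / "variants.tsv"
    write_variants_tsv(records, path)
    back = read_variants(path, dialect="TSV")
    assert back == records
    assert back[1].cadd_phred is None


def test_inconsistent_vaf_rejected():
    with pytest.raises(ValueError, match="inconsistent"):
        make_variant(vaf=0.9)


# ---------------------------------------------------------------------------
# filtering

@pytest.mark.parametrize("kwargs,kept,rule", [
    (dict(ref_reads=4, alt_reads=3, vaf=3 / 7), False, "depth"),   # depth 7
    (dict(ref_reads=4, alt_reads=4, vaf=0.5), True, None),         # depth 8
    (dict(ref_reads=95, alt_reads=5, vaf=0.05), True, None),       # VAF at bound
    (dict(ref_reads=96, alt_reads=4, vaf=0.04), False, "vaf"),
    (dict(pop_af_gnomad=0.001), False, "pop_af"),                  # strict <
    (dict(pop_af_gnomad=0.0009), True, None),
    (dict(pop_af_gnomad=None, pop_af_1000g=None, pop_af_exac=None), True, None),
])
def test_filter_boundary_semantics(kwargs, kept, rule):
    result = filter_somatic_variants([make_variant(**kwargs)])
    assert (len(result.kept) == 1) is kept
    if rule:
        assert result.rejected[rule] == 1


def test_filter_counts_partition_input():
    records = [
        make_variant(ref_reads=3, alt_reads=2, vaf=0.4),
        make_variant(ref_reads=96, alt_reads=4, vaf=0.04),
        make_variant(pop_af_1000g=0.01),
        make_variant(),
    ]
    result = filter_somatic_variants(records)
    assert len(result.kept) + sum(result.rejected.values()) == len(records)
    assert result.rejected == {"depth": 1, "vaf": 1, "pop_af": 1}


variant_strategy = st.builds(
    make_variant,
    ref_reads=st.integers(0, 200),
    alt_reads=st.integers(0, 200),
    vaf=st.none(),
    pop_af_gnomad=st.none() | st.floats(0, 0.01),
    pop_af_1000g=st.none() | st.floats(0, 0.01),
)


@settings(max_examples=50, deadline=None)
@given(st.lists(variant_strategy, max_size=20))
def test_filter_idempotent(records):
    once = filter_somatic_variants(records).kept
    twice = filter_somatic_variants(once).kept
    assert twice == once


@settings(max_examples=50, deadline=None)
@given(st.lists(variant_strategy, max_size=20),
       st.floats(0.01, 0.5), st.floats(0.01, 0.5))
def test_filter_monotone_in_vaf_threshold(records, t1, t2):
    lo, hi = sorted([t1, t2])
    kept_lo = filter_somatic_variants(records, FilterConfig(min_vaf=lo)).kept
    kept_hi = filter_somatic_variants(records, FilterConfig(min_vaf=hi)).kept
    assert set(id(v) for v in kept_hi) <= set(id(v) for v in kept_lo)


# ---------------------------------------------------------------------------
# classification: exhaustive truth table vs independent oracle

def oracle_classify(benign, recurrent, effect, cadd, role, threshold=20.0):
    """Independent restatement of the classification rules."""
    deleterious = cadd is not None and cadd > threshold
    truncating = effect in (Effect.NONSENSE, Effect.FRAMESHIFT)
    if benign:
        functionality = Functionality.NEUTRAL
    elif recurrent and (deleterious or truncating):
        functionality = Functionality.RELEVANT
    else:
        functionality = Functionality.INCONCLUSIVE
    if truncating or (role is VariantGeneRole.TSG
                      and effect is Effect.MISSENSE and deleterious):
        mechanism = Mechanism.LOF
    elif role is VariantGeneRole.ONCOGENE and recurrent:
        mechanism = Mechanism.GOF
    else:
        mechanism = Mechanism.UNKNOWN
    vus = functionality is Functionality.INCONCLUSIVE and not recurrent
    return functionality, mechanism, vus


def test_classify_full_decision_table_matches_oracle():
    for benign, recurrent, effect, cadd, role in itertools.product(
            [False, True], [False, True], list(Effect),
            [None, 10.0, 20.0, 25.0], list(VariantGeneRole)):
        v = make_variant(known_benign_flag=benign, recurrence_flag=recurrent,
                         effect=effect, cadd_phred=cadd, gene_role=role)
        cv = classify_variant(v)
        assert (cv.functionality, cv.mechanism, cv.is_vus) == \
            oracle_classify(benign, recurrent, effect, cadd, role), \
            (benign, recurrent, effect, cadd, role)


@pytest.mark.parametrize("kwargs,functionality,mechanism", [
    (dict(effect=Effect.NONSENSE, recurrence_flag=True,
          gene_role=VariantGeneRole.TSG),
     Functionality.RELEVANT, Mechanism.LOF),
    (dict(known_benign_flag=True), Functionality.NEUTRAL, Mechanism.LOF),
    (dict(gene_role=VariantGeneRole.ONCOGENE, cadd_phred=25.0,
          recurrence_flag=True, effect=Effect.MISSENSE),
     Functionality.RELEVANT, Mechanism.GOF),
])
def test_classify_named_examples(kwargs, functionality, mechanism):
    cv = classify_variant(make_variant(**kwargs))
    assert cv.functionality is functionality
    assert cv.mechanism is mechanism


def test_cadd_boundary_is_strict():
    at = classify_variant(make_variant(cadd_phred=20.0, effect=Effect.MISSENSE))
    above = classify_variant(make_variant(cadd_phred=20.01,
                                          effect=Effect.MISSENSE))
    assert at.functionality is Functionality.INCONCLUSIVE
    assert above.functionality is Functionality.RELEVANT


# ---------------------------------------------------------------------------
# summaries

def test_mutation_type_summary_proportions():
    classified = [classify_variant(make_variant(effect=e))
                  for e in [Effect.MISSENSE] * 3 + [Effect.NONSENSE]]
    summary = mutation_type_summary(classified)
    assert not summary["empty"]
    assert summary["by_effect"] == {"MISSENSE": 0.75, "NONSENSE": 0.25}
    assert sum(summary["by_effect"].values()) == pytest.approx(1.0)


def test_mutation_type_summary_empty():
    assert mutation_type_summary([])["empty"] is True
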