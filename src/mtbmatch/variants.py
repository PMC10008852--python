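"""Somatic variant parsing, filtering and functional classification.

Filtering follows fixed boundary semantics on annotated somatic calls
(no matched germline is assumed):

* total read depth (ref + alt) at the variant position >= 8 (inclusive),
* variant allele frequency (VAF) >= 5% (inclusive),
* every *present* population allele frequency (1000 Genomes, gnomAD,
  ExAC) strictly below 0.001; missing annotations never reject.

Rules are applied in fixed priority order (depth, VAF, population AF) so
per-rule rejection counts partition the rejected set.

Functional classification is a deterministic surrogate for manual
database curation: recurrence and known-benign flags are inputs (from the
annotation step), and the rule table below maps them together with effect
class, CADD deleteriousness and gene role onto functionality
(RELEVANT / NEUTRAL / INCONCLUSIVE), mechanism (LOF / GOF / UNKNOWN) and
variant-of-unknown-significance status.
"""

from __future__ import annotations

import csv
import dataclasses
import enum
import logging
import math
from pathlib import Path
from typing import Optional, Sequence

logger = logging.getLogger(__name__)


class Effect(enum.Enum):
    MISSENSE = "MISSENSE"
    NONSENSE = "NONSENSE"
    FRAMESHIFT = "FRAMESHIFT"
    INFRAME_INDEL = "INFRAME_INDEL"
    SPLICE = "SPLICE"
    SYNONYMOUS = "SYNONYMOUS"
    OTHER = "OTHER"


#: Effect classes treated as protein-truncating.
TRUNCATING_EFFECTS = frozenset({Effect.NONSENSE, Effect.FRAMESHIFT})


class Functionality(enum.Enum):
    RELEVANT = "RELEVANT"
    NEUTRAL = "NEUTRAL"
    INCONCLUSIVE = "INCONCLUSIVE"


class Mechanism(enum.Enum):
    LOF = "LOF"
    GOF = "GOF"
    UNKNOWN = "UNKNOWN"


class VariantGeneRole(enum.Enum):
    ONCOGENE = "ONCOGENE"
    TSG = "TSG"
    UNKNOWN = "UNKNOWN"


@dataclasses.dataclass(frozen=True)
class VariantRecord:
    """One annotated somatic variant (1-based coordinates, hg19 convention)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    effect: Effect
    ref_reads: Optional[int] = None
    alt_reads: Optional[int] = None
    vaf: Optional[float] = None
    pop_af_1000g: Optional[float] = None
    pop_af_gnomad: Optional[float] = None
    pop_af_exac: Optional[float] = None
    cadd_phred: Optional[float] = None
    recurrence_flag: bool = False
    known_benign_flag: bool = False
    gene_role: VariantGeneRole = VariantGeneRole.UNKNOWN
    subclone_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.vaf is not None and not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"VAF outside [0,1]: {self.vaf}")
        if (self.vaf is not None and self.ref_reads is not None
                and self.alt_reads is not None):
            depth = self.ref_reads + self.alt_reads
            if depth > 0 and abs(self.vaf - self.alt_reads / depth) > 0.01:
                raise ValueError(
                    f"{self.gene} {self.chrom}:{self.pos}: VAF {self.vaf} "
                    f"inconsistent with AD {self.alt_reads}/{depth}")

    @property
    def depth(self) -> Optional[int]:
        if self.ref_reads is None or self.alt_reads is None:
            return None
        return self.ref_reads + self.alt_reads

    @property
    def effective_vaf(self) -> Optional[float]:
        """Stated VAF, or VAF recomputed from read counts."""
        if self.vaf is not None:
            return self.vaf
        if self.depth:
            return self.alt_reads / self.depth
        return None

    @property
    def population_afs(self) -> dict:
        return {
            "1000g": self.pop_af_1000g,
            "gnomad": self.pop_af_gnomad,
            "exac": self.pop_af_exac,
        }


@dataclasses.dataclass(frozen=True)
class FilterConfig:
    min_total_reads: int = 8
    min_vaf: float = 0.05
    max_pop_af: float = 0.001
    cadd_deleterious_threshold: float = 20.0

    def __post_init__(self) -> None:
        if self.min_total_reads <= 0 or self.min_vaf <= 0 \
                or self.max_pop_af <= 0 or self.cadd_deleterious_threshold <= 0:
            raise ValueError("all filter thresholds must be positive")
        if self.min_vaf >= 1:
            raise ValueError("min_vaf must be < 1")


@dataclasses.dataclass(frozen=True)
class ClassifiedVariant:
    variant: VariantRecord
    functionality: Functionality
    mechanism: Mechanism
    is_vus: bool


@dataclasses.dataclass
class FilterResult:
    kept: list
    rejected: dict  # rule name -> count

    def __iter__(self):
        return iter(self.kept)

    def __len__(self):
        return len(self.kept)


# ---------------------------------------------------------------------------
# parsing

_TSV_FIELDS = {
    "chrom": str, "pos": int, "ref": str, "alt": str, "gene": str,
    "effect": str, "ref_reads": int, "alt_reads": int, "vaf": float,
    "pop_af_1000g": float, "pop_af_gnomad": float, "pop_af_exac": float,
    "cadd_phred": float, "recurrence_flag": bool, "known_benign_flag": bool,
    "gene_role": str, "subclone_id": str,
}

TSV_HEADER = list(_TSV_FIELDS)


def _coerce(value: str, typ):
    value = (value or "").strip()
    if value in ("", ".", "NA", "-"):
        return None
    if typ is bool:
        return value.lower() in ("1", "true", "yes")
    return typ(value)


def read_variants(path, dialect: Optional[str] = None,
                  strict: bool = True) -> list:
    """Read annotated variants from VCF or TSV.

    The dialect is auto-detected from the extension when not given.  VCF
    input expects the annotation keys GENE, EFFECT, CADD, AF_1000G,
    AF_GNOMAD and AF_EXAC in INFO and per-sample AD (or DP) FORMAT
    fields; the TSV dialect expects one header-named column per record
    field.  Missing optional annotations stay missing — they are never
    coerced to zero.
    """
    path = Path(path)
    if dialect is None:
        dialect = "VCF" if path.suffix.lower() in (".vcf", ".gz") else "TSV"
    if dialect.upper() == "VCF":
        return _read_vcf(path, strict)
    return _read_tsv(path, strict)


def _read_tsv(path: Path, strict: bool) -> list:
    records = []
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=2):
            try:
                kwargs = {}
                for field, typ in _TSV_FIELDS.items():
                    if field in row:
                        kwargs[field] = _coerce(row[field], typ)
                kwargs["effect"] = Effect(kwargs.get("effect") or "OTHER")
                kwargs["gene_role"] = VariantGeneRole(
                    kwargs.get("gene_role") or "UNKNOWN")
                kwargs["recurrence_flag"] = bool(kwargs.get("recurrence_flag"))
                kwargs["known_benign_flag"] = bool(kwargs.get("known_benign_flag"))
                if kwargs.get("vaf") is None and kwargs.get("alt_reads") is not None:
                    depth = (kwargs.get("ref_reads") or 0) + kwargs["alt_reads"]
                    kwargs["vaf"] = kwargs["alt_reads"] / depth if depth else None
                records.append(VariantRecord(**kwargs))
            except (ValueError, KeyError, TypeError) as exc:
                if strict:
                    raise ValueError(f"{path} line {lineno}: {exc}") from exc
                logger.warning("skipping unparsable record %s:%d: %s",
                               path, lineno, exc)
    return records


def _read_vcf(path: Path, strict: bool) -> list:
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            try:
                info = rec.info
                ref_reads = alt_reads = None
                if rec.samples:
                    sample = rec.samples[0]
                    ad = sample.get("AD")
                    if ad is not None and len(ad) >= 2 and ad[0] is not None:
                        ref_reads, alt_reads = int(ad[0]), int(ad[1])
                vaf = None
                if ref_reads is not None and alt_reads is not None \
                        and ref_reads + alt_reads > 0:
                    vaf = alt_reads / (ref_reads + alt_reads)
                records.append(VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0] if rec.alts else ".",
                    gene=str(_info_scalar(info, "GENE") or ""),
                    effect=Effect(str(_info_scalar(info, "EFFECT") or "OTHER")),
                    ref_reads=ref_reads,
                    alt_reads=alt_reads,
                    vaf=vaf,
                    pop_af_1000g=_info_float(info, "AF_1000G"),
                    pop_af_gnomad=_info_float(info, "AF_GNOMAD"),
                    pop_af_exac=_info_float(info, "AF_EXAC"),
                    cadd_phred=_info_float(info, "CADD"),
                    recurrence_flag=bool(_info_scalar(info, "RECURRENT")),
                    known_benign_flag=bool(_info_scalar(info, "BENIGN")),
                    gene_role=VariantGeneRole(
                        str(_info_scalar(info, "ROLE") or "UNKNOWN")),
                ))
            except (ValueError, KeyError, TypeError) as exc:
                if strict:
                    raise ValueError(
                        f"{path} {rec.chrom}:{rec.pos}: {exc}") from exc
                logger.warning("skipping unparsable VCF record %s:%s: %s",
                               rec.chrom, rec.pos, exc)
    return records


def _info_scalar(info, key):
    try:  # pysam raises on keys absent from the header
        value = info.get(key)
    except (KeyError, ValueError):
        return None
    if isinstance(value, tuple):
        value = value[0] if value else None
    return value


def _info_float(info, key):
    value = _info_scalar(info, key)
    if value is None:
        return None
    value = float(value)
    return None if math.isnan(value) else value


def write_variants_tsv(records: Sequence[VariantRecord], path) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(TSV_HEADER)
        for v in records:
            writer.writerow([
                v.chrom, v.pos, v.ref, v.alt, v.gene, v.effect.value,
                _fmt(v.ref_reads), _fmt(v.alt_reads), _fmt(v.vaf),
                _fmt(v.pop_af_1000g), _fmt(v.pop_af_gnomad),
                _fmt(v.pop_af_exac), _fmt(v.cadd_phred),
                int(v.recurrence_flag), int(v.known_benign_flag),
                v.gene_role.value, v.subclone_id or "",
            ])
    return path


def _fmt(value):
    if value is None:
        return ""
    if isinstance(value, float):
        return repr(value)
    return value


# ---------------------------------------------------------------------------
# filtering

def filter_somatic_variants(records: Sequence[VariantRecord],
                            config: FilterConfig = FilterConfig()) -> FilterResult:
    """Apply the depth / VAF / population-AF filters in priority order.

    Order is preserved.  Depth is total (ref + alt) coverage; records
    without read counts are not rejected on depth.  The VAF bound is
    inclusive, the population-AF bound strict, and each present
    population database is tested independently.
    """
    kept: list = []
    rejected = {"depth": 0, "vaf": 0, "pop_af": 0}
    for v in records:
        depth = v.depth
        if depth is not None and depth < config.min_total_reads:
            rejected["depth"] += 1
            continue
        vaf = v.effective_vaf
        if vaf is not None and vaf < config.min_vaf:
            rejected["vaf"] += 1
            continue
        afs = [af for af in v.population_afs.values() if af is not None]
        if any(af >= config.max_pop_af for af in afs):
            rejected["pop_af"] += 1
            continue
        kept.append(v)
    return FilterResult(kept=kept, rejected=rejected)


# ---------------------------------------------------------------------------
# classification

def classify_variant(v: VariantRecord,
                     config: FilterConfig = FilterConfig()) -> ClassifiedVariant:
    """Deterministic functional classification of a filtered variant.

    Functionality: known-benign variants are NEUTRAL; recurrent variants
    that are strongly deleterious (CADD phred above threshold) or
    truncating are RELEVANT; everything else is INCONCLUSIVE.

    Mechanism: truncating effects — or deleterious missense in a tumor
    suppressor — are loss-of-function; recurrent alterations in an
    oncogene are gain-of-function; otherwise unknown.

    A variant is a VUS when functionally inconclusive and not recurrent;
    VUS are excluded from both terms of the matching score.
    """
    cadd_deleterious = (v.cadd_phred is not None
                        and v.cadd_phred > config.cadd_deleterious_threshold)

    if v.known_benign_flag:
        functionality = Functionality.NEUTRAL
    elif v.recurrence_flag and (cadd_deleterious
                                or v.effect in TRUNCATING_EFFECTS):
        functionality = Functionality.RELEVANT
    else:
        functionality = Functionality.INCONCLUSIVE

    if v.effect in TRUNCATING_EFFECTS or (
            v.gene_role is VariantGeneRole.TSG
            and v.effect is Effect.MISSENSE and cadd_deleterious):
        mechanism = Mechanism.LOF
    elif v.gene_role is VariantGeneRole.ONCOGENE and v.recurrence_flag:
        mechanism = Mechanism.GOF
    else:
        mechanism = Mechanism.UNKNOWN

    is_vus = (functionality is Functionality.INCONCLUSIVE
              and not v.recurrence_flag)
    return ClassifiedVariant(variant=v, functionality=functionality,
                             mechanism=mechanism, is_vus=is_vus)


def mutation_type_summary(classified: Sequence[ClassifiedVariant]) -> dict:
    """Proportions of variants by effect class and by mechanism.

    Returns ``{"empty": bool, "by_effect": {...}, "by_mechanism": {...}}``;
    proportions sum to 1 for non-empty input.
    """
    if not classified:
        return {"empty": True, "by_effect": {}, "by_mechanism": {}}
    n = len(classified)
    by_effect: dict = {}
    by_mechanism: dict = {}
    for cv in classified:
        by_effect[cv.variant.effect.value] = \
            by_effect.get(cv.variant.effect.value, 0) + 1
        by_mechanism[cv.mechanism.value] = \
            by_mechanism.get(cv.mechanism.value, 0) + 1
    return {
        "empty": False,
        "by_effect": {k: c / n for k, c in sorted(by_effect.items())},
        "by_mechanism": {k: c / n for k, c in sorted(by_mechanism.items())},
    }
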