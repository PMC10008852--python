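"""Local actionability knowledge base.

One :class:`KnowledgeBaseEntry` encodes a single actionability rule:
a target (gene for mutations, surface marker for IHC, or a genomic
biomarker state such as TMB-high) mapped to a drug or drug combination,
graded on the NCT/DKTK and ESCAT scales, carrying regulatory approval
status and a mechanism-of-action treatment basket.  The file stands in
for manual database research across COSMIC/OncoKB/ClinVar/cBioPortal and
CIViC/OncoKB/CGI/DGIdb: the curated end result of that chain is frozen
into a reviewable TSV (or JSON) snapshot.

Resistance knowledge lives in the same file: an entry flagged as a
resistance exclusion names a triggering target plus the drug class that
must be withheld when that target is altered (e.g. CDK4/6 inhibitors in
TP53-mutant disease).

TSV dialect
-----------
Header columns: ``target_id  modality  role  drugs  nct  escat  approval
basket  drug_class  flags  notes``.  Within ``drugs``, ``+`` joins the
components of one combination (a single entry, one evidence level, one
basket) and ``;`` separates alternative agents, which become separate
entries on load.  ``approval`` is ``/``-separated; ``-`` marks an empty
optional cell.
"""

from __future__ import annotations

import csv
import dataclasses
import datetime
import enum
import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

from .evidence import (
    ApprovalStatus,
    Basket,
    ELIGIBLE_APPROVALS,
    EscatTier,
    EvidenceLevelNCT,
)

logger = logging.getLogger(__name__)

KB_COLUMNS = [
    "target_id", "modality", "role", "drugs", "nct", "escat",
    "approval", "basket", "drug_class", "flags", "notes",
]


class TargetModality(enum.Enum):
    MUTATION = "MUTATION"
    IHC = "IHC"
    TMB_HIGH = "TMB_HIGH"
    MSI_HIGH = "MSI_HIGH"
    BRCANESS = "BRCANESS"


class GeneRole(enum.Enum):
    ONCOGENE = "ONCOGENE"
    TSG = "TSG"
    ANY = "ANY"


class KBValidationError(ValueError):
    """A knowledge-base entry or file violates the schema."""


@dataclasses.dataclass(frozen=True)
class KnowledgeBaseEntry:
    target_id: str
    target_modality: TargetModality
    required_role: GeneRole
    drugs: tuple[str, ...]          # >1 component = one combination
    nct_level: EvidenceLevelNCT
    escat_tier: EscatTier
    approval: frozenset
    basket: Basket
    drug_class: str = ""
    is_resistance_exclusion: bool = False
    excluded_drug_class: str = ""
    notes: str = ""

    @property
    def drug_label(self) -> str:
        return " + ".join(self.drugs)

    @property
    def is_combination(self) -> bool:
        return len(self.drugs) > 1

    @property
    def approval_eligible(self) -> bool:
        """Meets the study minimum: approval or fast-track designation."""
        return bool(self.approval & ELIGIBLE_APPROVALS)

    def validate(self) -> None:
        if not self.drugs or any(not d.strip() for d in self.drugs):
            raise KBValidationError(
                f"entry {self.target_id}: drugs must be non-empty")
        if not self.is_resistance_exclusion and not self.approval_eligible:
            raise KBValidationError(
                f"entry {self.target_id}/{self.drug_label}: no eligible "
                "approval status (needs FDA/EMA approval or fast-track "
                "designation, or the resistance-exclusion flag)")
        if self.is_resistance_exclusion and not self.excluded_drug_class:
            raise KBValidationError(
                f"entry {self.target_id}: resistance exclusion without an "
                "excluded drug class")


@dataclasses.dataclass
class KnowledgeBase:
    entries: list
    version: str = "0"
    source_date: str = ""
    dropped: int = 0   # lenient-mode load: invalid entries discarded

    def __post_init__(self) -> None:
        seen = set()
        for e in self.entries:
            key = (e.target_id, e.target_modality, e.drugs)
            if key in seen:
                raise KBValidationError(f"duplicate KB entry {key}")
            seen.add(key)

    @property
    def therapeutic_entries(self) -> list:
        return [e for e in self.entries if not e.is_resistance_exclusion]

    @property
    def exclusion_entries(self) -> list:
        return [e for e in self.entries if e.is_resistance_exclusion]


def _parse_enum(cls, token: str, row: int):
    token = token.strip()
    try:
        return cls(token)
    except ValueError:
        raise KBValidationError(
            f"row {row}: unknown {cls.__name__} code {token!r}") from None


def _parse_approval(cell: str, row: int) -> frozenset:
    tokens = [t.strip().replace("-", "_") for t in cell.split("/") if t.strip()]
    if not tokens:
        return frozenset({ApprovalStatus.NONE})
    return frozenset(_parse_enum(ApprovalStatus, t, row) for t in tokens)


def _entries_from_row(rec: dict, row: int) -> list:
    """Expand one tabular row into entries (';' = alternative agents)."""
    missing = [c for c in ("target_id", "modality", "drugs", "nct",
                           "escat", "approval", "basket") if c not in rec]
    if missing:
        raise KBValidationError(f"missing required column/field: {missing[0]}")
    flags = {f.strip() for f in (rec.get("flags") or "").split(",") if f.strip() and f.strip() != "-"}
    is_exclusion = "exclusion" in flags
    entries = []
    for alternative in str(rec["drugs"]).split(";"):
        drugs = tuple(d.strip() for d in alternative.split("+") if d.strip())
        entry = KnowledgeBaseEntry(
            target_id=str(rec["target_id"]).strip(),
            target_modality=_parse_enum(TargetModality, str(rec["modality"]), row),
            required_role=_parse_enum(GeneRole, str(rec.get("role") or "ANY"), row),
            drugs=drugs,
            nct_level=_parse_enum(EvidenceLevelNCT, str(rec["nct"]), row),
            escat_tier=_parse_enum(EscatTier, str(rec["escat"]), row),
            approval=_parse_approval(str(rec["approval"]), row),
            basket=_parse_enum(Basket, str(rec["basket"]), row),
            drug_class=_none_if_dash(rec.get("drug_class")),
            is_resistance_exclusion=is_exclusion,
            excluded_drug_class=_none_if_dash(rec.get("excluded_drug_class"))
            or (_none_if_dash(rec.get("drug_class")) if is_exclusion else ""),
            notes=_none_if_dash(rec.get("notes")),
        )
        entries.append(entry)
    return entries


def _none_if_dash(value) -> str:
    if value is None:
        return ""
    value = str(value).strip()
    return "" if value == "-" else value


def load_knowledge_base(path, strict: bool = True) -> KnowledgeBase:
    """Load and validate a knowledge base from TSV or JSON.

    In strict mode any invalid entry raises :class:`KBValidationError`;
    in lenient mode invalid entries are dropped with a logged warning and
    counted in ``KnowledgeBase.dropped``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        rows = payload.get("entries", [])
        version = str(payload.get("version", "0"))
        source_date = str(payload.get("source_date", ""))
    else:
        with path.open(newline="") as fh:
            reader = csv.DictReader(fh, delimiter="\t")
            if reader.fieldnames is None:
                rows = []
            else:
                for col in ("target_id", "modality", "drugs"):
                    if col not in reader.fieldnames:
                        raise KBValidationError(
                            f"missing required column/field: {col}")
                rows = [r for r in reader
                        if any((v or "").strip() for v in r.values())]
        version, source_date = "0", ""

    entries: list = []
    dropped = 0
    for i, rec in enumerate(rows, start=2):  # header = line 1
        try:
            for entry in _entries_from_row(rec, i):
                entry.validate()
                entries.append(entry)
        except KBValidationError as exc:
            if strict:
                raise
            dropped += 1
            logger.warning("dropping invalid KB row %d: %s", i, exc)
    if not entries:
        logger.warning("knowledge base %s has no entries", path)
    return KnowledgeBase(entries=entries, version=version,
                         source_date=source_date or
                         datetime.date.today().isoformat(),
                         dropped=dropped)


def write_knowledge_base(kb: KnowledgeBase, path) -> Path:
    """Serialize a KB back to the TSV dialect (round-trip safe)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(KB_COLUMNS)
        for e in kb.entries:
            writer.writerow([
                e.target_id,
                e.target_modality.value,
                e.required_role.value,
                "+".join(e.drugs),
                e.nct_level.value,
                e.escat_tier.value,
                "/".join(sorted(a.value for a in e.approval)),
                e.basket.value,
                e.drug_class or "-",
                "exclusion" if e.is_resistance_exclusion else "-",
                e.notes or "-",
            ])
    return path


def lookup(kb: KnowledgeBase, target_id: str,
           modality: TargetModality) -> list:
    """All therapeutic entries for a target, strongest evidence first.

    Sort: NCT/DKTK level descending, ties broken by ESCAT tier then by
    lexicographic drug label.  No match is a valid empty result.
    """
    matches = [e for e in kb.therapeutic_entries
               if e.target_id == target_id and e.target_modality == modality]
    matches.sort(key=lambda e: (-e.nct_level.rank, -e.escat_tier.rank,
                                e.drug_label))
    return matches


def resistance_exclusions_for(kb: KnowledgeBase,
                              mutated_genes: Iterable[str]) -> list:
    """Exclusion rules triggered by the case's mutated genes."""
    mutated = set(mutated_genes)
    return [e for e in kb.exclusion_entries if e.target_id in mutated]


def paper_kb_path() -> Path:
    """Path of the bundled 14-case study knowledge base snapshot."""
    return Path(__file__).parent / "data" / "kb_paper.tsv"


def minimal_kb_path() -> Path:
    return Path(__file__).parent / "data" / "kb_minimal.tsv"
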