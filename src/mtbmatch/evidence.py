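"""Evidence scales and categorical vocabularies for therapy matching.

Two external grading scales are modelled: the German NCT/DKTK MASTER
molecular evidence levels (m1A strongest ... m4 weakest; m1 = evidence in
the same entity, m2 = other entity, m3 = in-vitro, m4 = biological
rationale; suffix A/B/C = prospective trial / retrospective cohort / case
evidence) and the ESMO Scale for Clinical Actionability of molecular
Targets (ESCAT, tiers IA strongest ... V, plus X for lack of evidence).
Treatment baskets follow the Horak et al. mechanism-of-action grouping
(TK, PAM, CC, RME, IE, OTH) extended with a B-cell-target basket (BCT)
for surface markers addressable by antibody(-conjugate) therapy.
"""

from __future__ import annotations

import enum


class EvidenceLevelNCT(enum.Enum):
    """NCT/DKTK molecular evidence level; total order m1A > ... > m4."""

    m1A = "m1A"
    m1B = "m1B"
    m1C = "m1C"
    m2A = "m2A"
    m2B = "m2B"
    m2C = "m2C"
    m3 = "m3"
    m4 = "m4"

    @property
    def rank(self) -> int:
        """Higher rank = stronger evidence (m1A = 8 ... m4 = 1)."""
        return _NCT_RANK[self]

    def __lt__(self, other: "EvidenceLevelNCT") -> bool:
        if not isinstance(other, EvidenceLevelNCT):
            return NotImplemented
        return self.rank < other.rank

    def __le__(self, other: "EvidenceLevelNCT") -> bool:
        if not isinstance(other, EvidenceLevelNCT):
            return NotImplemented
        return self.rank <= other.rank

    def __gt__(self, other: "EvidenceLevelNCT") -> bool:
        if not isinstance(other, EvidenceLevelNCT):
            return NotImplemented
        return self.rank > other.rank

    def __ge__(self, other: "EvidenceLevelNCT") -> bool:
        if not isinstance(other, EvidenceLevelNCT):
            return NotImplemented
        return self.rank >= other.rank


_NCT_ORDER = [
    EvidenceLevelNCT.m1A,
    EvidenceLevelNCT.m1B,
    EvidenceLevelNCT.m1C,
    EvidenceLevelNCT.m2A,
    EvidenceLevelNCT.m2B,
    EvidenceLevelNCT.m2C,
    EvidenceLevelNCT.m3,
    EvidenceLevelNCT.m4,
]
_NCT_RANK = {lvl: len(_NCT_ORDER) - i for i, lvl in enumerate(_NCT_ORDER)}


class EscatTier(enum.Enum):
    """ESCAT actionability tier; total order IA > IB > ... > V > X."""

    IA = "IA"
    IB = "IB"
    IC = "IC"
    IIA = "IIA"
    IIB = "IIB"
    IIIA = "IIIA"
    IIIB = "IIIB"
    IVA = "IVA"
    IVB = "IVB"
    V = "V"
    X = "X"

    @property
    def rank(self) -> int:
        return _ESCAT_RANK[self]

    def __lt__(self, other: "EscatTier") -> bool:
        if not isinstance(other, EscatTier):
            return NotImplemented
        return self.rank < other.rank

    def __le__(self, other: "EscatTier") -> bool:
        if not isinstance(other, EscatTier):
            return NotImplemented
        return self.rank <= other.rank

    def __gt__(self, other: "EscatTier") -> bool:
        if not isinstance(other, EscatTier):
            return NotImplemented
        return self.rank > other.rank

    def __ge__(self, other: "EscatTier") -> bool:
        if not isinstance(other, EscatTier):
            return NotImplemented
        return self.rank >= other.rank


_ESCAT_ORDER = [
    EscatTier.IA, EscatTier.IB, EscatTier.IC,
    EscatTier.IIA, EscatTier.IIB,
    EscatTier.IIIA, EscatTier.IIIB,
    EscatTier.IVA, EscatTier.IVB,
    EscatTier.V, EscatTier.X,
]
_ESCAT_RANK = {t: len(_ESCAT_ORDER) - i for i, t in enumerate(_ESCAT_ORDER)}


class Basket(enum.Enum):
    """Mechanism-of-action treatment basket."""

    TK = "TK"
    PAM = "PAM"
    CC = "CC"
    RME = "RME"
    IE = "IE"
    BCT = "BCT"
    OTH = "OTH"

    @property
    def label(self) -> str:
        return _BASKET_LABELS[self]


_BASKET_LABELS = {
    Basket.TK: "tyrosine kinases",
    Basket.PAM: "PI3K-MTOR-AKT pathway",
    Basket.CC: "cell cycle alterations",
    Basket.RME: "RAF-MEK-ERK cascade",
    Basket.IE: "immune evasion",
    Basket.BCT: "B-cell targets",
    Basket.OTH: "others",
}


class ApprovalStatus(enum.Enum):
    FDA = "FDA"
    EMA = "EMA"
    FDA_FT = "FDA_FT"
    EMA_FT = "EMA_FT"
    NONE = "NONE"


#: Approval statuses meeting the study's minimum bar for a recommendable
#: drug: regulatory approval by FDA and/or EMA, or at minimum a fast-track
#: development designation.
ELIGIBLE_APPROVALS = frozenset({
    ApprovalStatus.FDA,
    ApprovalStatus.EMA,
    ApprovalStatus.FDA_FT,
    ApprovalStatus.EMA_FT,
})


def compare_evidence(a: EvidenceLevelNCT, b: EvidenceLevelNCT) -> int:
    """Compare two NCT/DKTK evidence levels.

    Returns +1 if ``a`` is the stronger level, -1 if ``b`` is stronger,
    0 on equality.  Agents addressing the same target are preferred by the
    highest level on this scale (e.g. daratumumab m1C over isatuximab m2A).
    """
    if not isinstance(a, EvidenceLevelNCT) or not isinstance(b, EvidenceLevelNCT):
        raise TypeError("compare_evidence expects two EvidenceLevelNCT values")
    if a.rank > b.rank:
        return 1
    if a.rank < b.rank:
        return -1
    return 0


def approval_sort_key(approvals: frozenset) -> int:
    """Preference order among equal-evidence drugs: full approval before
    fast-track-only, before none."""
    if approvals & {ApprovalStatus.FDA, ApprovalStatus.EMA}:
        return 0
    if approvals & {ApprovalStatus.FDA_FT, ApprovalStatus.EMA_FT}:
        return 1
    return 2
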