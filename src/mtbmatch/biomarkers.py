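"""Case-level genomic biomarkers.

Covers tumor mutational burden (TMB, mutations per megabase of
interrogated exome, with the >= 10 mut/Mb immunotherapy cutoff),
mutational-signature refitting of a 96-context single-base-substitution
catalog by non-negative least squares, the SBS6-based BRCAness score
(homologous-recombination-deficiency surrogate, positive at >= 20%
exposure), the SBS26 mismatch-repair-deficiency predominance flag, and
consumption of an upstream microsatellite-instability score.

The bundled signature reference is a *synthetic* matrix: simplified
probability profiles peaked at each signature's characteristic contexts
(SBS1 C>T at NpCpG, SBS6/SBS26 MMR-deficiency-like, SBS5 flat-ish clock,
plus a uniform background).  It is sufficient for refitting and testing;
a COSMIC-format matrix can be loaded in its place with
:func:`load_reference_signatures`.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .variants import ClassifiedVariant, Effect, VariantRecord

SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
BASES = ["A", "C", "G", "T"]

#: COSMIC ordering of the 96 pyrimidine-centred trinucleotide contexts.
CONTEXTS_96 = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]

DEFAULT_SIGNATURES = ["SBS1", "SBS5", "SBS6", "SBS26", "BG"]


@dataclasses.dataclass
class MutationCatalog:
    """96-vector of trinucleotide-context substitution counts."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError(
                f"catalog must have exactly 96 entries, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("catalog counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_series(cls, series: pd.Series) -> "MutationCatalog":
        return cls(series.reindex(CONTEXTS_96).fillna(0.0).to_numpy())

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=CONTEXTS_96, name="count")


@dataclasses.dataclass
class SignatureExposures:
    exposures: dict           # signature name -> fraction
    residual: float = 0.0
    empty: bool = False

    def fraction(self, name: str) -> float:
        return self.exposures.get(name, 0.0)


@dataclasses.dataclass
class BiomarkerPanel:
    """Per-case biomarker summary feeding the recommendation engine."""

    tmb: float = 0.0
    tmb_high: bool = False
    msi_score: Optional[float] = None
    msi_high: bool = False
    msi_untested: bool = False
    brcaness_fraction: float = 0.0
    brcaness_positive: bool = False
    mmrd_predominant: bool = False

    def __post_init__(self) -> None:
        if self.tmb < 0:
            raise ValueError("TMB must be non-negative")


# ---------------------------------------------------------------------------
# TMB

def compute_tmb(variants: Sequence, exome_size_mb: float = 30.0) -> float:
    """Mutations per megabase over the filtered variant list.

    Eligible variants are non-synonymous SNVs and indels; synonymous
    calls are excluded.  Accepts plain or classified variant records.
    The exome denominator is a configuration choice (default 30 Mb).
    """
    if exome_size_mb <= 0:
        raise ValueError("exome_size_mb must be positive")
    eligible = 0
    for item in variants:
        v = item.variant if isinstance(item, ClassifiedVariant) else item
        if v.effect is not Effect.SYNONYMOUS:
            eligible += 1
    return eligible / exome_size_mb


# ---------------------------------------------------------------------------
# signature refitting

def _peaked_profile(rng: np.random.Generator, peak_mask: np.ndarray,
                    peak_weight: float) -> np.ndarray:
    base = rng.uniform(0.2, 1.0, size=96)
    profile = base * (1.0 - peak_weight) / base[~peak_mask].sum() \
        if peak_mask.any() else base / base.sum()
    if peak_mask.any():
        peaks = rng.uniform(0.5, 1.0, size=int(peak_mask.sum()))
        profile = np.where(peak_mask, 0.0, profile)
        profile[peak_mask] = peaks / peaks.sum() * peak_weight
    return profile / profile.sum()


def synthetic_reference_signatures(
        names: Sequence[str] = DEFAULT_SIGNATURES) -> pd.DataFrame:
    """Deterministic synthetic 96xS signature reference matrix.

    Each column is a probability vector concentrated on that signature's
    characteristic context family; columns are mutually distinguishable,
    which is what refitting needs.  Not COSMIC data.
    """
    rng = np.random.default_rng(96)
    ctx = np.array(CONTEXTS_96)
    sub = np.array([c[2:5] for c in ctx])
    three = np.array([c[-1] for c in ctx])
    masks = {
        "SBS1": (sub == "C>T") & (three == "G"),            # NpCpG deamination
        "SBS5": (sub == "T>G"),                              # broad, distinct
        "SBS6": (sub == "C>T") & (three != "G"),             # MMRd-like C>T
        "SBS26": (sub == "T>C"),                             # MMRd-like T>C
    }
    cols = {}
    for name in names:
        if name == "BG":                                     # uniform floor
            cols[name] = np.full(96, 1.0 / 96)
            continue
        mask = masks.get(name, np.zeros(96, dtype=bool))
        cols[name] = _peaked_profile(rng, mask, 0.85)
    return pd.DataFrame(cols, index=CONTEXTS_96)


def load_reference_signatures(path) -> pd.DataFrame:
    """Load a COSMIC-style TSV (context rows x signature columns)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = set(CONTEXTS_96) - set(df.index)
    if missing:
        raise ValueError(f"reference matrix lacks {len(missing)} contexts")
    df = df.loc[CONTEXTS_96]
    return df / df.sum(axis=0)


def bundled_reference_path() -> Path:
    return Path(__file__).parent / "data" / "signatures_synthetic.tsv"


def default_reference_signatures() -> pd.DataFrame:
    path = bundled_reference_path()
    if path.exists():
        return load_reference_signatures(path)
    return synthetic_reference_signatures()


def refit_signatures(catalog: MutationCatalog,
                     reference: pd.DataFrame) -> SignatureExposures:
    """Non-negative least-squares refit of a catalog against reference
    signature profiles; exposures are normalized to fractions and the
    residual is the Euclidean norm of the unexplained counts divided by
    the total mutation count."""
    matrix = reference.to_numpy(dtype=float)
    if matrix.shape[0] != 96:
        raise ValueError("reference must have 96 context rows")
    total = catalog.total
    if total == 0:
        return SignatureExposures(
            exposures={name: 0.0 for name in reference.columns},
            residual=0.0, empty=True)
    weights, rnorm = nnls(matrix, catalog.counts)
    weight_sum = weights.sum()
    if weight_sum == 0:
        fractions = np.zeros_like(weights)
    else:
        fractions = weights / weight_sum
    return SignatureExposures(
        exposures={name: float(f)
                   for name, f in zip(reference.columns, fractions)},
        residual=float(rnorm) / total,
    )


# ---------------------------------------------------------------------------
# derived flags

def brcaness_score(exposures: SignatureExposures,
                   cutoff: float = 0.20) -> tuple:
    """SBS6 exposure fraction and positivity at the inclusive cutoff."""
    if "SBS6" not in exposures.exposures:
        raise KeyError("SBS6 missing from fitted signature set")
    fraction = exposures.fraction("SBS6")
    return fraction, fraction >= cutoff


def mmrd_flag(exposures: SignatureExposures) -> bool:
    """True iff SBS26 carries the strictly largest exposure (ties are
    conservatively not predominant)."""
    if not exposures.exposures:
        return False
    sbs26 = exposures.fraction("SBS26")
    others = [f for name, f in exposures.exposures.items() if name != "SBS26"]
    return bool(others) and all(sbs26 > f for f in others) or \
        (not others and sbs26 > 0)


def msi_status(score: Optional[float], threshold: float = 10.0) -> tuple:
    """(msi_high, untested).  Missing scores are untested, never high."""
    if score is None:
        return False, True
    if score < 0:
        raise ValueError("MSI score must be non-negative")
    return score >= threshold, False


def biomarker_panel(variants: Sequence,
                    exome_size_mb: float = 30.0,
                    tmb_high_cutoff: float = 10.0,
                    catalog: Optional[MutationCatalog] = None,
                    reference: Optional[pd.DataFrame] = None,
                    msi_score: Optional[float] = None,
                    msi_threshold: float = 10.0,
                    brcaness_cutoff: float = 0.20) -> BiomarkerPanel:
    """Assemble the full biomarker panel for one case."""
    tmb = compute_tmb(variants, exome_size_mb)
    brca_frac, brca_pos, mmrd = 0.0, False, False
    if catalog is not None:
        ref = reference if reference is not None \
            else default_reference_signatures()
        exposures = refit_signatures(catalog, ref)
        brca_frac, brca_pos = brcaness_score(exposures, brcaness_cutoff)
        mmrd = mmrd_flag(exposures)
    msi_high, untested = msi_status(msi_score, msi_threshold)
    return BiomarkerPanel(
        tmb=tmb, tmb_high=tmb >= tmb_high_cutoff,
        msi_score=msi_score, msi_high=msi_high, msi_untested=untested,
        brcaness_fraction=brca_frac, brcaness_positive=brca_pos,
        mmrd_predominant=mmrd,
    )
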