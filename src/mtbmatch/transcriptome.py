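"""Expression-based verification of candidate driver mutations.

A mutated oncogene is biologically conclusive when the case's expression
of that gene is at or above the cohort average (within-cohort z >= 0);
a tumor suppressor when at or below it (z <= 0).  Cases without RNA-seq
yield PROVISIONAL calls — the mutation stays a candidate but cannot be
promoted to a verified driver.  A simplified per-sample gene-set score
(background-centred mean z of member genes) stands in for gene-set
variation analysis; it is descriptive only and never gates a
recommendation.
"""

from __future__ import annotations

import dataclasses
import enum
from typing import Sequence

import numpy as np
import pandas as pd

from .kb import GeneRole


class Conclusiveness(enum.Enum):
    CONCLUSIVE = "CONCLUSIVE"
    INCONCLUSIVE = "INCONCLUSIVE"
    PROVISIONAL = "PROVISIONAL"


@dataclasses.dataclass(frozen=True)
class ConclusivenessCall:
    gene: str
    role: GeneRole
    zscore: float | None
    call: Conclusiveness
    note: str = ""


class ExpressionMatrix:
    """Genes x samples matrix of log-scale normalized expression."""

    def __init__(self, values: pd.DataFrame):
        if values.index.duplicated().any():
            raise ValueError("duplicate gene symbols in expression matrix")
        self._df = values.astype(float)

    @property
    def genes(self) -> list:
        return list(self._df.index)

    @property
    def samples(self) -> list:
        return list(self._df.columns)

    @property
    def values(self) -> pd.DataFrame:
        return self._df

    def zscores(self) -> pd.DataFrame:
        """Within-cohort z-score of each gene across all samples."""
        mean = self._df.mean(axis=1)
        std = self._df.std(axis=1, ddof=0)
        z = self._df.sub(mean, axis=0).div(std.replace(0.0, np.nan), axis=0)
        return z.fillna(0.0)

    @classmethod
    def read_tsv(cls, path) -> "ExpressionMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path) -> None:
        self._df.to_csv(path, sep="\t")


def conclusiveness_check(gene: str, role: GeneRole, case_id: str,
                         expr: ExpressionMatrix | None) -> ConclusivenessCall:
    """Verify a candidate driver against the case's expression.

    Oncogenes are expected over- (z >= 0), tumor suppressors
    under-expressed (z <= 0); expression exactly at the cohort mean never
    blocks a candidate.  Absent case or matrix -> PROVISIONAL; absent
    gene row -> PROVISIONAL with a gene-unmeasured note.
    """
    if role not in (GeneRole.ONCOGENE, GeneRole.TSG):
        raise ValueError(f"role must be ONCOGENE or TSG, got {role}")
    if expr is None or str(case_id) not in map(str, expr.samples):
        return ConclusivenessCall(gene, role, None, Conclusiveness.PROVISIONAL,
                                  note="no RNA-seq for case")
    if gene not in expr.genes:
        return ConclusivenessCall(gene, role, None, Conclusiveness.PROVISIONAL,
                                  note="gene-unmeasured")
    col = [s for s in expr.samples if str(s) == str(case_id)][0]
    z = float(expr.zscores().loc[gene, col])
    if role is GeneRole.ONCOGENE:
        ok = z >= 0
    else:
        ok = z <= 0
    return ConclusivenessCall(
        gene, role, z,
        Conclusiveness.CONCLUSIVE if ok else Conclusiveness.INCONCLUSIVE)


def gene_set_score(case_id: str, gene_set: Sequence[str],
                   expr: ExpressionMatrix) -> tuple:
    """Background-centred mean-z gene-set score for one case.

    Mean within-cohort z-score of the measured member genes minus the
    mean z over *all* measured genes for that case.  Returns
    (score, coverage) where coverage is the fraction of the set measured.
    The all-genes set scores exactly 0 by construction.
    """
    if not gene_set:
        raise ValueError("gene_set must be non-empty")
    members = [g for g in dict.fromkeys(gene_set) if g in expr.genes]
    if not members:
        raise ValueError("set not represented: no member gene measured")
    col = [s for s in expr.samples if str(s) == str(case_id)]
    if not col:
        raise KeyError(f"case {case_id} absent from expression matrix")
    z = expr.zscores()[col[0]]
    score = float(z.loc[members].mean() - z.mean())
    return score, len(members) / len(dict.fromkeys(gene_set))
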