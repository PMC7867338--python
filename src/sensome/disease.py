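"""Apply the core sensome to disease/aging DE tables and summarise directions.

Disease datasets enter as published differential-expression summaries
(gene, log2FC, adjusted p), one table per condition; raw reads are never
reprocessed here.  Each core gene is called up, down, or non-significant per
condition — up/down require adjusted p strictly below alpha, with the sign of
the fold change deciding the direction — and genes missing from a table are
"absent", never imputed.  A cross-condition helper reports the genes moving
in one consistent direction everywhere they are observed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .enrichment import size_factors
from .exceptions import ConfigError, ValidationError
from .io import CountMatrix

logger = logging.getLogger("sensome")

__all__ = [
    "DiseaseDEResult",
    "DiseaseChangeTable",
    "core_changes",
    "cross_condition_consistency",
    "heatmap_matrix",
]

DIRECTIONS = ("up", "down", "ns", "absent")


@dataclass
class DiseaseDEResult:
    """One condition's DE summary: log2fc and padj per gene symbol."""

    condition_label: str
    table: pd.DataFrame  # index gene; columns log2fc, padj

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(
                f"{self.condition_label}: duplicate gene {dup!r} in DE table"
            )
        padj = self.table["padj"]
        if ((padj < 0) | (padj > 1)).any():
            raise ValidationError(f"{self.condition_label}: padj outside [0, 1]")


@dataclass
class DiseaseChangeTable:
    """Direction call (up/down/ns/absent) per core gene for one condition."""

    condition_label: str
    direction: dict[str, str]
    alpha: float

    def genes_with(self, direction: str) -> list[str]:
        return sorted(g for g, d in self.direction.items() if d == direction)


def core_changes(
    core_genes: list[str], de: DiseaseDEResult, alpha: float = 0.05
) -> DiseaseChangeTable:
    """Call each core gene's direction of change in one condition.

    up: padj < alpha and log2fc > 0; down: padj < alpha and log2fc < 0;
    ns: padj >= alpha (strict inequalities, so padj exactly alpha is ns);
    absent: gene not in the table.
    """
    if not 0.0 < alpha < 1.0:
        raise ConfigError("alpha must lie in (0, 1)")
    if not core_genes:
        raise ValidationError("core gene list is empty")
    by_key = {g.casefold(): g for g in de.table.index}
    calls: dict[str, str] = {}
    for gene in core_genes:
        key = gene.casefold()
        if key not in by_key:
            calls[gene] = "absent"
            continue
        row = de.table.loc[by_key[key]]
        if row["padj"] < alpha and row["log2fc"] > 0:
            calls[gene] = "up"
        elif row["padj"] < alpha and row["log2fc"] < 0:
            calls[gene] = "down"
        else:
            calls[gene] = "ns"
    return DiseaseChangeTable(
        condition_label=de.condition_label, direction=calls, alpha=alpha
    )


def cross_condition_consistency(
    tables: list[DiseaseChangeTable],
) -> tuple[pd.DataFrame, set[str]]:
    """Per-gene direction across conditions plus the uniformly-moving genes.

    Returns a genes-by-conditions direction matrix and the set of genes
    present in every condition with the same non-ns direction throughout.
    The result does not depend on the order of the input tables.
    """
    if len(tables) < 2:
        raise ValidationError("need at least 2 condition tables")
    genes = sorted({g for t in tables for g in t.direction})
    labels = [t.condition_label for t in tables]
    matrix = pd.DataFrame(index=genes, columns=labels, dtype=object)
    for t in tables:
        for g, d in t.direction.items():
            matrix.at[g, t.condition_label] = d
    matrix = matrix.fillna("absent")

    consistent: set[str] = set()
    for g in genes:
        dirs = set(matrix.loc[g])
        if len(dirs) == 1 and dirs <= {"up", "down"}:
            consistent.add(g)
    if not consistent:
        logger.warning("cross_condition_consistency: no uniformly changed genes")
    return matrix, consistent


def heatmap_matrix(m: CountMatrix, genes: list[str]) -> pd.DataFrame:
    """Shifted-log normalised expression for heatmap export.

    Values are log2(size-factor-normalised count + 1); rows follow the
    requested gene order, genes missing from the matrix are warned and
    dropped.  Size factors are rescaled to geometric mean 1 before use, so
    rescaling one sample's library leaves every other sample's values exactly
    unchanged.
    """
    present = [g for g in genes if g in m.counts.index]
    missing = [g for g in genes if g not in m.counts.index]
    if missing:
        logger.warning("heatmap_matrix: %d genes not in matrix: %s%s",
                       len(missing), missing[:5], "..." if len(missing) > 5 else "")
    sf = size_factors(m)
    sf_vec = np.array([sf[s] for s in m.sample_ids])
    sf_vec = sf_vec / np.exp(np.mean(np.log(sf_vec)))
    sub = m.counts.loc[present].to_numpy(dtype=float) / sf_vec[None, :]
    return pd.DataFrame(np.log2(sub + 1.0), index=present, columns=m.sample_ids)
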