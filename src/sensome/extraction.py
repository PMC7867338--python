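"""Staged sensome extraction: GO membrane filter, top-expression bar, curation.

The full pipeline composes, in order: sample QC, the microglia-vs-tissue
enrichment gate, membership in one of four membrane/receptor GO terms,
a top-25% microglial-expression bar, and curation down to a fixed-size
ordered gene set.  An expression-only mode skips the enrichment gate for
designs without a tissue comparator (e.g. single-cell-derived microglia
profiles) and ranks purely by mean microglial expression.

Curation is a human verdict supplied in the annotation table (verified /
rejected / unknown), never computed here; the verification rubric — the
encoded protein sits in the plasma membrane, is not secreted, and transduces
an extracellular signal — is documentation for the curator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .enrichment import (
    EnrichmentResult,
    candidate_enriched,
    enrichment_test,
    expression_summary,
    sample_qc,
)
from .exceptions import ConfigError, ValidationError
from .io import CountMatrix, GeneAnnotationTable, SensomeSet
from .vocab import MEMBRANE_GO_TERMS

logger = logging.getLogger("sensome")

__all__ = ["ExtractionConfig", "go_membrane_filter", "top_quantile_filter",
           "apply_curation", "extract_sensome"]


@dataclass
class ExtractionConfig:
    """Tunable thresholds of the extraction pipeline.

    ``quantile_universe`` chooses the gene pool over which the
    top-expression cut is computed: ``"all"`` (a transcriptome-wide bar,
    the default) or ``"candidates"`` (the bar among surviving candidates
    only).
    """

    go_terms: set[str] = field(default_factory=lambda: set(MEMBRANE_GO_TERMS))
    top_fraction: float = 0.25
    target_size: int = 100
    use_enrichment: bool = True
    lfc_min: float = 2.0
    fdr: float = 0.05
    quantile_universe: str = "all"
    species: str = "mouse"
    source_label: str = "extracted"

    def validate(self) -> None:
        if not self.go_terms:
            raise ConfigError("go_terms must be non-empty")
        if not 0.0 < self.top_fraction <= 1.0:
            raise ConfigError("top_fraction must lie in (0, 1]")
        if self.target_size < 1:
            raise ConfigError("target_size must be >= 1")
        if self.quantile_universe not in ("all", "candidates"):
            raise ConfigError("quantile_universe must be 'all' or 'candidates'")


def go_membrane_filter(
    genes: set[str], annot: GeneAnnotationTable, cfg: ExtractionConfig
) -> tuple[set[str], set[str]]:
    """Split ``genes`` into GO-qualified and GO-unmapped sets.

    Genes carrying at least one configured membrane/receptor GO term are
    kept.  Genes with no GO annotation at all (including genes absent from
    the table) are routed onward as *unmapped* — they survive to manual
    curation rather than being discarded.  Genes annotated only with
    non-configured terms are excluded.
    """
    cfg.validate()
    kept: set[str] = set()
    unmapped: set[str] = set()
    for g in genes:
        if g not in annot:
            unmapped.add(g)
            continue
        terms = annot.go_terms(g)
        if not terms:
            unmapped.add(g)
        elif terms & cfg.go_terms:
            kept.add(g)
    return kept, unmapped


def top_quantile_filter(
    candidates: set[str], enr: EnrichmentResult, cfg: ExtractionConfig
) -> set[str]:
    """Keep candidates at or above the (1 - top_fraction) expression quantile.

    The quantile is computed over the mean microglial expression of the
    configured universe (all tested genes by default); ties at the cut are
    included.
    """
    cfg.validate()
    if not candidates:
        logger.warning("top_quantile_filter: empty candidate set")
        return set()
    expr = enr.table["mean_microglia_expression"]
    universe = expr if cfg.quantile_universe == "all" else expr.loc[sorted(candidates)]
    cut = float(np.quantile(universe.to_numpy(), 1.0 - cfg.top_fraction))
    present = [g for g in candidates if g in expr.index]
    missing = candidates - set(present)
    if missing:
        raise ValidationError(
            f"candidates without expression values: {sorted(missing)[:3]}"
        )
    return {g for g in present if expr.at[g] >= cut}


def apply_curation(
    candidates: set[str],
    annot: GeneAnnotationTable,
    enr: EnrichmentResult,
    cfg: ExtractionConfig,
    allow_partial: bool = False,
) -> SensomeSet:
    """Reduce verified candidates to the target-size sensome.

    Candidates with curation status ``verified`` are ranked by mean
    microglial expression (rank 1 = highest; ties broken by symbol) and cut
    at ``target_size``.  ``rejected`` genes are excluded; ``unknown`` genes
    are excluded with a logged list for the user to curate.  A shortfall is
    an error unless ``allow_partial``.
    """
    cfg.validate()
    verified, unknown = [], []
    for g in candidates:
        status = annot.curation_status(g) if g in annot else "unknown"
        if status == "verified":
            verified.append(g)
        elif status == "unknown":
            unknown.append(g)
    if unknown:
        logger.info(
            "apply_curation: %d candidates with unknown curation excluded: %s%s",
            len(unknown), sorted(unknown)[:10], "..." if len(unknown) > 10 else "",
        )
    expr = enr.table["mean_microglia_expression"]
    symbols = {g: (annot.symbol(g) if g in annot else g) for g in verified}
    ranked = sorted(verified, key=lambda g: (-float(expr.at[g]), symbols[g]))
    if len(ranked) < cfg.target_size and not allow_partial:
        raise ValidationError(
            f"only {len(ranked)} verified candidates for a target of "
            f"{cfg.target_size} (shortfall {cfg.target_size - len(ranked)}); "
            "pass allow_partial to accept a smaller set"
        )
    chosen = ranked[: cfg.target_size]
    return SensomeSet(
        species=cfg.species,
        source_label=cfg.source_label,
        genes=[symbols[g] for g in chosen],
        target_size=cfg.target_size,
        partial=len(chosen) < cfg.target_size,
    )


def extract_sensome(
    m: CountMatrix,
    annot: GeneAnnotationTable,
    cfg: ExtractionConfig,
    min_genes: int = 6000,
    min_reads: int = 5,
    allow_partial: bool = False,
) -> tuple[SensomeSet, dict[str, int]]:
    """Run the full staged extraction and return the sensome plus an audit.

    The audit maps stage name to the number of genes surviving that stage;
    counts are non-increasing along the pipeline.  With
    ``cfg.use_enrichment`` false, the enrichment gate is skipped and ranking
    is by mean microglial expression alone (microglia-only designs).
    """
    cfg.validate()
    m_qc, _report = sample_qc(m, min_genes=min_genes, min_reads=min_reads)

    if cfg.use_enrichment:
        enr = enrichment_test(m_qc)
        candidates = candidate_enriched(enr, lfc_min=cfg.lfc_min, fdr=cfg.fdr)
    else:
        enr = expression_summary(m_qc)
        candidates = set(enr.table.index)

    audit = {
        "input_genes": len(m.gene_ids),
        "tested_genes": len(enr.table),
        "enriched_candidates": len(candidates),
    }

    kept, unmapped = go_membrane_filter(candidates, annot, cfg)
    # unmapped genes survive to curation alongside GO-qualified genes
    go_pool = kept | unmapped
    audit["go_membrane"] = len(go_pool)

    top = top_quantile_filter(go_pool, enr, cfg)
    audit["top_expression"] = len(top)

    sensome = apply_curation(top, annot, enr, cfg, allow_partial=allow_partial)
    audit["curated"] = len(sensome)
    return sensome, audit
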