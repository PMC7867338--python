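"""Within-species overlaps, ortholog translation, and the k-of-n core sensome.

The "core" of two same-size sensomes is their intersection and the
"extended" set their union; the percent overlap is reported relative to the
common target size (100-gene lists give the familiar whole-number percents).
Across species, sensomes are translated to a common symbol namespace through
an ortholog map and the *microglia core sensome* is the set of genes present
in at least k of the n input sensomes (k = 3 of 4 in the reference design).
All symbol matching is case-insensitive, so mouse-cased and human-cased
symbols of the same gene compare equal.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .enrichment import EnrichmentResult
from .exceptions import ConfigError, ValidationError
from .io import GeneAnnotationTable, OrthologMap, SensomeSet
from .vocab import UNCATEGORIZED

logger = logging.getLogger("sensome")

__all__ = [
    "OverlapResult",
    "ConsensusResult",
    "CategorySummary",
    "overlap",
    "map_orthologs",
    "core_sensome",
    "categorize",
    "ligand_group_profile",
    "shared_ligand_groups",
]


@dataclass
class OverlapResult:
    """Core (intersection) and extended (union) sets of two sensomes."""

    set_a_label: str
    set_b_label: str
    intersection: list[str]
    union: list[str]
    percent_overlap: float


@dataclass
class ConsensusResult:
    """Per-gene membership over n sensomes and the k-of-n core flag.

    ``table`` is indexed by symbol with one boolean column per input
    sensome label, plus ``n_present`` and ``is_core``; ordered by
    (n_present descending, symbol).
    """

    table: pd.DataFrame
    k: int

    @property
    def core_genes(self) -> list[str]:
        return list(self.table.index[self.table["is_core"]])


@dataclass
class CategorySummary:
    """Functional-group assignment and counts for a gene list."""

    per_gene: pd.DataFrame  # index symbol; columns functional_group, log2fc
    group_counts: dict[str, int]

    @property
    def modal_group(self) -> str:
        return max(self.group_counts.items(), key=lambda kv: (kv[1], kv[0]))[0]


def overlap(a: SensomeSet, b: SensomeSet) -> OverlapResult:
    """Intersection ("core") and union ("extended") of two sensome sets.

    Symbols match case-insensitively; output symbols take set ``a``'s casing
    for shared genes.  Percent overlap is 100 * |intersection| / target_size
    when the sets share a target size, otherwise relative to the smaller set
    with a warning.
    """
    if not a.genes or not b.genes:
        raise ValidationError("overlap of an empty sensome set is undefined")
    keys_b = b.symbol_keys()
    inter = [g for g in a.genes if g.casefold() in keys_b]
    keys_a = a.symbol_keys()
    union = list(a.genes) + [g for g in b.genes if g.casefold() not in keys_a]
    if a.target_size == b.target_size:
        denom = a.target_size
    else:
        denom = min(len(a.genes), len(b.genes))
        logger.warning(
            "overlap: sets %r and %r differ in target size; percent relative to %d",
            a.source_label, b.source_label, denom,
        )
    return OverlapResult(
        set_a_label=a.source_label,
        set_b_label=b.source_label,
        intersection=inter,
        union=union,
        percent_overlap=100.0 * len(inter) / denom,
    )


def map_orthologs(
    s: SensomeSet, m: OrthologMap, target_species: str
) -> tuple[SensomeSet, list[str]]:
    """Translate a sensome to ``target_species`` symbols via an ortholog map.

    Rank order is preserved.  Unmapped symbols are excluded from the
    translated set and reported.  One-to-many orthologs expand to all
    targets (logged); many-to-one collapses keep the first occurrence
    (logged).
    """
    if len(m) == 0:
        raise ValidationError("ortholog map is empty")
    translated: list[str] = []
    seen: set[str] = set()
    unmapped: list[str] = []
    for sym in s.genes:
        targets = m.forward(sym)
        if not targets:
            targets = m.reverse(sym)
        if not targets:
            unmapped.append(sym)
            continue
        if len(targets) > 1:
            logger.info("map_orthologs: %r expands to %d orthologs", sym, len(targets))
        for t in targets:
            key = t.casefold()
            if key in seen:
                logger.info("map_orthologs: many-to-one collapse at %r", t)
                continue
            seen.add(key)
            translated.append(t)
    return (
        SensomeSet(
            species=target_species,
            source_label=f"{s.source_label}->{target_species}",
            genes=translated,
            target_size=len(translated),
            partial=True,
        ),
        unmapped,
    )


def core_sensome(sets: list[SensomeSet], k: int = 3) -> ConsensusResult:
    """Genes present in at least k of the n input sensomes.

    All sets must already share one symbol namespace.  Membership is
    case-insensitive; the reported symbol casing comes from the first set in
    which the gene appears.  Rows are ordered by (n_present descending,
    symbol ascending).
    """
    n = len(sets)
    if n < 2:
        raise ConfigError("need at least 2 sensome sets")
    if not 1 <= k <= n:
        raise ConfigError(f"k must lie in [1, {n}], got {k}")
    labels = [s.source_label for s in sets]
    if len(set(labels)) != n:
        labels = [f"{lab}_{i}" for i, lab in enumerate(labels)]

    display: dict[str, str] = {}
    membership: dict[str, list[bool]] = {}
    for i, s in enumerate(sets):
        for sym in s.genes:
            key = sym.casefold()
            display.setdefault(key, sym)
            membership.setdefault(key, [False] * n)[i] = True
    rows = []
    for key, flags in membership.items():
        n_present = sum(flags)
        rows.append((display[key], *flags, n_present, n_present >= k))
    table = pd.DataFrame(rows, columns=["symbol", *labels, "n_present", "is_core"])
    table = table.sort_values(
        by=["n_present", "symbol"], ascending=[False, True], kind="mergesort"
    ).set_index("symbol")
    return ConsensusResult(table=table, k=k)


def categorize(
    genes: list[str], annot: GeneAnnotationTable, enr: EnrichmentResult | None = None
) -> CategorySummary:
    """Assign each gene its functional group and count group memberships.

    Genes lacking an annotation or group are counted as ``uncategorized``
    with a warning.  When an enrichment result is supplied the per-gene
    table is ordered by its log2 fold change (descending), the order used
    for circ-plot export.
    """
    rows = []
    for sym in genes:
        gid = annot.by_symbol(sym)
        group = annot.functional_group(gid) if gid is not None else None
        if group is None:
            logger.warning("categorize: %r has no functional group", sym)
            group = UNCATEGORIZED
        lfc = float("nan")
        if enr is not None:
            key = gid if gid is not None and gid in enr.table.index else sym
            if key in enr.table.index:
                lfc = float(enr.table.at[key, "log2fc"])
        rows.append((sym, group, lfc))
    per_gene = pd.DataFrame(rows, columns=["symbol", "functional_group", "log2fc"])
    if enr is not None:
        per_gene = per_gene.sort_values(
            by="log2fc", ascending=False, kind="mergesort", na_position="last"
        )
    per_gene = per_gene.set_index("symbol")
    counts = dict(Counter(per_gene["functional_group"]))
    return CategorySummary(per_gene=per_gene, group_counts=counts)


def ligand_group_profile(genes: list[str], annot: GeneAnnotationTable) -> dict[str, int]:
    """Count, per ligand group, how many of ``genes`` recognise it.

    A gene contributes to every ligand group it is annotated with; genes
    with empty ligand annotation contribute nothing.
    """
    counts: Counter[str] = Counter()
    for sym in genes:
        gid = annot.by_symbol(sym)
        if gid is None:
            continue
        counts.update(annot.ligand_groups(gid))
    return dict(counts)


def shared_ligand_groups(
    genes_a: list[str], genes_b: list[str], annot: GeneAnnotationTable
) -> set[str]:
    """Ligand groups recognised by both gene lists."""
    a = {g for g, c in ligand_group_profile(genes_a, annot).items() if c > 0}
    b = {g for g, c in ligand_group_profile(genes_b, annot).items() if c > 0}
    return a & b
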