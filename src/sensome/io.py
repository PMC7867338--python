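"""Tabular I/O for every artifact the pipeline touches.

All on-disk formats are plain text: tab-separated values without quoting,
UTF-8, Unix newlines.  Sample sheets are comma-separated.  Multi-valued
fields (GO terms, ligand groups) are pipe-delimited within their column.

Readers validate eagerly and never drop rows silently: every exclusion is
logged with a reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParseError, ValidationError
from .vocab import CURATION_STATUSES, SAMPLE_GROUPS, SPECIES

logger = logging.getLogger("sensome")

__all__ = [
    "CountMatrix",
    "GeneAnnotationTable",
    "SensomeSet",
    "OrthologMap",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_list",
    "write_gene_list",
    "read_annotation_table",
    "write_annotation_table",
    "write_sensome_table",
    "read_sensome_table",
    "read_disease_table",
    "write_disease_table",
    "read_ortholog_map",
    "write_ortholog_map",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class CountMatrix:
    """Integer gene-by-sample count matrix with sample metadata.

    Parameters
    ----------
    counts
        DataFrame indexed by gene id, one column per sample, non-negative
        integer entries.
    sample_group
        Map sample id -> ``"microglia"`` or ``"tissue"``.
    species
        Map sample id -> ``"mouse"`` or ``"human"``.
    """

    counts: pd.DataFrame
    sample_group: dict[str, str]
    species: dict[str, str]

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.has_duplicates:
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if self.counts.columns.has_duplicates:
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if not np.issubdtype(self.counts.to_numpy().dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        for s in self.counts.columns:
            if s not in self.sample_group:
                raise ValidationError(f"sample {s!r} missing from sample sheet")
            if self.sample_group[s] not in SAMPLE_GROUPS:
                raise ValidationError(
                    f"sample {s!r} has unknown group {self.sample_group[s]!r}"
                )
            if s not in self.species:
                raise ValidationError(f"sample {s!r} has no species assignment")
            if self.species[s] not in SPECIES:
                raise ValidationError(
                    f"sample {s!r} has unknown species {self.species[s]!r}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.sample_group[s] == group]

    def subset_samples(self, keep: list[str]) -> "CountMatrix":
        return CountMatrix(
            counts=self.counts[keep].copy(),
            sample_group={s: self.sample_group[s] for s in keep},
            species={s: self.species[s] for s in keep},
        )


@dataclass
class GeneAnnotationTable:
    """Per-gene annotation: symbol, GO terms, curation, functional group, ligands.

    Backed by a DataFrame indexed by gene id with columns ``symbol``,
    ``go_terms`` (set of str), ``curation_status``, ``functional_group``
    (str or None), ``ligand_groups`` (set of str).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id in annotation: {dup!r}")
        bad = set(self.table["curation_status"]) - CURATION_STATUSES
        if bad:
            raise ValidationError(f"unknown curation status values: {sorted(bad)}")

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index

    def symbol(self, gene_id: str) -> str:
        return self.table.at[gene_id, "symbol"]

    def go_terms(self, gene_id: str) -> set[str]:
        return self.table.at[gene_id, "go_terms"]

    def curation_status(self, gene_id: str) -> str:
        return self.table.at[gene_id, "curation_status"]

    def functional_group(self, gene_id: str) -> str | None:
        return self.table.at[gene_id, "functional_group"]

    def ligand_groups(self, gene_id: str) -> set[str]:
        return self.table.at[gene_id, "ligand_groups"]

    def by_symbol(self, symbol: str) -> str | None:
        """Return the gene id carrying ``symbol`` (case-insensitive), or None."""
        matches = self.table.index[
            self.table["symbol"].str.casefold() == symbol.casefold()
        ]
        return matches[0] if len(matches) else None


@dataclass
class SensomeSet:
    """An ordered, curated sensome gene list (rank 1 = most expressed)."""

    species: str
    source_label: str
    genes: list[str]
    target_size: int = 100
    partial: bool = False

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValidationError(f"unknown species {self.species!r}")
        keys = [g.casefold() for g in self.genes]
        if len(set(keys)) != len(keys):
            seen: set[str] = set()
            dup = next(k for k in keys if k in seen or seen.add(k))  # type: ignore[func-returns-value]
            raise ValidationError(f"duplicate symbol in sensome set: {dup!r}")
        if len(self.genes) != self.target_size and not self.partial:
            raise ValidationError(
                f"sensome set {self.source_label!r} has {len(self.genes)} genes, "
                f"expected {self.target_size} (mark partial to allow)"
            )

    def __len__(self) -> int:
        return len(self.genes)

    def symbol_keys(self) -> set[str]:
        """Casefolded symbols, for case-insensitive set arithmetic."""
        return {g.casefold() for g in self.genes}


@dataclass
class OrthologMap:
    """One-to-possibly-many ortholog pairs between two species' symbols."""

    pairs: set[tuple[str, str]] = field(default_factory=set)

    def __post_init__(self) -> None:
        for a, b in self.pairs:
            if not a or not b:
                raise ValidationError("ortholog pair with empty symbol")
        self._fwd: dict[str, list[str]] = {}
        self._rev: dict[str, list[str]] = {}
        for a, b in sorted(self.pairs):
            self._fwd.setdefault(a.casefold(), []).append(b)
            self._rev.setdefault(b.casefold(), []).append(a)

    def forward(self, symbol: str) -> list[str]:
        return list(self._fwd.get(symbol.casefold(), []))

    def reverse(self, symbol: str) -> list[str]:
        return list(self._rev.get(symbol.casefold(), []))

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------


def read_count_matrix(path_counts: str | Path, path_sample_sheet: str | Path) -> CountMatrix:
    """Read a tab-separated count matrix plus its CSV sample sheet.

    The counts file has gene ids in the first column (header ``gene_id``)
    and one column per sample.  The sample sheet has columns
    ``sample_id,group,species``.
    """
    path_counts = Path(path_counts)
    raw = pd.read_csv(path_counts, sep="\t", dtype=str)
    if raw.columns[0] != "gene_id":
        raise ParseError(
            f"{path_counts}: first column must be 'gene_id', got {raw.columns[0]!r}"
        )
    raw = raw.set_index("gene_id")
    counts = pd.DataFrame(index=raw.index)
    for col in raw.columns:
        try:
            counts[col] = raw[col].astype(np.int64)
        except (ValueError, TypeError):
            numeric = pd.to_numeric(raw[col], errors="coerce")
            bad_rows = raw.index[numeric.isna() | (numeric % 1 != 0)]
            bad = bad_rows[0] if len(bad_rows) else raw.index[0]
            raise ParseError(
                f"{path_counts}: non-integer count at gene {bad!r}, sample {col!r}"
            ) from None

    sheet = pd.read_csv(path_sample_sheet, dtype=str)
    for needed in ("sample_id", "group", "species"):
        if needed not in sheet.columns:
            raise ParseError(f"{path_sample_sheet}: missing column {needed!r}")
    group = dict(zip(sheet["sample_id"], sheet["group"]))
    species = dict(zip(sheet["sample_id"], sheet["species"]))
    return CountMatrix(counts=counts, sample_group=group, species=species)


def write_count_matrix(
    m: CountMatrix, path_counts: str | Path, path_sample_sheet: str | Path
) -> None:
    out = m.counts.copy()
    out.index.name = "gene_id"
    out.to_csv(path_counts, sep="\t", lineterminator="\n")
    sheet = pd.DataFrame(
        {
            "sample_id": m.sample_ids,
            "group": [m.sample_group[s] for s in m.sample_ids],
            "species": [m.species[s] for s in m.sample_ids],
        }
    )
    sheet.to_csv(path_sample_sheet, index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# gene lists
# ---------------------------------------------------------------------------


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-symbol-per-line gene list; '#' lines are comments.

    Order is preserved; duplicates (case-insensitive) are removed with a
    logged warning.  An empty list is an error.
    """
    symbols: list[str] = []
    seen: set[str] = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        sym = line.strip()
        if not sym or sym.startswith("#"):
            continue
        key = sym.casefold()
        if key in seen:
            logger.warning("duplicate symbol %r in %s dropped", sym, path)
            continue
        seen.add(key)
        symbols.append(sym)
    if not symbols:
        raise ValidationError(f"{path}: gene list is empty")
    return symbols


def write_gene_list(symbols: list[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(symbols) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# annotation tables
# ---------------------------------------------------------------------------

_ANNOT_COLS = [
    "gene_id",
    "symbol",
    "go_terms",
    "curation_status",
    "functional_group",
    "ligand_groups",
]


def _join_pipe(values: set[str]) -> str:
    return "|".join(sorted(values))


def _split_pipe(cell: str) -> set[str]:
    if not cell or pd.isna(cell):
        return set()
    return {v for v in str(cell).split("|") if v}


def read_annotation_table(path: str | Path) -> GeneAnnotationTable:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in _ANNOT_COLS if c not in raw.columns]
    if missing:
        raise ParseError(f"{path}: missing annotation columns {missing}")
    table = pd.DataFrame(
        {
            "symbol": raw["symbol"].values,
            "go_terms": [_split_pipe(c) for c in raw["go_terms"]],
            "curation_status": raw["curation_status"].values,
            "functional_group": [c if c else None for c in raw["functional_group"]],
            "ligand_groups": [_split_pipe(c) for c in raw["ligand_groups"]],
        },
        index=pd.Index(raw["gene_id"], name="gene_id"),
    )
    return GeneAnnotationTable(table=table)


def write_annotation_table(annot: GeneAnnotationTable, path: str | Path) -> None:
    t = annot.table
    out = pd.DataFrame(
        {
            "gene_id": t.index,
            "symbol": t["symbol"].values,
            "go_terms": [_join_pipe(v) for v in t["go_terms"]],
            "curation_status": t["curation_status"].values,
            "functional_group": [v or "" for v in t["functional_group"]],
            "ligand_groups": [_join_pipe(v) for v in t["ligand_groups"]],
        }
    )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


# ---------------------------------------------------------------------------
# sensome tables
# ---------------------------------------------------------------------------


def write_sensome_table(sensome: "SensomeSet", enr, path: str | Path, annot=None) -> None:
    """Serialize a curated sensome with its per-gene statistics.

    ``enr`` is an :class:`~sensome.enrichment.EnrichmentResult`; genes absent
    from it get empty statistic cells and a logged note.  When ``annot`` is
    given, functional groups are included.
    """
    rows = []
    stats = enr.table if enr is not None else None
    for rank, sym in enumerate(sensome.genes, start=1):
        gid = None
        if annot is not None:
            gid = annot.by_symbol(sym)
        key = gid if gid is not None else sym
        if stats is not None and key in stats.index:
            r = stats.loc[key]
            lfc, padj, mexpr = (
                f"{r['log2fc']:.6g}",
                f"{r['padj']:.6g}",
                f"{r['mean_microglia_expression']:.6g}",
            )
        else:
            logger.warning("gene %r missing from enrichment result; empty stats", sym)
            lfc = padj = mexpr = ""
        fg = ""
        if annot is not None and gid is not None:
            fg = annot.functional_group(gid) or ""
        rows.append((rank, sym, lfc, padj, mexpr, fg))
    out = pd.DataFrame(
        rows,
        columns=["rank", "symbol", "log2fc", "padj", "mean_expression", "functional_group"],
    )
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_sensome_table(path: str | Path, species: str, source_label: str,
                       target_size: int = 100, partial: bool = False) -> SensomeSet:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "symbol" not in raw.columns:
        raise ParseError(f"{path}: missing 'symbol' column")
    return SensomeSet(
        species=species,
        source_label=source_label,
        genes=list(raw["symbol"]),
        target_size=target_size if not partial else len(raw),
        partial=partial,
    )


# ---------------------------------------------------------------------------
# disease DE tables
# ---------------------------------------------------------------------------


def read_disease_table(path: str | Path, condition_label: str):
    """Read a disease DE summary table (columns: gene, log2fc, padj)."""
    from .disease import DiseaseDEResult

    raw = pd.read_csv(path, sep="\t", dtype={"gene": str})
    for needed in ("gene", "log2fc", "padj"):
        if needed not in raw.columns:
            raise ParseError(f"{path}: missing column {needed!r}")
    table = raw.set_index("gene")[["log2fc", "padj"]].astype(float)
    return DiseaseDEResult(condition_label=condition_label, table=table)


def write_disease_table(de, path: str | Path) -> None:
    out = de.table.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", lineterminator="\n")


# ---------------------------------------------------------------------------
# ortholog maps
# ---------------------------------------------------------------------------


def read_ortholog_map(path: str | Path) -> OrthologMap:
    raw = pd.read_csv(path, sep="\t", dtype=str)
    for needed in ("symbol_a", "symbol_b"):
        if needed not in raw.columns:
            raise ParseError(f"{path}: missing column {needed!r}")
    return OrthologMap(pairs=set(zip(raw["symbol_a"], raw["symbol_b"])))


def write_ortholog_map(m: OrthologMap, path: str | Path) -> None:
    out = pd.DataFrame(sorted(m.pairs), columns=["symbol_a", "symbol_b"])
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
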