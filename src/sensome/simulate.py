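"""Synthetic data with planted ground truth for end-to-end pipeline testing.

The generator emulates the two-group design the extraction pipeline assumes:
sorted microglia versus whole-tissue bulk RNA-seq counts.  Counts are
negative-binomial with variance mu + phi * mu^2, per-sample multiplicative
library sizes, and a planted subset of microglia-enriched genes that satisfy
every candidacy predicate by construction — fold enrichment above the
threshold, a membrane GO annotation, verified curation status, and a baseline
expression drawn from the upper half of the gene-mean distribution so the
planted genes clear the top-expression bar.

Everything is reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import CountMatrix, GeneAnnotationTable, OrthologMap
from .vocab import FUNCTIONAL_GROUPS, LIGAND_GROUPS, MEMBRANE_GO_TERMS

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_counts",
    "generate_ortholog_map",
    "generate_disease_table",
    "write_ground_truth",
]

_NON_MEMBRANE_GO = ("nucleus", "cytoplasm", "mitochondrion", "ribosome")


@dataclass
class SimConfig:
    """Parameters of one synthetic microglia-vs-tissue dataset.

    Defaults encode a small bulk design: 5 microglia and 5 tissue samples,
    5,000 genes with log-normal baseline means (median ~55 normalised
    counts), a global NB dispersion of 0.05, and 100 planted sensome genes
    with log2 enrichments drawn uniformly from [2.5, 6].
    """

    n_genes: int = 5000
    n_microglia_samples: int = 5
    n_tissue_samples: int = 5
    n_planted_sensome: int = 100
    planted_log2fc_range: tuple[float, float] = (2.5, 6.0)
    baseline_mean_log_mu: float = 4.0
    baseline_mean_log_sigma: float = 1.5
    dispersion: float = 0.05
    library_size_range: tuple[float, float] = (0.7, 1.3)
    p_membrane_background: float = 0.3
    p_curation_pass_background: float = 0.5
    seed: int = 0
    # optional knobs beyond the core design
    species: str = "mouse"
    per_gene_dispersion: bool = False
    gene_symbols: list[str] | None = None
    planted_gene_ids: list[str] | None = None

    def validate(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be positive")
        if self.n_microglia_samples < 1:
            raise ConfigError("n_microglia_samples must be positive")
        if self.n_tissue_samples < 1:
            raise ConfigError("n_tissue_samples must be positive")
        if self.n_planted_sensome < 0:
            raise ConfigError("n_planted_sensome must be non-negative")
        if self.n_planted_sensome > self.n_genes:
            raise ConfigError("n_planted_sensome exceeds n_genes")
        lo, hi = self.planted_log2fc_range
        if lo < 2.0:
            raise ConfigError("planted_log2fc_range low must be >= 2 (the enrichment threshold)")
        if hi < lo:
            raise ConfigError("planted_log2fc_range must be (low, high) with high >= low")
        if self.dispersion <= 0:
            raise ConfigError("dispersion must be positive")
        lo, hi = self.library_size_range
        if lo <= 0 or hi < lo:
            raise ConfigError("library_size_range must be positive with high >= low")
        for name in ("p_membrane_background", "p_curation_pass_background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        if self.gene_symbols is not None and len(self.gene_symbols) != self.n_genes:
            raise ConfigError("gene_symbols length must equal n_genes")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    planted_genes: set[str]
    planted_log2fc: dict[str, float] = field(default_factory=dict)
    planted_disease_direction: dict[str, str] = field(default_factory=dict)


def _default_symbols(n: int, species: str) -> list[str]:
    width = len(str(n))
    if species == "human":
        return [f"GENE{i:0{width}d}" for i in range(1, n + 1)]
    return [f"Gene{i:0{width}d}" for i in range(1, n + 1)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """NB(mean, var = mean + phi mean^2) via the (n, p) parameterisation."""
    mean = np.maximum(mean, 1e-12)
    phi = np.asarray(phi, dtype=float)
    out = np.empty(mean.shape, dtype=np.int64)
    poisson_like = phi < 1e-10
    if poisson_like.any():
        out[poisson_like] = rng.poisson(mean[poisson_like])
    nb = ~poisson_like
    if nb.any():
        size = 1.0 / phi[nb]
        p = size / (size + mean[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def generate_counts(
    config: SimConfig,
) -> tuple[CountMatrix, GeneAnnotationTable, GroundTruth]:
    """Simulate one microglia-vs-tissue dataset with planted sensome genes.

    Planted genes have microglia-group mean equal to tissue-group mean times
    2**lfc with lfc drawn uniformly from ``planted_log2fc_range``, carry one
    of the four membrane GO terms, and are curation-verified.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    symbols = config.gene_symbols or _default_symbols(config.n_genes, config.species)
    gene_ids = list(symbols)

    if config.planted_gene_ids is not None:
        unknown = set(config.planted_gene_ids) - set(gene_ids)
        if unknown:
            raise ConfigError(f"planted_gene_ids not in gene universe: {sorted(unknown)[:3]}")
        if len(config.planted_gene_ids) != config.n_planted_sensome:
            raise ConfigError("planted_gene_ids length must equal n_planted_sensome")
        planted = list(config.planted_gene_ids)
    else:
        planted = list(rng.choice(gene_ids, size=config.n_planted_sensome, replace=False))
    planted_set = set(planted)
    planted_idx = np.array([gene_ids.index(g) for g in planted], dtype=int)

    mu_log = config.baseline_mean_log_mu
    sigma = config.baseline_mean_log_sigma
    baseline = np.exp(rng.normal(mu_log, sigma, size=config.n_genes))
    # planted genes start from the upper half of the baseline distribution so
    # they clear the top-expression quantile once enriched
    if len(planted_idx):
        baseline[planted_idx] = np.exp(
            mu_log + np.abs(rng.normal(0.0, sigma, size=len(planted_idx)))
        )

    lfc = rng.uniform(*config.planted_log2fc_range, size=len(planted_idx))
    lfc_map = {g: float(v) for g, v in zip(planted, lfc)}

    mean_tissue = baseline.copy()
    mean_microglia = baseline.copy()
    if len(planted_idx):
        mean_microglia[planted_idx] = baseline[planted_idx] * np.exp2(lfc)

    n_mg, n_ts = config.n_microglia_samples, config.n_tissue_samples
    lib = rng.uniform(*config.library_size_range, size=n_mg + n_ts)
    if config.per_gene_dispersion:
        phi = config.dispersion * np.exp(rng.normal(0.0, 0.3, size=config.n_genes))
    else:
        phi = np.full(config.n_genes, config.dispersion)

    counts = np.empty((config.n_genes, n_mg + n_ts), dtype=np.int64)
    for j in range(n_mg + n_ts):
        group_mean = mean_microglia if j < n_mg else mean_tissue
        counts[:, j] = _nb_draw(rng, group_mean * lib[j], phi)

    sample_ids = [f"mg_{i + 1}" for i in range(n_mg)] + [f"ts_{i + 1}" for i in range(n_ts)]
    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=sample_ids),
        sample_group={s: ("microglia" if s.startswith("mg_") else "tissue") for s in sample_ids},
        species={s: config.species for s in sample_ids},
    )

    annot = _generate_annotation(rng, gene_ids, symbols, planted_set, config)
    truth = GroundTruth(planted_genes=planted_set, planted_log2fc=lfc_map)
    return matrix, annot, truth


def _generate_annotation(
    rng: np.random.Generator,
    gene_ids: list[str],
    symbols: list[str],
    planted: set[str],
    config: SimConfig,
) -> GeneAnnotationTable:
    membrane_terms = sorted(MEMBRANE_GO_TERMS)
    go_col, status_col, group_col, ligand_col = [], [], [], []
    for gid in gene_ids:
        if gid in planted:
            terms = {membrane_terms[rng.integers(len(membrane_terms))]}
            if rng.random() < 0.5:  # some genes carry several membrane terms
                terms.add(membrane_terms[rng.integers(len(membrane_terms))])
            go_col.append(terms)
            status_col.append("verified")
            group_col.append(FUNCTIONAL_GROUPS[rng.integers(len(FUNCTIONAL_GROUPS))])
            k = 1 + int(rng.random() < 0.4)
            ligand_col.append(set(rng.choice(LIGAND_GROUPS, size=k, replace=False)))
        elif rng.random() < config.p_membrane_background:
            go_col.append({membrane_terms[rng.integers(len(membrane_terms))]})
            if rng.random() < config.p_curation_pass_background:
                status_col.append("verified")
            else:
                status_col.append("rejected" if rng.random() < 0.5 else "unknown")
            group_col.append(None)
            ligand_col.append(set())
        elif rng.random() < 0.05:
            go_col.append(set())  # unmapped: no GO annotation at all
            status_col.append("unknown")
            group_col.append(None)
            ligand_col.append(set())
        else:
            go_col.append({_NON_MEMBRANE_GO[rng.integers(len(_NON_MEMBRANE_GO))]})
            status_col.append("unknown")
            group_col.append(None)
            ligand_col.append(set())
    table = pd.DataFrame(
        {
            "symbol": symbols,
            "go_terms": go_col,
            "curation_status": status_col,
            "functional_group": group_col,
            "ligand_groups": ligand_col,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return GeneAnnotationTable(table=table)


def generate_ortholog_map(
    gene_ids_a: list[str],
    gene_ids_b: list[str],
    frac_mapped: float,
    seed: int,
) -> OrthologMap:
    """One-to-one ortholog pairs covering floor(frac * min(|a|, |b|)) genes.

    Genes are paired positionally; a seeded random subset of positions of the
    required size is mapped, the rest stay unmapped.
    """
    if not gene_ids_a or not gene_ids_b:
        raise ConfigError("gene id lists must be non-empty")
    if not 0.0 <= frac_mapped <= 1.0:
        raise ConfigError("frac_mapped must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n = min(len(gene_ids_a), len(gene_ids_b))
    n_mapped = int(np.floor(frac_mapped * n))
    chosen = sorted(rng.choice(n, size=n_mapped, replace=False)) if n_mapped else []
    pairs = {(gene_ids_a[i], gene_ids_b[i]) for i in chosen}
    return OrthologMap(pairs=pairs)


def generate_disease_table(
    core_genes: set[str] | list[str],
    n_up: int,
    n_down: int,
    seed: int,
    condition_label: str = "synthetic",
    alpha: float = 0.05,
):
    """Synthetic disease DE summary over the core sensome.

    ``n_up`` genes get positive log2FC with adjusted p below ``alpha``,
    ``n_down`` get negative log2FC below ``alpha``, the remainder are
    non-significant.  Returns the table and the planted directions.
    """
    from .disease import DiseaseDEResult

    core = sorted(core_genes)
    if n_up < 0 or n_down < 0 or n_up + n_down > len(core):
        raise ConfigError("n_up + n_down must not exceed the number of core genes")
    rng = np.random.default_rng(seed)
    perm = list(rng.permutation(core))
    up, down = perm[:n_up], perm[n_up : n_up + n_down]
    rest = perm[n_up + n_down :]

    rows = {}
    directions = {}
    for g in up:
        rows[g] = (rng.uniform(0.5, 4.0), rng.uniform(1e-8, alpha * 0.5))
        directions[g] = "up"
    for g in down:
        rows[g] = (-rng.uniform(0.5, 4.0), rng.uniform(1e-8, alpha * 0.5))
        directions[g] = "down"
    for g in rest:
        rows[g] = (rng.uniform(-0.4, 0.4), rng.uniform(max(alpha, 0.1), 0.95))

    table = pd.DataFrame.from_dict(rows, orient="index", columns=["log2fc", "padj"])
    table = table.loc[core]
    table.index.name = "gene"
    de = DiseaseDEResult(condition_label=condition_label, table=table)
    truth = GroundTruth(planted_genes=set(up) | set(down), planted_disease_direction=directions)
    return de, truth


def write_ground_truth(truth: GroundTruth, path: str | Path) -> None:
    rows = []
    for g in sorted(truth.planted_genes):
        rows.append(
            (
                g,
                f"{truth.planted_log2fc.get(g, float('nan')):.6g}",
                truth.planted_disease_direction.get(g, ""),
            )
        )
    out = pd.DataFrame(rows, columns=["gene_id", "planted_log2fc", "disease_direction"])
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")
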