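import numpy as np
import pandas as pd
import pytest

from sensome import (
    CountMatrix,
    GeneAnnotationTable,
    SensomeSet,
    SimConfig,
    generate_counts,
)


def make_matrix(counts: np.ndarray, gene_ids=None, n_microglia=None,
                species="mouse") -> CountMatrix:
    """Wrap a raw array as a CountMatrix; first n_microglia columns are microglia."""
    counts = np.asarray(counts, dtype=np.int64)
    n_genes, n_samples = counts.shape
    if gene_ids is None:
        gene_ids = [f"g{i}" for i in range(n_genes)]
    if n_microglia is None:
        n_microglia = n_samples // 2
    sample_ids = [f"s{i}" for i in range(n_samples)]
    group = {
        s: ("microglia" if i < n_microglia else "tissue")
        for i, s in enumerate(sample_ids)
    }
    return CountMatrix(
        counts=pd.DataFrame(counts, index=gene_ids, columns=sample_ids),
        sample_group=group,
        species={s: species for s in sample_ids},
    )


def make_annotation(rows: dict) -> GeneAnnotationTable:
    """Build an annotation table from {gene_id: (symbol, go, status, group, ligands)}."""
    table = pd.DataFrame(
        {
            "symbol": [v[0] for v in rows.values()],
            "go_terms": [set(v[1]) for v in rows.values()],
            "curation_status": [v[2] for v in rows.values()],
            "functional_group": [v[3] if len(v) > 3 else None for v in rows.values()],
            "ligand_groups": [set(v[4]) if len(v) > 4 else set() for v in rows.values()],
        },
        index=pd.Index(list(rows), name="gene_id"),
    )
    return GeneAnnotationTable(table=table)


def make_set(symbols, species="mouse", label="test", target_size=None) -> SensomeSet:
    return SensomeSet(
        species=species,
        source_label=label,
        genes=list(symbols),
        target_size=target_size if target_size is not None else len(symbols),
    )


@pytest.fixture(scope="session")
def sim_dataset():
    """One standard synthetic dataset (5 vs 5, 5,000 genes, 100 planted)."""
    cfg = SimConfig(seed=7)
    return generate_counts(cfg)
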