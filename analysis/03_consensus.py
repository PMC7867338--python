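"""Within-species overlaps, the 3-of-4 cross-species core sensome, categories.

Reads the four sensome tables from results/ and the ortholog map from
scratch/, computes the mouse and human core/extended sets, translates the
human sensomes into mouse symbols, takes the genes present in at least 3 of
the 4 sensomes (the "microglia core sensome"), and summarises functional
groups and ligand groups of the core.  Also runs the expression-only
extraction variant on a microglia-only dataset and reports its overlap with
the bulk-derived mouse sensomes.

Run:  python analysis/03_consensus.py [seed]
"""

import sys
from pathlib import Path

import pandas as pd

from sensome import (
    ExtractionConfig,
    categorize,
    core_sensome,
    extract_sensome,
    ligand_group_profile,
    map_orthologs,
    overlap,
    read_annotation_table,
    read_ortholog_map,
    read_sensome_table,
)
from sensome.simulate import SimConfig, generate_counts
from sensome.study import DATASET_NAMES, QC_MIN_GENES, SENSOME_SIZE, _symbols

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2021

root = Path(__file__).resolve().parents[1]
scratch = root / "scratch" / "datasets"
results = root / "results"

sensomes = {}
for name in DATASET_NAMES:
    species = "human" if name.startswith("human") else "mouse"
    path = results / f"sensome_{name}.tsv"
    if not path.exists():
        sys.exit(f"{path} missing - run analysis/02_extract_sensomes.py first")
    sensomes[name] = read_sensome_table(path, species=species, source_label=name,
                                        target_size=SENSOME_SIZE)
orth = read_ortholog_map(scratch / "orthologs.tsv")

# within-species core/extended sets
rows = []
for label, a, b in [("mouse", "mouse_a", "mouse_b"), ("human", "human_a", "human_b")]:
    res = overlap(sensomes[a], sensomes[b])
    rows.append({"pair": label, "core_size": len(res.intersection),
                 "extended_size": len(res.union),
                 "percent_overlap": res.percent_overlap})
    print(f"{label}: {res.percent_overlap:.0f}% overlap -> "
          f"core {len(res.intersection)}, extended {len(res.union)}")
pd.DataFrame(rows).to_csv(results / "within_species_overlap.tsv", sep="\t", index=False)

# translate the human sensomes to mouse symbols, then 3-of-4 consensus
translated = []
for name in ("human_a", "human_b"):
    t, unmapped = map_orthologs(sensomes[name], orth, "mouse")
    translated.append(t)
    if unmapped:
        print(f"{name}: {len(unmapped)} symbols without mouse ortholog: {unmapped}")
consensus = core_sensome(
    [sensomes["mouse_a"], sensomes["mouse_b"], *translated], k=3
)
consensus.table.to_csv(results / "core_sensome.tsv", sep="\t")
core = consensus.core_genes
print(f"microglia core sensome: {len(core)} genes present in >=3 of 4 sensomes")

# functional and ligand categorisation of the core, using mouse_a's annotation
annot = read_annotation_table(scratch / "mouse_a" / "annotation.tsv")
cats = categorize(core, annot)
pd.Series(cats.group_counts).rename_axis("functional_group").rename("n_genes").to_csv(
    results / "core_functional_groups.tsv", sep="\t"
)
print(f"modal functional group of the core: {cats.modal_group!r}")
ligands = ligand_group_profile(core, annot)
pd.Series(ligands).rename_axis("ligand_group").rename("n_genes").sort_index().to_csv(
    results / "core_ligand_groups.tsv", sep="\t"
)
print(f"core genes recognise {len(ligands)} ligand groups")

# single-cell-style check: expression-only extraction on microglia-only counts
pool, filler = _symbols("mouse")
import numpy as np
rng = np.random.default_rng(SEED + 601)
planted = sorted(rng.choice(pool, size=SENSOME_SIZE, replace=False))
cfg_sim = SimConfig(
    n_genes=5000, n_microglia_samples=8, n_tissue_samples=1,
    n_planted_sensome=SENSOME_SIZE, seed=SEED + 602,
    gene_symbols=pool + filler, planted_gene_ids=planted,
)
m_sc, annot_sc, _ = generate_counts(cfg_sim)
mg_only = m_sc.subset_samples(m_sc.samples_in_group("microglia"))
cfg = ExtractionConfig(use_enrichment=False, target_size=SENSOME_SIZE,
                       source_label="microglia_only")
sc_sensome, _ = extract_sensome(mg_only, annot_sc, cfg, min_genes=QC_MIN_GENES,
                                allow_partial=True)
for name in ("mouse_a", "mouse_b"):
    res = overlap(sc_sensome, sensomes[name])
    print(f"expression-only sensome vs {name}: {len(res.intersection)} shared genes")
shared_core = {g.casefold() for g in sc_sensome.genes} & {g.casefold() for g in core}
print(f"{100 * len(shared_core) / len(core):.0f}% of core sensome genes appear "
      "in the expression-only sensome")
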