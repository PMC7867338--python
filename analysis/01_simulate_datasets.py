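"""Simulate the four-dataset study inputs.

Generates two mouse and two human microglia-vs-tissue count matrices (5 vs 5
samples, 5,000 genes each) sharing a 130-gene planted sensing pool per
species, plus the mouse<->human ortholog map.  Full matrices go to
scratch/datasets/ (regenerable, not part of the deliverable); a small
ground-truth summary goes to results/.

Run from the repository root:  python analysis/01_simulate_datasets.py [seed]
"""

import sys
from pathlib import Path

import pandas as pd

from sensome import write_annotation_table, write_count_matrix, write_ortholog_map
from sensome.simulate import write_ground_truth
from sensome.study import simulate_study

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2021

root = Path(__file__).resolve().parents[1]
scratch = root / "scratch" / "datasets"
results = root / "results"
scratch.mkdir(parents=True, exist_ok=True)
results.mkdir(exist_ok=True)

inputs = simulate_study(SEED)

summary_rows = []
for name, ds in inputs.datasets.items():
    out = scratch / name
    out.mkdir(exist_ok=True)
    write_count_matrix(ds.matrix, out / "counts.tsv", out / "samples.csv")
    write_annotation_table(ds.annotation, out / "annotation.tsv")
    write_ground_truth(ds.truth, out / "ground_truth.tsv")
    summary_rows.append(
        {
            "dataset": name,
            "species": ds.species,
            "n_genes": len(ds.matrix.gene_ids),
            "n_samples": len(ds.matrix.sample_ids),
            "n_planted": len(ds.truth.planted_genes),
            "total_reads": int(ds.matrix.counts.to_numpy().sum()),
        }
    )
    print(f"{name}: {summary_rows[-1]['n_genes']} genes, "
          f"{summary_rows[-1]['n_samples']} samples, "
          f"{summary_rows[-1]['n_planted']} planted sensome genes")

write_ortholog_map(inputs.ortholog_map, scratch / "orthologs.tsv")
print(f"ortholog map: {len(inputs.ortholog_map)} pairs")

pd.DataFrame(summary_rows).to_csv(
    results / "dataset_summary.tsv", sep="\t", index=False
)
print(f"wrote {results / 'dataset_summary.tsv'}; matrices under {scratch}")
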