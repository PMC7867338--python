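"""Apply the core sensome to synthetic disease DE tables.

Reads the core sensome from results/, generates three condition tables
(aging, ALS, AD) with planted up/down genes — one gene planted up in every
condition — calls per-gene directions, and reports the genes changing
consistently across all conditions.  Direction matrix and per-condition
counts go to results/.

Run:  python analysis/04_disease_application.py [seed]
"""

import sys
from pathlib import Path

import pandas as pd

from sensome.disease import cross_condition_consistency
from sensome.study import run_disease_application

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 2021

root = Path(__file__).resolve().parents[1]
results = root / "results"
core_path = results / "core_sensome.tsv"
if not core_path.exists():
    sys.exit(f"{core_path} missing - run analysis/03_consensus.py first")

core_table = pd.read_csv(core_path, sep="\t")
core = list(core_table.loc[core_table["is_core"], "symbol"])
print(f"core sensome: {len(core)} genes")

out = run_disease_application(core, SEED)

rows = []
for t, (cond, truth) in zip(out.tables, out.truths.items()):
    planted_up = {g for g, d in truth.planted_disease_direction.items() if d == "up"}
    planted_down = {g for g, d in truth.planted_disease_direction.items() if d == "down"}
    called_up, called_down = set(t.genes_with("up")), set(t.genes_with("down"))
    ok = called_up == planted_up and called_down == planted_down
    rows.append({"condition": cond, "up": len(called_up), "down": len(called_down),
                 "ns": len(t.genes_with("ns")), "calls_match_truth": ok})
    print(f"{cond}: {len(called_up)} up, {len(called_down)} down "
          f"({'exact' if ok else 'MISMATCHED'} recovery of planted directions)")

matrix, consistent = cross_condition_consistency(out.tables)
matrix.rename_axis("gene").to_csv(results / "disease_direction_matrix.tsv", sep="\t")
pd.DataFrame(rows).to_csv(results / "disease_condition_summary.tsv", sep="\t",
                          index=False)
print(f"genes changed in the same direction in every condition: {sorted(consistent)}")
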