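#!/usr/bin/env python
"""Cross-species cluster correlation on the simulated dataset.

Runs the five-step pipeline (markers -> intersection -> pseudobulk ->
specificity -> Pearson correlation -> best match) on the matrices produced by
01_simulate_expression.py and reports whether the known class homology is
recovered.
"""

from pathlib import Path

import pandas as pd

from interevo.pipeline import run_compare

ROOT = Path(__file__).resolve().parent.parent / "results"
EXPR = ROOT / "expression"
if not (EXPR / "species_a.csv").exists():
    raise SystemExit("run analysis/01_simulate_expression.py first")

out = run_compare({
    "species_a": {"matrix": str(EXPR / "species_a.csv"),
                  "meta": str(EXPR / "species_a.cells.tsv"), "format": "csv"},
    "species_b": {"matrix": str(EXPR / "species_b.csv"),
                  "meta": str(EXPR / "species_b.cells.tsv"), "format": "csv"},
    "seed": 1,
    "heatmap": True,
}, ROOT / "compare")

truth = pd.read_csv(EXPR / "truth_type_map.tsv", sep="\t")
match = out["best_match"]
correct = sum(match.loc[ta, "best_match"] == tb
              for ta, tb in zip(truth["type_a"], truth["type_b"]))
print(f"shared marker genes: {out['n_shared_genes']}")
print(f"classes recovered: {correct}/{len(truth)}")
print(match)
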