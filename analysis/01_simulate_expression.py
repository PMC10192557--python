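#!/usr/bin/env python
"""Simulate the two-species interneuron dataset used by the comparison study.

Draws count matrices for two species sharing six interneuron-like classes
(PV/SST/VIP/Lamp5/Sncg/Meis2-like; 200 cells per class, 3,000 genes, 40
markers per class at log-fold-change 2) and writes them, with the truth
tables, under results/expression/.
"""

from pathlib import Path

from interevo.pipeline import run_simulate_expression

OUT = Path(__file__).resolve().parent.parent / "results" / "expression"

out = run_simulate_expression({"seed": 1, "format": "csv"}, OUT)
a, b = out["species_a"], out["species_b"]
print(f"species A: {a.shape[0]} cells x {a.shape[1]} genes "
      f"({a.clusters.nunique()} classes)")
print(f"species B: {b.shape[0]} cells x {b.shape[1]} genes")
print(f"truth tables and matrices written to {OUT}")
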