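#!/usr/bin/env python
"""Per-site conservation of the simulated alignment against mouse.

Profiles each alignment column as the fraction of the other species carrying
the mouse residue and writes the per-site table under results/conservation/.
"""

from pathlib import Path

from interevo.conservation import (conservation_table, mean_conservation,
                                   per_site_conservation)
from interevo.seqs import AlignedSeqs

ROOT = Path(__file__).resolve().parent.parent / "results"
SEQS = ROOT / "sequences"
if not (SEQS / "leaves.fasta").exists():
    raise SystemExit("run analysis/03_simulate_sequences.py first")

aln = AlignedSeqs.from_fasta(SEQS / "leaves.fasta")
prof = per_site_conservation(aln, "mouse")
OUT = ROOT / "conservation"
OUT.mkdir(parents=True, exist_ok=True)
conservation_table(prof, aln).to_csv(OUT / "conservation.tsv", sep="\t", index=False)

print(f"sites profiled: {prof.n_sites}")
print(f"mean conservation vs mouse: {mean_conservation(prof):.3f}")
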