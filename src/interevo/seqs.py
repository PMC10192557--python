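"""Gapped amino-acid alignments with FASTA round-trip via Biopython."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .substitution import AA_ALPHABET, MISSING_CHARS

_VALID = set(AA_ALPHABET) | {c for c in MISSING_CHARS}


@dataclass
class AlignedSeqs:
    """Mapping taxon -> aligned (gapped) amino-acid sequence, all equal length."""

    sequences: dict[str, str]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise ValueError("alignment is empty")
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) != 1:
            raise ValueError(f"sequences have unequal lengths: {sorted(lengths)}")
        self.length = lengths.pop()
        for name, seq in self.sequences.items():
            bad = set(seq.upper()) - _VALID
            if bad:
                raise ValueError(f"sequence {name!r} has invalid characters {sorted(bad)}")

    @property
    def taxa(self) -> list[str]:
        return list(self.sequences)

    def column(self, i: int) -> dict[str, str]:
        return {name: seq[i] for name, seq in self.sequences.items()}

    def __getitem__(self, taxon: str) -> str:
        return self.sequences[taxon]

    @classmethod
    def from_fasta(cls, path: str | Path) -> "AlignedSeqs":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        names = [r.id for r in records]
        if len(set(names)) != len(names):
            raise ValueError("duplicate FASTA record identifiers")
        return cls({r.id: str(r.seq).upper() for r in records})

    def to_fasta(self, path: str | Path) -> None:
        records = [SeqRecord(Seq(seq), id=name, description="")
                   for name, seq in self.sequences.items()]
        SeqIO.write(records, str(path), "fasta")


def write_fasta(path: str | Path, records: dict[str, str],
                descriptions: dict[str, str] | None = None) -> None:
    """Write arbitrary named sequences (e.g. ML/altAll ancestors) as FASTA."""
    descriptions = descriptions or {}
    recs = [SeqRecord(Seq(seq), id=name, description=descriptions.get(name, ""))
            for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")
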