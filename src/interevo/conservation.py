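"""Per-site conservation of an alignment relative to a reference taxon.

At each alignment column where the reference has a residue, conservation is
the fraction of the other sequences that carry the same residue.  Columns
where the reference is gapped are undefined (NaN).  By default a comparator
gap counts as a mismatch; alternatively gapped comparators can be excluded
from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqs import AlignedSeqs

GAP_CHARS = ("-", ".")


@dataclass
class ConservationProfile:
    reference: str
    fraction: np.ndarray        # (L,), NaN where the reference is gapped
    n_comparators: np.ndarray   # (L,), denominator actually used per site
    reference_site: np.ndarray  # (L,), 1-based ungapped reference coordinate, 0 at gaps
    gap_mode: str               # "mismatch" | "exclude"

    @property
    def n_sites(self) -> int:
        return self.fraction.shape[0]


def per_site_conservation(aln: AlignedSeqs, reference: str,
                          comparator_gaps: str = "mismatch") -> ConservationProfile:
    """Fraction of non-reference sequences matching the reference per site.

    Parameters
    ----------
    comparator_gaps:
        "mismatch" counts a gapped comparator as a non-match (default);
        "exclude" drops it from that site's denominator.
    """
    if reference not in aln.sequences:
        raise KeyError(f"reference {reference!r} not in alignment taxa {aln.taxa}")
    if len(aln.taxa) < 2:
        raise ValueError("alignment needs at least 2 sequences")
    if comparator_gaps not in ("mismatch", "exclude"):
        raise ValueError("comparator_gaps must be 'mismatch' or 'exclude'")

    ref = np.frombuffer(aln[reference].encode(), dtype="S1")
    others = np.stack([
        np.frombuffer(aln[t].encode(), dtype="S1")
        for t in aln.taxa if t != reference
    ])
    ref_gap = np.isin(ref, [g.encode() for g in GAP_CHARS])
    other_gap = np.isin(others, [g.encode() for g in GAP_CHARS])
    match = (others == ref[None, :]) & ~other_gap

    if comparator_gaps == "mismatch":
        denom = np.full(aln.length, others.shape[0], dtype=float)
    else:
        denom = (~other_gap).sum(axis=0).astype(float)

    with np.errstate(invalid="ignore", divide="ignore"):
        frac = match.sum(axis=0) / denom
    frac[ref_gap] = np.nan
    frac[(denom == 0) & ~ref_gap] = np.nan

    ref_site = np.cumsum(~ref_gap)
    ref_site[ref_gap] = 0
    return ConservationProfile(
        reference=reference,
        fraction=frac,
        n_comparators=np.where(ref_gap, 0, denom).astype(int),
        reference_site=ref_site.astype(int),
        gap_mode=comparator_gaps,
    )


def mean_conservation(p: ConservationProfile) -> float:
    """Arithmetic mean of conservation over the defined (non-gap) sites."""
    defined = ~np.isnan(p.fraction)
    if not defined.any():
        raise ValueError("no defined sites: reference is gapped everywhere")
    return float(p.fraction[defined].mean())


def conservation_table(p: ConservationProfile, aln: AlignedSeqs) -> pd.DataFrame:
    """Tidy per-site table (1-based alignment coordinates) for TSV export."""
    return pd.DataFrame({
        "alignment_site": np.arange(1, p.n_sites + 1),
        "reference_site": p.reference_site,
        "reference_residue": list(aln[p.reference]),
        "fraction": p.fraction,
        "n_comparators": p.n_comparators,
    })
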