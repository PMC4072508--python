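"""Shannon-entropy conservation filter over multiple sequence alignments.

Authentic BH3 motifs tend to be more conserved than the rest of their parent
protein, with conservation concentrated in the 12-residue 2d-4a core.  The
filter computes the Shannon entropy S = -sum(p ln p) of each alignment
column (gaps excluded from the frequencies), sums it over 12-column windows,
and calls a candidate core conserved when its window entropy is strictly
lower than the mean entropy of every other 12-column window in the alignment.
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass

from Bio import SeqIO

__all__ = ["CONSERVATION_WINDOW", "Msa", "column_entropy", "window_entropy",
           "is_conserved"]

CONSERVATION_WINDOW = 12  # matches the span of the conserved 2d-4a core
GAP = "-"


@dataclass
class Msa:
    rows: list

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> list:
        return [r[j] for r in self.rows]

    @classmethod
    def from_fasta(cls, source) -> "Msa":
        if isinstance(source, str) and source.lstrip().startswith(">"):
            source = io.StringIO(source)
        rows = [str(rec.seq).upper() for rec in SeqIO.parse(source, "fasta")]
        return cls(rows)


def column_entropy(column) -> float:
    """Shannon entropy (nats) of one alignment column, gaps excluded."""
    if len(column) == 0:
        raise ValueError("empty column")
    observed = [c for c in column if c != GAP and c != "."]
    if not observed:
        warnings.warn("all-gap column: entropy defined as 0")
        return 0.0
    total = len(observed)
    ent = 0.0
    for c in set(observed):
        p = observed.count(c) / total
        ent -= p * math.log(p)
    return ent


def window_entropy(msa: Msa, start: int,
                   width: int = CONSERVATION_WINDOW) -> float:
    """Sum of column entropies over ``width`` columns starting at ``start``."""
    if start < 0 or start + width > msa.n_columns:
        raise ValueError("entropy window out of alignment range")
    return sum(column_entropy(msa.column(j)) for j in range(start, start + width))


def is_conserved(msa: Msa, core_start: int,
                 width: int = CONSERVATION_WINDOW) -> bool:
    """True iff the core window is more conserved than the alignment average.

    The core (the candidate's 2d-4a span) must have strictly lower summed
    entropy than the mean over all other sliding windows of the same width
    (step 1, the core window itself excluded).  Ties are not conserved.
    """
    core = window_entropy(msa, core_start, width)
    others = [window_entropy(msa, s, width)
              for s in range(msa.n_columns - width + 1) if s != core_start]
    if not others:
        raise ValueError("alignment too short: no windows other than the core")
    return core < sum(others) / len(others)
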