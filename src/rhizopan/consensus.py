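"""Majority-rule consensus construction and per-sequence identity scoring.

Given a pre-computed multiple alignment of a marker gene (16S rRNA in
the motivating use case), build the per-column majority consensus and
score each aligned sequence's percent similarity to it. Gap (``-``) and
ambiguous (``N``) symbols are not nucleotides: they neither vote during
consensus construction nor enter the similarity denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
ALPHABET = frozenset(BASES) | {"N", "-"}
GAP = "-"


@dataclass(frozen=True)
class Alignment:
    """A fixed-length multiple alignment over {A, C, G, T, N, -}."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self):
        if not self.records:
            raise ValueError("alignment has no sequences")
        length = len(self.records[0][1])
        if length < 1:
            raise ValueError("alignment length must be >= 1")
        seen: set[str] = set()
        for rid, seq in self.records:
            if rid in seen:
                raise ValueError(f"duplicate sequence id {rid!r}")
            seen.add(rid)
            if len(seq) != length:
                raise ValueError(
                    f"sequence {rid!r} has length {len(seq)}, expected {length}"
                )
            bad = set(seq) - ALPHABET
            if bad:
                raise ValueError(
                    f"sequence {rid!r} contains invalid symbols {sorted(bad)}"
                )

    @classmethod
    def from_records(cls, records) -> "Alignment":
        return cls(tuple((rid, seq.upper()) for rid, seq in records))

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def length(self) -> int:
        return len(self.records[0][1])

    def __len__(self) -> int:
        return len(self.records)

    def to_array(self) -> np.ndarray:
        """Character matrix of shape (n_sequences, length)."""
        return np.array([list(seq) for _, seq in self.records])


def build_consensus(aln: Alignment) -> str:
    """Per-column majority consensus.

    Only A/C/G/T vote; ties break toward the lexicographically smallest
    base. A column with no informative symbol at all yields ``-``.
    """
    chars = aln.to_array()
    out = []
    for col in chars.T:
        counts = [(col == b).sum() for b in BASES]
        best = max(counts)
        if best == 0:
            out.append(GAP)
        else:
            # BASES is lexicographically sorted, so index() breaks ties low
            out.append(BASES[counts.index(best)])
    return "".join(out)


def similarity_to_consensus(seq: str, consensus: str) -> float:
    """Percent identity over columns where both symbols are A/C/G/T.

    Returns ``100 * (1 - differences / compared_columns)`` rounded to one
    decimal. Symmetric in its arguments. Raises if no column is comparable.
    """
    if len(seq) != len(consensus):
        raise ValueError(
            f"length mismatch: {len(seq)} vs {len(consensus)}"
        )
    a = np.array(list(seq.upper()))
    b = np.array(list(consensus.upper()))
    informative = np.isin(a, BASES) & np.isin(b, BASES)
    compared = int(informative.sum())
    if compared == 0:
        raise ValueError("no comparable columns: similarity undefined")
    differences = int((a[informative] != b[informative]).sum())
    return round(100.0 * (1.0 - differences / compared), 1)


def similarity_table(aln: Alignment, consensus: str | None = None) -> pd.DataFrame:
    """Similarity of every aligned sequence to the (given or rebuilt)
    consensus, as a two-column DataFrame."""
    if consensus is None:
        consensus = build_consensus(aln)
    rows = [
        {"strain": rid, "similarity_percent": similarity_to_consensus(seq, consensus)}
        for rid, seq in aln.records
    ]
    return pd.DataFrame(rows, columns=["strain", "similarity_percent"])
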