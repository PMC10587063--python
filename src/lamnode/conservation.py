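"""Pairwise global alignment, percent-identity matrices and conservation maps.

Alignment is affine-gap global (Needleman–Wunsch–Gotoh) through Biopython's
``PairwiseAligner`` with a BLOSUM62 substitution table in which the ambiguity
code X scores 0 against everything.  Percent identity uses the aligned-columns
denominator: identical columns divided by columns where at least one sequence
has a residue (pairwise global alignments contain no dual-gap columns).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

__all__ = [
    "AlignmentResult",
    "IdentityMatrix",
    "global_align",
    "identity_matrix",
    "map_conservation",
]

_VALID = set("ACDEFGHIKLMNPQRSTVWYXBZUO")


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("gapped strings must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.aligned_a)

    @property
    def n_identical(self) -> int:
        return sum(
            1 for a, b in zip(self.aligned_a, self.aligned_b) if a == b and a != "-"
        )

    @property
    def identity_pct(self) -> float:
        cols = sum(
            1
            for a, b in zip(self.aligned_a, self.aligned_b)
            if not (a == "-" and b == "-")
        )
        return 100.0 * self.n_identical / cols if cols else 0.0


@lru_cache(maxsize=8)
def _aligner(gap_open: float, gap_extend: float, matrix_name: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    matrix = substitution_matrices.load(matrix_name)
    if "X" in matrix.alphabet:
        matrix = matrix.copy()
        ix = matrix.alphabet.index("X")
        matrix[ix, :] = 0.0
        matrix[:, ix] = 0.0
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -gap_open
    aligner.extend_gap_score = -gap_extend
    return aligner


def global_align(
    seq_a: str,
    seq_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> AlignmentResult:
    """Optimal affine-gap global alignment of two protein sequences.

    ``gap_open`` is the cost of the first gapped position and ``gap_extend``
    each further one (both positive penalties).  Unknown letters map to X.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    sa = "".join(c if c in _VALID else "X" for c in seq_a.upper())
    sb = "".join(c if c in _VALID else "X" for c in seq_b.upper())
    aligner = _aligner(gap_open, gap_extend, matrix)
    aln = aligner.align(sa, sb)[0]
    text_a, text_b = str(aln[0]), str(aln[1])
    return AlignmentResult(aligned_a=text_a, aligned_b=text_b, score=float(aln.score))


@dataclass
class IdentityMatrix:
    labels: list[str]
    values: np.ndarray  # %, symmetric, diagonal 100

    def as_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def off_diagonal(self) -> np.ndarray:
        n = len(self.labels)
        mask = ~np.eye(n, dtype=bool)
        return self.values[mask]


def identity_matrix(
    records: Sequence[tuple[str, str]],
    regions: Optional[Mapping[str, tuple[int, int]]] = None,
    **align_kwargs,
) -> IdentityMatrix:
    """All-vs-all percent identity over ``(label, sequence)`` records.

    ``regions`` optionally restricts each record to a 1-based inclusive
    residue range before aligning.  The matrix is symmetric by construction
    (each pair aligned once) and invariant to record order.
    """
    if len(records) < 2:
        raise ValueError("need at least two records")
    labels, seqs = [], []
    for label, seq in records:
        if regions and label in regions:
            lo, hi = regions[label]
            if lo < 1 or hi > len(seq) or lo > hi:
                raise ValueError(f"region {lo}-{hi} out of bounds for record {label!r}")
            seq = seq[lo - 1 : hi]
        labels.append(label)
        seqs.append(seq)
    n = len(labels)
    values = np.full((n, n), 100.0)
    order = sorted(range(n), key=lambda i: labels[i])  # order-invariant pairing
    for ii in range(n):
        for jj in range(ii + 1, n):
            i, j = order[ii], order[jj]
            ident = global_align(seqs[i], seqs[j], **align_kwargs).identity_pct
            values[i, j] = values[j, i] = ident
    return IdentityMatrix(labels=labels, values=values)


def map_conservation(
    sequences: Sequence[tuple[str, str]],
    chain_sequence: str,
    min_match_pct: float = 95.0,
    **align_kwargs,
) -> np.ndarray:
    """Per-residue conservation of a structure chain across homologous sequences.

    The chain sequence must occur (>= ``min_match_pct`` ungapped identity) in
    one of the supplied sequences.  Every sequence is aligned to the chain
    sequence; each chain position is then scored as the frequency of the most
    common residue in its alignment column (gaps count as mismatch), so
    identical sequences give 1.0 everywhere and a fully variable column among
    three sequences gives 1/3.
    """
    if not chain_sequence:
        raise ValueError("chain sequence is empty")
    best = max(
        global_align(chain_sequence, seq, **align_kwargs).identity_pct
        for _, seq in sequences
    )
    if best < min_match_pct:
        raise ValueError(
            f"chain sequence not locatable in the alignment set "
            f"(best identity {best:.1f}% < {min_match_pct}%)"
        )
    n = len(chain_sequence)
    columns: list[list[str]] = [[c] for c in chain_sequence]
    for _, seq in sequences:
        aln = global_align(chain_sequence, seq, **align_kwargs)
        ic = 0
        for ca, cb in zip(aln.aligned_a, aln.aligned_b):
            if ca != "-":
                columns[ic].append(cb)
                ic += 1
    out = np.zeros(n)
    n_seqs = len(sequences)
    for i, col in enumerate(columns):
        votes = col[1:]  # the aligned letters, one per input sequence
        counts: dict[str, int] = {}
        for c in votes:
            if c != "-":
                counts[c] = counts.get(c, 0) + 1
        out[i] = (max(counts.values()) / n_seqs) if counts else 0.0
    return out
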