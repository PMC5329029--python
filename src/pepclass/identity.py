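"""Global pairwise percent identity between protein sequences.

Identity is computed from one optimal global (Needleman-Wunsch) alignment
under a fixed, fully specified convention: BLOSUM62 substitution scores,
gap open 10, gap extension 0.5 (an opened gap's first position costs 10,
each further position 0.5).  Percent identity is

    100 * identical residue pairs / aligned residue columns,

where the denominator excludes every column containing a gap.  Different
alignment conventions (and different co-optimal alignments) can shift
identities by a few percent; the convention here is deterministic and is
used for all reported matrices.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

from .seq_io import ProteinRecord

GAP_OPEN = 10.0
GAP_EXTEND = 0.5


def make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -GAP_OPEN
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric percent-identity matrix with 100s on the diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=list(self.ids), columns=list(self.ids))


def global_identity(a: ProteinRecord, b: ProteinRecord) -> float:
    """Percent identity of one optimal global alignment of two proteins.

    Several alignments can share the optimal score but differ slightly in
    identity; the pair is aligned in a canonical (lexicographic) order so
    the reported value does not depend on argument order.
    """
    if not a.sequence or not b.sequence:
        raise ValueError("both sequences must be non-empty")
    if (b.sequence, b.id) < (a.sequence, a.id):
        a, b = b, a
    aligner = make_aligner()
    alignment = aligner.align(a.sequence, b.sequence)[0]
    counts = alignment.counts()
    aligned = counts.identities + counts.mismatches
    if aligned == 0:
        return 0.0
    return 100.0 * counts.identities / aligned


def identity_matrix(records: Sequence[ProteinRecord]) -> IdentityMatrix:
    """All-pairs global percent identity (symmetric, diagonal 100)."""
    if len(records) < 2:
        raise ValueError("identity_matrix requires at least 2 records")
    n = len(records)
    values = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pct = global_identity(records[i], records[j])
            values[i, j] = values[j, i] = pct
    return IdentityMatrix(tuple(r.id for r in records), values)
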