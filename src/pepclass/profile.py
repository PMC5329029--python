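"""Positional statistics of conserved peptides and catalytic-serine motifs.

The position of a conserved peptide within a protein family is summarised
by the median of its (first-occurrence, 1-based) start position over all
family sequences that contain it; the median rather than the mean makes
the statistic robust to length variation and truncated entries.  Binned
over a peptide list, these medians show where conservation concentrates
along the protein — for the glucuronoyl-esterase families this hotspot
sits around residues 160-200, the region of the catalytic serine.

The serine-motif scan looks for the short G-x-S-x context typical of the
nucleophilic serine of alpha/beta-hydrolases (GHSF, GRSG, ...) inside
peptide-list entries.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Sequence

import pandas as pd

from .ppr import PeptideList
from .seq_io import ProteinRecord


@dataclass(frozen=True)
class PeptidePosition:
    """Median 1-based start position of a peptide over containing records.

    ``median_position`` may be half-integer (even count) and is None when
    no record contains the peptide (``n_sequences`` 0).
    """

    peptide: str
    n_sequences: int
    median_position: float | None


@dataclass(frozen=True)
class SerineMotifHit:
    """A 4-residue G-x-S-x window inside a list peptide (0-based offset)."""

    peptide: str
    motif: str
    offset: int


def peptide_median_position(
    peptide: str, records: Sequence[ProteinRecord]
) -> PeptidePosition:
    """Median first-occurrence start of ``peptide`` over containing records.

    Records lacking the peptide are excluded; the first occurrence is
    taken when it recurs within one sequence.  Even counts give the mean
    of the two central positions (kept fractional).
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    positions = []
    for rec in records:
        idx = rec.sequence.find(peptide)
        if idx >= 0:
            positions.append(idx + 1)
    if not positions:
        return PeptidePosition(peptide, 0, None)
    return PeptidePosition(peptide, len(positions), float(median(positions)))


def position_histogram(
    peptide_list: PeptideList,
    records: Sequence[ProteinRecord],
    bin_width: int = 20,
) -> pd.DataFrame:
    """Number of conserved peptides per median-position bin.

    Bins partition the 1-based coordinate axis as [1, w], [w+1, 2w], ...;
    each list peptide contributes once to the bin holding its median
    position, peptides absent from every record contribute nowhere.
    Returns columns bin_start, bin_end, n_peptides covering bins up to
    the largest occupied one (empty record sets give an empty table).
    """
    if bin_width < 1:
        raise ValueError("bin_width must be >= 1")
    medians = [
        pos.median_position
        for p in peptide_list.peptides
        if (pos := peptide_median_position(p, records)).n_sequences > 0
    ]
    if not medians:
        return pd.DataFrame(columns=["bin_start", "bin_end", "n_peptides"])
    indices = [int(m - 1) // bin_width for m in medians]
    n_bins = max(indices) + 1
    counts = [0] * n_bins
    for i in indices:
        counts[i] += 1
    return pd.DataFrame(
        {
            "bin_start": [1 + i * bin_width for i in range(n_bins)],
            "bin_end": [(i + 1) * bin_width for i in range(n_bins)],
            "n_peptides": counts,
        }
    )


def find_serine_motifs(peptide_list: PeptideList) -> list[SerineMotifHit]:
    """All G-x-S-x windows inside the list's peptides.

    One hit per (peptide, offset); the pattern fixes glycine at the first
    and serine at the third of four consecutive residues.
    """
    hits = []
    for pep in peptide_list.peptides:
        for i in range(len(pep) - 3):
            if pep[i] == "G" and pep[i + 2] == "S":
                hits.append(SerineMotifHit(pep, pep[i : i + 4], i))
    return hits
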