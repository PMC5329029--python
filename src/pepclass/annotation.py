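"""Annotation of proteins and raw genomes against group peptide lists.

Proteins are scored against every group-specific peptide list (distinct
list peptides contained in the sequence) and assigned to the top-scoring
group when that score reaches a threshold and the maximum is unique.

Genomes are screened without gene models: the sequence is split into
fragments of 2000 bases overlapping by 100, each fragment is translated
in all six reading frames, and every stop-free translated segment of at
least 51 residues (no start-codon requirement) is scored like a protein.
The overlap exists to rescue genes cut by a fragment boundary; duplicate
segments re-found in the overlap are collapsed.  Coordinates are 0-based
half-open on the forward strand throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from sklearn.base import BaseEstimator

from .ppr import (
    PeptideList,
    PPRParams,
    derive_peptide_list,
    score_protein,
    _as_records,
    UNCLASSIFIED,
)
from .seq_io import GenomeRecord, ProteinRecord

logger = logging.getLogger(__name__)

DEFAULT_MIN_SCORE = 5

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def _codon_map(table_id: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


def translate_dna(dna: str, table_id: int = 1) -> str:
    """Translate in-frame DNA; trailing partial codon ignored.

    Stop codons become ``*``.  Any codon outside the unambiguous code
    (e.g. containing N) becomes ``X``: an N-codon is never trusted to be
    a stop, and ``X`` is excluded from peptide matching downstream.
    """
    mapping = _codon_map(table_id)
    return "".join(
        mapping.get(dna[i : i + 3], "X") for i in range(0, len(dna) - 2, 3)
    )


@dataclass(frozen=True)
class GenomeScanParams:
    """Fragmenting/translation parameters of the genome screen.

    fragment_length / overlap: bases (defaults 2000 / 100).
    min_orf_residues: minimum stop-free segment length kept (default 51,
    i.e. "longer than 50 residues").
    """

    fragment_length: int = 2000
    overlap: int = 100
    min_orf_residues: int = 51
    translation_table: int = 1

    def __post_init__(self) -> None:
        if not 0 <= self.overlap < self.fragment_length:
            raise ValueError("require 0 <= overlap < fragment_length")
        if self.min_orf_residues < 1:
            raise ValueError("min_orf_residues must be >= 1")


@dataclass
class OrfHit:
    """A translated stop-free segment from a genome fragment.

    ``genome_start``/``genome_end`` are 0-based half-open on the forward
    strand; ``frame`` is the offset (0-2) within the fragment on the
    strand read.  ``scores`` maps group_id -> peptide-list score once the
    hit has been scored; ``best_group`` is None when unassigned.
    """

    genome_id: str
    fragment_offset: int
    strand: str
    frame: int
    peptide: str
    genome_start: int
    genome_end: int
    scores: dict[int, int] = field(default_factory=dict)
    best_group: int | None = None
    ambiguous: bool = False


@dataclass(frozen=True)
class ProteinAssignment:
    id: str
    best_group: int | None
    score: int
    scores: Mapping[int, int]
    ambiguous: bool = False


@dataclass(frozen=True)
class AnnotationResult:
    assignments: tuple[ProteinAssignment, ...]
    min_score: int

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "id": a.id,
                "best_group": UNCLASSIFIED if a.best_group is None else a.best_group,
                "score": a.score,
                "ambiguous": a.ambiguous,
            }
            for a in self.assignments
        ]
        return pd.DataFrame(rows, columns=["id", "best_group", "score", "ambiguous"])

    def assigned_counts(self) -> dict[int, int]:
        """Assigned items per group id."""
        counts: dict[int, int] = {}
        for a in self.assignments:
            if a.best_group is not None:
                counts[a.best_group] = counts.get(a.best_group, 0) + 1
        return counts


def _assign(scores: Mapping[int, int], min_score: int) -> tuple[int | None, bool]:
    """Argmax assignment; ties or sub-threshold maxima are unassigned.

    Returns (group or None, ambiguous) where ambiguous flags a tie at an
    above-threshold maximum.
    """
    if not scores:
        return None, False
    best = max(scores.values())
    if best < min_score:
        return None, False
    winners = [g for g, s in scores.items() if s == best]
    if len(winners) > 1:
        return None, True
    return winners[0], False


def annotate_proteins(
    records: Sequence[ProteinRecord],
    lists: Sequence[PeptideList],
    min_score: int = DEFAULT_MIN_SCORE,
) -> AnnotationResult:
    """Score every protein against every peptide list and assign groups."""
    group_ids = [pl.group_id for pl in lists]
    if not lists:
        raise ValueError("at least one peptide list is required")
    if len(set(group_ids)) != len(group_ids):
        raise ValueError("peptide lists carry duplicate group_ids")
    assignments = []
    for rec in records:
        scores = {pl.group_id: score_protein(rec.sequence, pl) for pl in lists}
        best, ambiguous = _assign(scores, min_score)
        assignments.append(
            ProteinAssignment(
                id=rec.id,
                best_group=best,
                score=max(scores.values()),
                scores=scores,
                ambiguous=ambiguous,
            )
        )
    return AnnotationResult(tuple(assignments), min_score)


def fragment_genome(
    genome: GenomeRecord, params: GenomeScanParams | None = None
) -> list[tuple[int, str]]:
    """Split a genome into overlapping fragments.

    Fragments start at offsets 0, fragment_length - overlap, ...; the
    last fragment runs to the genome end and may be shorter.  Every base
    is covered by at least one fragment.  Fragments shorter than one
    codon are dropped.
    """
    params = params or GenomeScanParams()
    seq = genome.sequence
    step = params.fragment_length - params.overlap
    offsets = [0]
    while offsets[-1] + params.fragment_length < len(seq):
        offsets.append(offsets[-1] + step)
    fragments = [(off, seq[off : off + params.fragment_length]) for off in offsets]
    return [(off, frag) for off, frag in fragments if len(frag) >= 3]


def _stop_free_segments(aa: str) -> Iterable[tuple[str, int]]:
    """Maximal '*'-free runs of a translated frame with codon-index starts."""
    start = 0
    for i, c in enumerate(aa):
        if c == "*":
            if i > start:
                yield aa[start:i], start
            start = i + 1
    if len(aa) > start:
        yield aa[start:], start


def six_frame_orfs(
    fragment: tuple[int, str],
    params: GenomeScanParams | None = None,
    genome_id: str = "",
) -> list[OrfHit]:
    """Translate one fragment in six frames and keep long stop-free segments.

    Segments are stop-to-stop with no start-codon requirement; segments
    truncated by the fragment edge are kept when long enough, since the
    screen cannot see past the fragment.  Codons containing N translate
    to ``X`` (kept in the peptide, never matched).
    """
    params = params or GenomeScanParams()
    offset, seq = fragment
    L = len(seq)
    hits: list[OrfHit] = []
    for strand, read in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            aa = translate_dna(read[frame:], params.translation_table)
            for segment, codon_start in _stop_free_segments(aa):
                if len(segment) < params.min_orf_residues:
                    continue
                span = 3 * len(segment)
                if strand == "+":
                    start = offset + frame + 3 * codon_start
                    end = start + span
                else:
                    end = offset + L - (frame + 3 * codon_start)
                    start = end - span
                hits.append(
                    OrfHit(
                        genome_id=genome_id,
                        fragment_offset=offset,
                        strand=strand,
                        frame=frame,
                        peptide=segment,
                        genome_start=start,
                        genome_end=end,
                    )
                )
    return hits


def scan_genome(
    genome: GenomeRecord,
    lists: Sequence[PeptideList],
    params: GenomeScanParams | None = None,
    min_score: int = DEFAULT_MIN_SCORE,
) -> list[OrfHit]:
    """Fragment, six-frame translate, score and assign a whole genome.

    Duplicate segments found in two overlapping fragments — identical
    (strand, genome_start, genome_end) — are collapsed to the earliest
    fragment's copy.  Output is sorted by genome_start, then strand.
    """
    params = params or GenomeScanParams()
    group_ids = [pl.group_id for pl in lists]
    if len(set(group_ids)) != len(group_ids):
        raise ValueError("peptide lists carry duplicate group_ids")
    seen: set[tuple[str, int, int]] = set()
    hits: list[OrfHit] = []
    for fragment in fragment_genome(genome, params):
        for hit in six_frame_orfs(fragment, params, genome.id):
            key = (hit.strand, hit.genome_start, hit.genome_end)
            if key in seen:
                continue
            seen.add(key)
            hits.append(hit)
    for hit in hits:
        hit.scores = {pl.group_id: score_protein(hit.peptide, pl) for pl in lists}
        hit.best_group, hit.ambiguous = _assign(hit.scores, min_score)
    hits.sort(key=lambda h: (h.genome_start, h.strand, h.genome_end))
    logger.info(
        "scan_genome(%s): %d ORFs, %d assigned",
        genome.id, len(hits), sum(h.best_group is not None for h in hits),
    )
    return hits


def hits_to_frame(hits: Sequence[OrfHit]) -> pd.DataFrame:
    rows = [
        {
            "genome_id": h.genome_id,
            "start": h.genome_start,
            "end": h.genome_end,
            "strand": h.strand,
            "frame": h.frame,
            "length_aa": len(h.peptide),
            "best_group": UNCLASSIFIED if h.best_group is None else h.best_group,
            "score": max(h.scores.values()) if h.scores else 0,
        }
        for h in hits
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "genome_id", "start", "end", "strand", "frame",
            "length_aa", "best_group", "score",
        ],
    )


def hits_to_bed(hits: Sequence[OrfHit]) -> str:
    """BED6 lines for assigned hits; name = group id, score capped at 1000."""
    lines = []
    for h in hits:
        if h.best_group is None:
            continue
        score = min(1000, max(h.scores.values()) if h.scores else 0)
        lines.append(
            f"{h.genome_id}\t{h.genome_start}\t{h.genome_end}"
            f"\tgroup{h.best_group}\t{score}\t{h.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")


def summarize_by_class(
    results: Sequence[tuple[str, str, AnnotationResult]],
    expected_classes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Mean assigned count per organism class, overall and per group.

    ``results`` holds (organism_id, class_label, AnnotationResult); every
    organism must carry a non-empty class label.  Returns one row per
    class with ``n_organisms``, per-group mean columns ``group_<id>`` and
    a ``total`` column.  Expected classes with no organisms are omitted
    with a warning.
    """
    per_org = []
    for organism, label, result in results:
        if not label:
            raise ValueError(f"organism {organism!r} has no class label")
        counts = result.assigned_counts()
        per_org.append((organism, label, counts))
    all_groups = sorted({g for _, _, c in per_org for g in c})
    classes = sorted({label for _, label, _ in per_org})
    if expected_classes is not None:
        for label in expected_classes:
            if label not in classes:
                logger.warning("summarize_by_class: class %r has no organisms", label)
    rows = []
    for label in classes:
        members = [c for _, lab, c in per_org if lab == label]
        row: dict[str, object] = {"class": label, "n_organisms": len(members)}
        for g in all_groups:
            row[f"group_{g}"] = float(np.mean([c.get(g, 0) for c in members]))
        row["total"] = float(np.mean([sum(c.values()) for c in members]))
        rows.append(row)
    columns = ["class", "n_organisms"] + [f"group_{g}" for g in all_groups] + ["total"]
    return pd.DataFrame(rows, columns=columns)


class PeptideAnnotator(BaseEstimator):
    """Peptide-list classifier in scikit-learn form.

    ``fit(X, y)`` derives one conserved-peptide list per class from
    labelled sequences (labels of -1 are treated as unclassified and
    ignored); alternatively build the estimator from precomputed lists
    with :meth:`from_peptide_lists`.  ``predict`` assigns each sequence
    to the top-scoring list, or -1 when no score reaches ``min_score`` or
    the maximum is tied.
    """

    def __init__(
        self,
        min_score: int = DEFAULT_MIN_SCORE,
        peptide_length: int = 6,
        peptides_per_group: int = 70,
    ):
        self.min_score = min_score
        self.peptide_length = peptide_length
        self.peptides_per_group = peptides_per_group

    def fit(self, X: Sequence, y: Sequence[int]) -> "PeptideAnnotator":
        records = _as_records(X)
        y = np.asarray(list(y), dtype=int)
        if len(y) != len(records):
            raise ValueError("X and y length mismatch")
        params = PPRParams(
            peptide_length=self.peptide_length,
            peptides_per_protein=1,
            peptides_per_group=self.peptides_per_group,
        )
        lists = []
        for label in np.unique(y):
            if label == UNCLASSIFIED:
                continue
            members = [r for r, lab in zip(records, y) if lab == label]
            lists.append(derive_peptide_list(members, params, int(label)))
        self.peptide_lists_ = tuple(lists)
        self.classes_ = np.array([pl.group_id for pl in lists], dtype=int)
        return self

    @classmethod
    def from_peptide_lists(
        cls, lists: Sequence[PeptideList], min_score: int = DEFAULT_MIN_SCORE
    ) -> "PeptideAnnotator":
        lengths = {pl.peptide_length for pl in lists if len(pl)}
        est = cls(
            min_score=min_score,
            peptide_length=lengths.pop() if len(lengths) == 1 else 6,
        )
        est.peptide_lists_ = tuple(lists)
        est.classes_ = np.array([pl.group_id for pl in lists], dtype=int)
        return est

    def annotate(self, X: Sequence) -> AnnotationResult:
        records = _as_records(X)
        return annotate_proteins(records, self.peptide_lists_, self.min_score)

    def decision_function(self, X: Sequence) -> pd.DataFrame:
        """Score matrix: one row per sequence, one column per group id."""
        records = _as_records(X)
        data = {
            pl.group_id: [score_protein(r.sequence, pl) for r in records]
            for pl in self.peptide_lists_
        }
        return pd.DataFrame(data, index=[r.id for r in records])

    def predict(self, X: Sequence) -> np.ndarray:
        result = self.annotate(X)
        return np.array(
            [
                UNCLASSIFIED if a.best_group is None else a.best_group
                for a in result.assignments
            ],
            dtype=int,
        )
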