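"""Peptide pattern recognition (PPR): conserved-hexapeptide clustering.

PPR partitions a set of protein sequences into groups defined not by
alignment but by shared short conserved peptides.  Each group carries a
bounded "peptide list" — the most widely shared fixed-length peptides
among its members (hexapeptides at the default length of 6) — and a
protein belongs to the group when it contains at least a threshold number
of distinct list peptides.  The defaults reproduce the published
operating point for carbohydrate-esterase family classification: peptide
length 6, membership threshold 10 peptides per protein, list size 70
peptides per group.

Group formation is an iterative seed-and-refine scheme: seed a candidate
group from the single most protein-frequent peptide, then alternate
between deriving the peptide list from the current members and re-electing
members as all proteins scoring at or above the threshold, until the
member set reaches a fixed point.  Groups are peeled off one at a time;
whatever cannot form a group of at least ``min_group_size`` members ends
up unclassified.  Everything is deterministic for a fixed input order:
ties in peptide frequency are broken lexicographically, and a refinement
cycle falls back to the largest member set visited (earliest on ties).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .seq_io import ProteinRecord

logger = logging.getLogger(__name__)

UNCLASSIFIED = -1


@dataclass(frozen=True)
class PPRParams:
    """Tunable parameters of the PPR clustering.

    peptide_length
        Length of the conserved peptide unit (residues).
    peptides_per_protein
        Minimum number of distinct group-list peptides a protein must
        contain to count as a group member.
    peptides_per_group
        Maximum size of a group's peptide list.
    min_group_size
        Minimum member count for a group to be reported.
    max_iterations
        Cap on list<->membership refinement rounds per group.
    """

    peptide_length: int = 6
    peptides_per_protein: int = 10
    peptides_per_group: int = 70
    min_group_size: int = 2
    max_iterations: int = 100

    def __post_init__(self) -> None:
        for name in (
            "peptide_length", "peptides_per_protein", "peptides_per_group",
            "min_group_size", "max_iterations",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.peptides_per_protein > self.peptides_per_group:
            raise ValueError("peptides_per_protein must not exceed peptides_per_group")


@dataclass(frozen=True)
class PeptideList:
    """The ordered conserved-peptide list defining one PPR group.

    Peptides are sorted by descending protein frequency, ties broken by
    ascending lexicographic order; ``frequencies`` aligns with
    ``peptides``.  Peptides containing ``X`` are never listed.
    """

    group_id: int
    peptides: tuple[str, ...]
    frequencies: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.peptides)) != len(self.peptides):
            raise ValueError("peptide list entries must be distinct")
        if any("X" in p for p in self.peptides):
            raise ValueError("peptide list entries must not contain 'X'")
        lengths = {len(p) for p in self.peptides}
        if len(lengths) > 1:
            raise ValueError("peptide list entries must share one length")

    def __len__(self) -> int:
        return len(self.peptides)

    @property
    def peptide_length(self) -> int:
        return len(self.peptides[0]) if self.peptides else 0


@dataclass(frozen=True)
class PPRGroup:
    group_id: int
    member_ids: tuple[str, ...]
    peptide_list: PeptideList
    member_scores: tuple[int, ...]  # aligned with member_ids


@dataclass(frozen=True)
class PPRGroupSet:
    """Outcome of a PPR clustering run: a partition of the input."""

    groups: tuple[PPRGroup, ...]
    unclassified: tuple[str, ...]
    params: PPRParams

    def labels(self, ids: Sequence[str]) -> np.ndarray:
        """Group id per input id (UNCLASSIFIED, i.e. -1, if in no group)."""
        lookup = {m: g.group_id for g in self.groups for m in g.member_ids}
        return np.array([lookup.get(i, UNCLASSIFIED) for i in ids], dtype=int)

    @property
    def peptide_lists(self) -> tuple[PeptideList, ...]:
        return tuple(g.peptide_list for g in self.groups)


def extract_peptides(sequence: str, length: int) -> list[tuple[str, int]]:
    """All overlapping windows of ``length`` with 1-based start positions.

    Windows containing ``X`` are excluded.  Sequences shorter than
    ``length`` yield an empty list.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    out = []
    for i in range(len(sequence) - length + 1):
        window = sequence[i : i + length]
        if "X" not in window:
            out.append((window, i + 1))
    return out


def peptide_kmer_set(sequence: str, length: int) -> frozenset[str]:
    """Distinct X-free windows of ``length`` in ``sequence``."""
    return frozenset(p for p, _ in extract_peptides(sequence, length))


def peptide_protein_frequency(
    records: Sequence[ProteinRecord], length: int
) -> Counter[str]:
    """Map peptide -> number of proteins containing it.

    Presence counting: a peptide occurring twice within one protein still
    counts once for that protein.
    """
    counts: Counter[str] = Counter()
    for rec in records:
        counts.update(peptide_kmer_set(rec.sequence, length))
    return counts


def derive_peptide_list(
    records: Sequence[ProteinRecord], params: PPRParams, group_id: int
) -> PeptideList:
    """The ``peptides_per_group`` most protein-frequent peptides.

    Ties at any rank are broken by ascending lexicographic order; fewer
    peptides are returned when fewer distinct ones exist.
    """
    if not records:
        raise ValueError("cannot derive a peptide list from zero records")
    freq = peptide_protein_frequency(records, params.peptide_length)
    ranked = sorted(freq.items(), key=lambda kv: (-kv[1], kv[0]))
    top = ranked[: params.peptides_per_group]
    return PeptideList(
        group_id=group_id,
        peptides=tuple(p for p, _ in top),
        frequencies=tuple(n for _, n in top),
    )


def score_protein(sequence: str, peptide_list: PeptideList) -> int:
    """Number of distinct list peptides occurring in ``sequence``.

    Each peptide counts once regardless of copy number.  Because all list
    entries share one length, the count is the size of the intersection
    between the list and the sequence's k-mer set.
    """
    k = peptide_list.peptide_length
    if k == 0:
        return 0
    return len(peptide_kmer_set(sequence, k) & set(peptide_list.peptides))


def form_group(
    working: Sequence[ProteinRecord], params: PPRParams, group_id: int
) -> tuple[PPRGroup | None, list[ProteinRecord]]:
    """Attempt to peel one group off ``working``.

    Seed members are all proteins containing the single most
    protein-frequent peptide (ties lexicographic).  The list<->membership
    refinement then runs to a fixed point; if the member set revisits an
    earlier state without stabilising, the largest visited state wins
    (earliest on ties).  Returns ``(group, remaining)`` or
    ``(None, working)`` when no group of ``min_group_size`` forms.
    """
    if not working:
        raise ValueError("form_group requires a non-empty working set")
    freq = peptide_protein_frequency(working, params.peptide_length)
    if not freq:
        return None, list(working)
    seed_peptide = min(freq.items(), key=lambda kv: (-kv[1], kv[0]))[0]
    members = [r for r in working if seed_peptide in r.sequence]

    # Each visited state pairs the peptide list with the member set that
    # list elects, so the membership-score contract holds for whichever
    # state is finally kept.
    visited: list[tuple[PeptideList, list[ProteinRecord]]] = []
    visited_keys: list[frozenset[str]] = []
    current = members
    final: tuple[PeptideList, list[ProteinRecord]] | None = None
    for _ in range(params.max_iterations):
        if not current:
            break
        plist = derive_peptide_list(current, params, group_id)
        elected = [
            r for r in working
            if score_protein(r.sequence, plist) >= params.peptides_per_protein
        ]
        key = frozenset(r.id for r in elected)
        if key == frozenset(r.id for r in current):
            final = (plist, elected)
            break
        if key in visited_keys:
            cycle_states = visited + [(plist, elected)]
            final = max(cycle_states, key=lambda st: len(st[1]))
            break
        visited.append((plist, elected))
        visited_keys.append(key)
        current = elected
    else:
        if visited:
            final = max(visited, key=lambda st: len(st[1]))

    if final is None or len(final[1]) < params.min_group_size:
        return None, list(working)
    plist, members = final
    member_ids = tuple(r.id for r in members)
    scores = tuple(score_protein(r.sequence, plist) for r in members)
    group = PPRGroup(group_id, member_ids, plist, scores)
    member_set = set(member_ids)
    remaining = [r for r in working if r.id not in member_set]
    return group, remaining


def ppr_cluster(
    records: Sequence[ProteinRecord], params: PPRParams | None = None
) -> PPRGroupSet:
    """Partition curated records into PPR groups.

    Groups are formed greedily with ids 1, 2, 3, ... in formation order
    until no further group forms; leftovers are unclassified.  The run is
    deterministic for a fixed input order.
    """
    params = params or PPRParams()
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("record ids must be unique (curate the input first)")
    working = list(records)
    groups: list[PPRGroup] = []
    group_id = 1
    while working:
        group, working = form_group(working, params, group_id)
        if group is None:
            break
        logger.info(
            "ppr_cluster: group %d formed with %d members",
            group.group_id, len(group.member_ids),
        )
        groups.append(group)
        group_id += 1
    return PPRGroupSet(
        groups=tuple(groups),
        unclassified=tuple(r.id for r in working),
        params=params,
    )


def _as_records(X: Sequence) -> list[ProteinRecord]:
    """Accept ProteinRecords or plain sequences; synthesise ids as needed."""
    records = []
    for i, item in enumerate(X):
        if isinstance(item, ProteinRecord):
            records.append(item)
        else:
            records.append(ProteinRecord(id=f"seq{i:06d}", sequence=str(item)))
    return records


class PPRClusterer(ClusterMixin, BaseEstimator):
    """Scikit-learn style estimator for PPR clustering.

    Parameters mirror :class:`PPRParams`.  ``fit(X)`` accepts a sequence
    of :class:`ProteinRecord` or plain amino-acid strings.

    Attributes (after fit)
    ----------------------
    labels_ : ndarray of shape (n_sequences,)
        Group id per input sequence; -1 marks unclassified.
    group_set_ : PPRGroupSet
        Full clustering outcome (members, peptide lists, scores).
    peptide_lists_ : tuple of PeptideList
        Group-specific conserved peptide lists, by formation order.

    Examples
    --------
    >>> clu = PPRClusterer(peptide_length=6, peptides_per_protein=10,
    ...                    peptides_per_group=70)
    >>> labels = clu.fit_predict(records)      # doctest: +SKIP
    """

    def __init__(
        self,
        peptide_length: int = 6,
        peptides_per_protein: int = 10,
        peptides_per_group: int = 70,
        min_group_size: int = 2,
        max_iterations: int = 100,
    ):
        self.peptide_length = peptide_length
        self.peptides_per_protein = peptides_per_protein
        self.peptides_per_group = peptides_per_group
        self.min_group_size = min_group_size
        self.max_iterations = max_iterations

    def _params(self) -> PPRParams:
        return PPRParams(
            peptide_length=self.peptide_length,
            peptides_per_protein=self.peptides_per_protein,
            peptides_per_group=self.peptides_per_group,
            min_group_size=self.min_group_size,
            max_iterations=self.max_iterations,
        )

    def fit(self, X: Sequence, y=None) -> "PPRClusterer":
        records = _as_records(X)
        self.group_set_ = ppr_cluster(records, self._params())
        self.labels_ = self.group_set_.labels([r.id for r in records])
        self.peptide_lists_ = self.group_set_.peptide_lists
        self.n_groups_ = len(self.group_set_.groups)
        return self
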