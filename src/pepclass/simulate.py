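"""Synthetic protein families and genomes with known ground truth.

The generator emulates the statistical structure the peptide-pattern
method assumes: several protein families, each defined by a consensus
sequence whose residues inside one or more "motif regions" are (nearly)
invariant across members while the background diverges heavily, plus
unrelated random background proteins, and genomes in which family genes
are planted on either strand between stretches of random intergenic DNA.
Ground-truth labels, planted motif peptides and gene coordinates are
emitted alongside the sequences.

Defaults mirror the study conditions of the esterase-family analysis:
300-residue proteins with a 40-residue conserved window at residues
160-200 (0-based, half-open), 50% per-residue background substitution,
exact motif conservation.  All randomness flows from an explicit seed;
there is no global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

from .annotation import reverse_complement, translate_dna
from .seq_io import AMINO_ACIDS, GenomeRecord, ProteinRecord

Interval = tuple[int, int]


@dataclass(frozen=True)
class FamilySpec:
    """Parameters of a synthetic protein-family benchmark.

    motif_regions are 0-based half-open residue intervals where member
    sequences stay at (or near) the family consensus; elsewhere each
    residue is redrawn from ``mutation_alphabet`` with probability
    ``background_substitution_rate``.  A redrawn residue may coincide
    with the original unless the mutation alphabet excludes it.
    """

    seed: int
    n_groups: int = 3
    members_per_group: int = 20
    sequence_length: int = 300
    motif_regions: tuple[Interval, ...] = ((160, 200),)
    background_substitution_rate: float = 0.5
    motif_substitution_rate: float = 0.0
    n_background: int = 0
    alphabet: str = AMINO_ACIDS
    mutation_alphabet: str | None = None

    def __post_init__(self) -> None:
        for rate in (self.background_substitution_rate, self.motif_substitution_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("substitution rates must lie in [0, 1]")
        for start, end in self.motif_regions:
            if not 0 <= start < end <= self.sequence_length:
                raise ValueError(
                    f"motif region [{start}, {end}) outside sequence length "
                    f"{self.sequence_length}"
                )
        if self.n_groups < 1 or self.members_per_group < 1:
            raise ValueError("n_groups and members_per_group must be positive")

    def conserved_peptide_capacity(self, peptide_length: int = 6) -> int:
        """Guaranteed shared peptides per group: window starts inside motifs."""
        return sum(
            max(0, end - start - peptide_length + 1)
            for start, end in self.motif_regions
        )


@dataclass(frozen=True)
class PlantedGene:
    genome_id: str
    gene_id: str
    group_id: int
    start: int   # 0-based half-open, forward strand, coding region only
    end: int
    strand: str
    peptide: str


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth emitted alongside synthetic data.

    labels: record id -> group id (-1 for background records).
    group_motifs: group id -> the hexapeptides guaranteed shared by all
    members (consensus windows fully inside motif regions).
    genes: planted-gene coordinates for synthetic genomes.
    """

    labels: dict[str, int] = field(default_factory=dict)
    group_motifs: dict[int, tuple[str, ...]] = field(default_factory=dict)
    genes: tuple[PlantedGene, ...] = ()


def _random_sequence(rng: np.random.Generator, length: int, alphabet: str) -> str:
    letters = list(alphabet)
    return "".join(rng.choice(letters, size=length))


def generate_families(
    spec: FamilySpec,
    peptide_length: int = 6,
    require_capacity: int | None = None,
) -> tuple[list[ProteinRecord], SyntheticTruth]:
    """Generate labelled protein families plus background proteins.

    Per group a random consensus is drawn; each member copies it,
    redrawing non-motif residues at the background rate and motif
    residues at the motif rate.  Record ids encode nothing about group
    membership (labels live only in the truth); record order is shuffled
    deterministically.

    ``require_capacity`` asserts that the motif regions can support at
    least that many guaranteed shared peptides per group (e.g. the
    membership threshold of a downstream clustering); an infeasible spec
    fails loudly rather than producing an unlearnable benchmark.
    """
    capacity = spec.conserved_peptide_capacity(peptide_length)
    if require_capacity is not None and capacity < require_capacity:
        raise ValueError(
            f"motif regions support only {capacity} guaranteed shared "
            f"{peptide_length}-mers per group; {require_capacity} required"
        )
    rng = np.random.default_rng(spec.seed)
    mutation_alphabet = spec.mutation_alphabet or spec.alphabet
    in_motif = np.zeros(spec.sequence_length, dtype=bool)
    for start, end in spec.motif_regions:
        in_motif[start:end] = True

    sequences: list[tuple[str, int]] = []  # (sequence, label)
    group_motifs: dict[int, tuple[str, ...]] = {}
    for group in range(1, spec.n_groups + 1):
        consensus = _random_sequence(rng, spec.sequence_length, spec.alphabet)
        motifs = []
        for start, end in spec.motif_regions:
            for i in range(start, end - peptide_length + 1):
                motifs.append(consensus[i : i + peptide_length])
        group_motifs[group] = tuple(dict.fromkeys(motifs))
        rates = np.where(
            in_motif, spec.motif_substitution_rate, spec.background_substitution_rate
        )
        for _ in range(spec.members_per_group):
            mutate = rng.random(spec.sequence_length) < rates
            replacements = rng.choice(list(mutation_alphabet), size=spec.sequence_length)
            member = "".join(
                replacements[i] if mutate[i] else consensus[i]
                for i in range(spec.sequence_length)
            )
            sequences.append((member, group))
    for _ in range(spec.n_background):
        sequences.append(
            (_random_sequence(rng, spec.sequence_length, spec.alphabet), -1)
        )

    order = rng.permutation(len(sequences))
    records, labels = [], {}
    for new_idx, old_idx in enumerate(order):
        seq, label = sequences[old_idx]
        rec_id = f"syn{new_idx:05d}"
        records.append(ProteinRecord(rec_id, seq, "synthetic protein"))
        labels[rec_id] = label
    return records, SyntheticTruth(labels=labels, group_motifs=group_motifs)


def _reverse_translate(rng: np.random.Generator, peptide: str, table_id: int = 1) -> str:
    table = CodonTable.unambiguous_dna_by_id[table_id]
    by_aa: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    for codons in by_aa.values():
        codons.sort()
    return "".join(str(rng.choice(by_aa[aa])) for aa in peptide)


def generate_genome(
    genes: Sequence[tuple[str, int]],
    intergenic_length: int = 500,
    seed: int = 0,
    genome_id: str = "syngenome",
    table_id: int = 1,
) -> tuple[GenomeRecord, SyntheticTruth]:
    """Plant protein-coding genes in random DNA.

    Each (peptide, group) gene is reverse-translated with uniformly random
    synonymous codons, flanked by in-frame stop codons, placed on a
    randomly chosen strand, and separated from its neighbours (and the
    genome ends) by ``intergenic_length`` bases of random DNA.  Truth
    coordinates cover the coding region only (0-based half-open, forward
    strand); translating that interval — reverse-complemented for '-'
    genes — reproduces the peptide exactly.
    """
    for peptide, _ in genes:
        if "*" in peptide or "X" in peptide:
            raise ValueError("gene peptides must be stop-free and unambiguous")
    rng = np.random.default_rng(seed)
    parts: list[str] = []
    planted: list[PlantedGene] = []
    cursor = 0

    def emit(chunk: str) -> None:
        nonlocal cursor
        parts.append(chunk)
        cursor += len(chunk)

    emit(_random_sequence(rng, intergenic_length, "ACGT"))
    for idx, (peptide, group) in enumerate(genes):
        cds = _reverse_translate(rng, peptide, table_id)
        stops = CodonTable.unambiguous_dna_by_id[table_id].stop_codons
        cassette = str(rng.choice(sorted(stops))) + cds + str(rng.choice(sorted(stops)))
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            cassette = reverse_complement(cassette)
        start = cursor + 3
        end = start + len(cds)
        emit(cassette)
        planted.append(
            PlantedGene(
                genome_id=genome_id,
                gene_id=f"gene{idx:04d}",
                group_id=group,
                start=start,
                end=end,
                strand=strand,
                peptide=peptide,
            )
        )
        emit(_random_sequence(rng, intergenic_length, "ACGT"))
    genome = GenomeRecord(genome_id, "".join(parts), "synthetic genome")
    for gene in planted:
        segment = genome.sequence[gene.start : gene.end]
        if gene.strand == "-":
            segment = reverse_complement(segment)
        assert translate_dna(segment, table_id) == gene.peptide
    return genome, SyntheticTruth(genes=tuple(planted))
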