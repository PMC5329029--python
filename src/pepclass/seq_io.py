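"""Sequence input/output and curation.

Reads protein and DNA FASTA into light record types, applies the two
curation steps used throughout the pipeline (exact-sequence deduplication
and a minimum-length filter), and writes every tabular report as TSV.

The protein alphabet is the 20 standard residues plus ``X``.  Anything
else on input (B, Z, J, U, O, ambiguity codes, digits) is mapped to ``X``
on read; ``X`` never participates in hexapeptide matching downstream, so
the mapping is conservative: it can only suppress motif hits, never
invent them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + "X")
DNA_ALPHABET = frozenset("ACGTN")

#: Minimum retained protein length after curation (residues).
DEFAULT_MIN_LENGTH = 51


@dataclass(frozen=True)
class ProteinRecord:
    """One amino-acid sequence with identifier and free-text provenance."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"protein record {self.id!r} has empty sequence")
        bad = set(self.sequence) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"protein record {self.id!r} contains residues outside the "
                f"21-letter alphabet: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GenomeRecord:
    """One DNA sequence over {A, C, G, T, N}."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"genome record {self.id!r} has empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"genome record {self.id!r} contains non-ACGTN characters: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _clean_protein(raw: str) -> str:
    seq = raw.upper().replace("*", "")
    seq = "".join(seq.split())
    return "".join(c if c in PROTEIN_ALPHABET else "X" for c in seq)


def _clean_dna(raw: str) -> str:
    seq = "".join(raw.upper().split())
    return "".join(c if c in DNA_ALPHABET else "N" for c in seq)


def read_protein_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased, ``*`` (stop) characters and whitespace are
    stripped, and residues outside the 21-letter alphabet are mapped to
    ``X``.  Entries with an empty sequence are rejected with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"protein FASTA not found: {path}")
    records: list[ProteinRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = _clean_protein(str(entry.seq))
        if not seq:
            logger.warning("read_protein_fasta: rejected empty entry %r", entry.id)
            continue
        records.append(ProteinRecord(entry.id, seq, entry.description))
    logger.info("read_protein_fasta: %d records from %s", len(records), path)
    return records


def read_genome_fasta(path: str | Path) -> list[GenomeRecord]:
    """Read a DNA FASTA file; non-ACGTN characters are mapped to ``N``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"genome FASTA not found: {path}")
    records: list[GenomeRecord] = []
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = _clean_dna(str(entry.seq))
        if not seq:
            logger.warning("read_genome_fasta: rejected empty entry %r", entry.id)
            continue
        records.append(GenomeRecord(entry.id, seq, entry.description))
    logger.info("read_genome_fasta: %d records from %s", len(records), path)
    return records


def write_fasta(records: Iterable[ProteinRecord | GenomeRecord], path: str | Path) -> None:
    """Write records to FASTA (60-column wrapped)."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description or "")
        for r in records
    ]
    with open(path, "w") as handle:
        SeqIO.write(seqrecs, handle, "fasta")


def deduplicate(records: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    """Remove exact full-sequence duplicates, keeping the first occurrence.

    Duplicate means string equality of the sequence, not of the id: pooled
    database hits routinely carry the same sequence under different
    accessions.  Output order is the input order of the survivors.
    """
    seen: set[str] = set()
    kept: list[ProteinRecord] = []
    for rec in records:
        if rec.sequence in seen:
            continue
        seen.add(rec.sequence)
        kept.append(rec)
    logger.info("deduplicate: kept %d of %d records", len(kept), len(records))
    return kept


def filter_by_length(
    records: Sequence[ProteinRecord], min_length: int = DEFAULT_MIN_LENGTH
) -> list[ProteinRecord]:
    """Retain records with sequence length >= ``min_length`` (default 51)."""
    if min_length < 1:
        raise ValueError("min_length must be >= 1")
    kept = [r for r in records if len(r.sequence) >= min_length]
    logger.info(
        "filter_by_length(min=%d): kept %d of %d records",
        min_length, len(kept), len(records),
    )
    return kept


def curate(
    records: Sequence[ProteinRecord], min_length: int = DEFAULT_MIN_LENGTH
) -> list[ProteinRecord]:
    """Fixed curation order: deduplicate, then length-filter."""
    return filter_by_length(deduplicate(records), min_length)


def write_table(rows: pd.DataFrame | Sequence[dict], path: str | Path) -> None:
    """Write tabular data as TSV with a header row.

    Row order is the caller's; every report in this package sorts rows by a
    documented key before writing so output is byte-reproducible.
    """
    frame = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table`."""
    return pd.read_csv(path, sep="\t")
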