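"""End-to-end orchestration: curate -> cluster -> profile -> scan -> report.

A run takes a protein FASTA (plus optional genome FASTAs), executes the
full peptide-pattern workflow and writes a directory of TSV reports, the
effective configuration, and a manifest listing every output with its
row count.  Reports carry documented sort keys so a rerun with the same
configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import seq_io
from .annotation import (
    GenomeScanParams,
    hits_to_bed,
    hits_to_frame,
    scan_genome,
)
from .ppr import PPRParams, PeptideList, UNCLASSIFIED, ppr_cluster, score_protein
from .profile import find_serine_motifs, peptide_median_position, position_histogram
from .seq_io import read_genome_fasta, read_protein_fasta, write_table

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Fully resolved configuration of one pipeline run."""

    proteins: str
    out_dir: str
    genomes: tuple[str, ...] = ()
    peptide_length: int = 6
    peptides_per_protein: int = 10
    peptides_per_group: int = 70
    min_group_size: int = 2
    max_iterations: int = 100
    min_length: int = 51
    min_score: int = 5
    fragment_length: int = 2000
    overlap: int = 100
    min_orf_residues: int = 51
    bin_width: int = 20
    seed: int = 0

    def ppr_params(self) -> PPRParams:
        return PPRParams(
            peptide_length=self.peptide_length,
            peptides_per_protein=self.peptides_per_protein,
            peptides_per_group=self.peptides_per_group,
            min_group_size=self.min_group_size,
            max_iterations=self.max_iterations,
        )

    def scan_params(self) -> GenomeScanParams:
        return GenomeScanParams(
            fragment_length=self.fragment_length,
            overlap=self.overlap,
            min_orf_residues=self.min_orf_residues,
        )


def _toml_value(value) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return str(value)
    if isinstance(value, (tuple, list)):
        return "[" + ", ".join(_toml_value(v) for v in value) + "]"
    return '"' + str(value).replace("\\", "\\\\").replace('"', '\\"') + '"'


def write_config(config: RunConfig, path: str | Path) -> None:
    lines = [
        f"{f.name} = {_toml_value(getattr(config, f.name))}"
        for f in dataclasses.fields(config)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path: str | Path) -> RunConfig:
    import tomllib

    with open(path, "rb") as handle:
        data = tomllib.load(handle)
    if "genomes" in data:
        data["genomes"] = tuple(data["genomes"])
    return RunConfig(**data)


def peptide_lists_to_frame(lists: list[PeptideList]) -> pd.DataFrame:
    rows = [
        {
            "group_id": pl.group_id,
            "rank": rank,
            "peptide": pep,
            "protein_frequency": freq,
        }
        for pl in lists
        for rank, (pep, freq) in enumerate(zip(pl.peptides, pl.frequencies), start=1)
    ]
    return pd.DataFrame(
        rows, columns=["group_id", "rank", "peptide", "protein_frequency"]
    )


def peptide_lists_from_frame(frame: pd.DataFrame) -> list[PeptideList]:
    lists = []
    for group_id, part in frame.groupby("group_id", sort=True):
        part = part.sort_values("rank")
        lists.append(
            PeptideList(
                group_id=int(group_id),
                peptides=tuple(part["peptide"]),
                frequencies=tuple(int(f) for f in part["protein_frequency"]),
            )
        )
    return lists


def read_peptide_lists(path: str | Path) -> list[PeptideList]:
    return peptide_lists_from_frame(seq_io.read_table(path))


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full workflow; returns the output directory.

    Reports written (sort keys in parentheses):
      peptide_lists.tsv   (group_id, rank)
      membership.tsv      (protein_id; unclassified rows carry group -1)
      profile_positions.tsv (group_id, rank)
      position_histogram.tsv (group_id, bin_start)
      serine_motifs.tsv   (group_id, peptide, offset)
      <genome>.hits.tsv / <genome>.hits.bed per scanned genome (start, strand)
      config.toml, manifest.tsv
    """
    proteins_path = Path(config.proteins)
    if not proteins_path.exists():
        raise FileNotFoundError(f"protein input not found: {proteins_path}")
    genome_paths = [Path(g) for g in config.genomes]
    for g in genome_paths:
        if not g.exists():
            raise FileNotFoundError(f"genome input not found: {g}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: list[dict] = []

    def report(name: str, n_rows: int) -> None:
        manifest.append({"file": name, "n_rows": n_rows})

    t0 = time.perf_counter()
    records = read_protein_fasta(proteins_path)
    curated = seq_io.curate(records, config.min_length)
    logger.info("pipeline: curated %d -> %d records", len(records), len(curated))

    group_set = ppr_cluster(curated, config.ppr_params())
    lists = list(group_set.peptide_lists)

    lists_frame = peptide_lists_to_frame(lists)
    write_table(lists_frame, out_dir / "peptide_lists.tsv")
    report("peptide_lists.tsv", len(lists_frame))

    by_id = {r.id: r for r in curated}
    membership_rows = [
        {"protein_id": m, "group_id": g.group_id, "score": s}
        for g in group_set.groups
        for m, s in zip(g.member_ids, g.member_scores)
    ] + [
        {"protein_id": u, "group_id": UNCLASSIFIED, "score": 0}
        for u in group_set.unclassified
    ]
    membership = pd.DataFrame(
        membership_rows, columns=["protein_id", "group_id", "score"]
    ).sort_values("protein_id", kind="stable", ignore_index=True)
    write_table(membership, out_dir / "membership.tsv")
    report("membership.tsv", len(membership))

    position_rows, histogram_frames, motif_rows = [], [], []
    for group in group_set.groups:
        members = [by_id[m] for m in group.member_ids]
        for rank, pep in enumerate(group.peptide_list.peptides, start=1):
            pos = peptide_median_position(pep, members)
            position_rows.append(
                {
                    "group_id": group.group_id,
                    "rank": rank,
                    "peptide": pep,
                    "n_sequences": pos.n_sequences,
                    "median_position": (
                        "" if pos.median_position is None else pos.median_position
                    ),
                }
            )
        hist = position_histogram(group.peptide_list, members, config.bin_width)
        hist.insert(0, "group_id", group.group_id)
        histogram_frames.append(hist)
        for hit in find_serine_motifs(group.peptide_list):
            motif_rows.append(
                {
                    "group_id": group.group_id,
                    "peptide": hit.peptide,
                    "motif": hit.motif,
                    "offset": hit.offset,
                }
            )

    positions = pd.DataFrame(
        position_rows,
        columns=["group_id", "rank", "peptide", "n_sequences", "median_position"],
    )
    write_table(positions, out_dir / "profile_positions.tsv")
    report("profile_positions.tsv", len(positions))

    histogram = (
        pd.concat(histogram_frames, ignore_index=True)
        if histogram_frames
        else pd.DataFrame(columns=["group_id", "bin_start", "bin_end", "n_peptides"])
    )
    write_table(histogram, out_dir / "position_histogram.tsv")
    report("position_histogram.tsv", len(histogram))

    motifs = pd.DataFrame(
        motif_rows, columns=["group_id", "peptide", "motif", "offset"]
    ).sort_values(["group_id", "peptide", "offset"], kind="stable", ignore_index=True)
    write_table(motifs, out_dir / "serine_motifs.tsv")
    report("serine_motifs.tsv", len(motifs))

    for path in genome_paths:
        for genome in read_genome_fasta(path):
            hits = scan_genome(genome, lists, config.scan_params(), config.min_score)
            frame = hits_to_frame(hits)
            name = f"{genome.id}.hits.tsv"
            write_table(frame, out_dir / name)
            report(name, len(frame))
            bed_name = f"{genome.id}.hits.bed"
            (out_dir / bed_name).write_text(hits_to_bed(hits))
            report(bed_name, sum(h.best_group is not None for h in hits))

    write_config(config, out_dir / "config.toml")
    report("config.toml", len(dataclasses.fields(RunConfig)))
    manifest_frame = pd.DataFrame(manifest, columns=["file", "n_rows"])
    write_table(manifest_frame, out_dir / "manifest.tsv")
    logger.info("pipeline: finished in %.2f s", time.perf_counter() - t0)
    return out_dir
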