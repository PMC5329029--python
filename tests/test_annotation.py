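from __future__ import annotations

import numpy as np
import pytest

from pepclass import (
    FamilySpec,
    GenomeRecord,
    GenomeScanParams,
    PeptideAnnotator,
    PeptideList,
    annotate_proteins,
    fragment_genome,
    generate_families,
    generate_genome,
    ppr_cluster,
    reverse_complement,
    scan_genome,
    six_frame_orfs,
    summarize_by_class,
    translate_dna,
)
from pepclass.annotation import AnnotationResult, ProteinAssignment

import oracles
from conftest import make_records


def _lists_for(*peptide_sets: tuple[str, ...]) -> list[PeptideList]:
    return [PeptideList(i + 1, peps) for i, peps in enumerate(peptide_sets)]


AAS = "ACDEFGHIKLMNPQRSTVWY"


def _random_peptides(rng, n: int) -> tuple[str, ...]:
    return tuple(sorted({"".join(rng.choice(list(AAS), 6)) for _ in range(n)}))


class TestAnnotateProteins:
    def _fixture(self, rng):
        a = _random_peptides(rng, 20)
        b = _random_peptides(rng, 20)
        return _lists_for(a, b), a, b

    def test_assigned_to_argmax_above_threshold(self, rng):
        lists, a, b = self._fixture(rng)
        seq = "".join(a[:12]) + "".join(b[:3])   # scores {1: 12, 2: >=3}
        result = annotate_proteins(make_records([seq]), lists, min_score=5)
        (assign,) = result.assignments
        assert assign.best_group == 1
        assert assign.scores[1] >= 12 and not assign.ambiguous

    def test_subthreshold_unassigned(self, rng):
        lists, a, b = self._fixture(rng)
        seq = "".join(a[:4])                     # best score 4 < 5
        (assign,) = annotate_proteins(make_records([seq]), lists, 5).assignments
        assert assign.best_group is None and not assign.ambiguous

    def test_tie_flagged_ambiguous(self, rng):
        lists, a, b = self._fixture(rng)
        seq = "".join(a[:7]) + "".join(b[:7])
        (assign,) = annotate_proteins(make_records([seq]), lists, 5).assignments
        if assign.scores[1] == assign.scores[2]:  # junction peptides can break the tie
            assert assign.best_group is None and assign.ambiguous

    def test_exact_tie_is_ambiguous(self):
        lists = _lists_for(("AAAAAA",), ("CCCCCC",))
        (assign,) = annotate_proteins(
            make_records(["AAAAAAWWCCCCCC"]), lists, min_score=1
        ).assignments
        assert assign.best_group is None and assign.ambiguous

    def test_duplicate_group_ids_rejected(self):
        lists = [PeptideList(1, ("AAAAAA",)), PeptideList(1, ("CCCCCC",))]
        with pytest.raises(ValueError):
            annotate_proteins(make_records(["AAAAAA"]), lists, 1)

    def test_scores_equal_bruteforce_for_every_pair(self, rng):
        lists, a, b = self._fixture(rng)
        seqs = ["".join(rng.choice(list(AAS), 100)) for _ in range(10)]
        result = annotate_proteins(make_records(seqs), lists, 5)
        for seq, assign in zip(seqs, result.assignments):
            for plist in lists:
                assert assign.scores[plist.group_id] == oracles.substring_score(
                    seq, plist.peptides
                )


class TestFragmentGenome:
    @pytest.mark.parametrize(
        "length, offsets, lengths",
        [
            (3900, [0, 1900], [2000, 2000]),
            (1500, [0], [1500]),
            (4000, [0, 1900, 3800], [2000, 2000, 200]),
            (2000, [0], [2000]),
            (2001, [0, 1900], [2000, 101]),
        ],
    )
    def test_offsets_and_lengths(self, length, offsets, lengths):
        genome = GenomeRecord("g", "A" * length)
        frags = fragment_genome(genome, GenomeScanParams())
        assert [o for o, _ in frags] == offsets
        assert [len(s) for _, s in frags] == lengths

    def test_every_base_covered(self):
        genome = GenomeRecord("g", "A" * 5731)
        frags = fragment_genome(genome, GenomeScanParams())
        covered = np.zeros(5731, dtype=bool)
        for off, seq in frags:
            covered[off : off + len(seq)] = True
        assert covered.all()

    def test_subcodon_genome_dropped(self):
        assert fragment_genome(GenomeRecord("g", "AT"), GenomeScanParams()) == []

    def test_params_validated(self):
        with pytest.raises(ValueError):
            GenomeScanParams(fragment_length=100, overlap=100)


def _codon_free_dna(rng, n_codons: int) -> str:
    """In-frame DNA with no stop codons."""
    safe = [c for c in oracles.GENETIC_CODE if oracles.GENETIC_CODE[c] != "*"]
    return "".join(rng.choice(safe) for _ in range(n_codons))


class TestSixFrameOrfs:
    def test_planted_stop_free_stretch_found_once(self, rng):
        cds = _codon_free_dna(rng, 60)
        frag_seq = "TAA" + cds + "TGA" + "TAA" * 40
        hits = six_frame_orfs((0, frag_seq), GenomeScanParams(), "g")
        forward0 = [h for h in hits if h.strand == "+" and h.frame == 0]
        assert len(forward0) == 1
        hit = forward0[0]
        assert len(hit.peptide) == 60
        assert hit.peptide == oracles.translate(cds)
        assert (hit.genome_start, hit.genome_end) == (3, 3 + 180)

    @pytest.mark.parametrize("n_codons, kept", [(51, True), (50, False)])
    def test_length_threshold_at_51_residues(self, rng, n_codons, kept):
        frag = "TAA" + _codon_free_dna(rng, n_codons) + "TAA"
        hits = six_frame_orfs((0, frag), GenomeScanParams(), "g")
        in_frame0 = [h for h in hits if h.strand == "+" and h.frame == 0]
        assert bool(in_frame0) is kept

    def test_all_stop_reading_frame_yields_nothing(self):
        # every codon of forward frame 0 is a stop, so that frame has no
        # segments; the shifted frames of a TAA repeat read N/I runs and
        # legitimately survive
        hits = six_frame_orfs((0, "TAATAATAA" * 30), GenomeScanParams(), "g")
        assert [h for h in hits if h.strand == "+" and h.frame == 0] == []

    def test_edge_segments_without_stop_are_kept(self, rng):
        frag = _codon_free_dna(rng, 60)  # no stops at all
        hits = six_frame_orfs((0, frag), GenomeScanParams(), "g")
        assert any(h.strand == "+" and h.frame == 0 for h in hits)

    def test_coordinate_round_trip_on_random_genome(self, rng):
        genome = "".join(rng.choice(list("ACGT"), 6000))
        params = GenomeScanParams(min_orf_residues=20)
        for off in (0, 1900):
            frag = (off, genome[off : off + 2000])
            for hit in six_frame_orfs(frag, params, "g"):
                segment = genome[hit.genome_start : hit.genome_end]
                if hit.strand == "-":
                    segment = oracles.revcomp(segment)
                assert oracles.translate(segment) == hit.peptide
                assert hit.genome_end - hit.genome_start == 3 * len(hit.peptide)

    def test_n_codons_translate_to_x(self):
        assert translate_dna("ATGNNNAAA") == "MXK"
        assert translate_dna("TAN") == "X"   # never trusted as a stop


class TestScanGenome:
    def test_matches_bruteforce_strand_peptide_sets(self, rng):
        lists = _lists_for(_random_peptides(rng, 10))
        for _ in range(3):
            genome_seq = "".join(rng.choice(list("ACGT"), 12000))
            genome = GenomeRecord("g", genome_seq)
            hits = scan_genome(genome, lists, GenomeScanParams(), 5)
            got = {(h.strand, h.peptide) for h in hits}
            assert got == oracles.six_frame_peptides(genome_seq)

    def test_minus_strand_planted_gene_assigned(self, family_data):
        spec, records, truth = family_data
        gs = ppr_cluster(records)
        by_id = {r.id: r for r in records}
        member = by_id[gs.groups[0].member_ids[0]]
        # force the gene onto the minus strand by regenerating until truth says so
        for seed in range(100):
            genome, gtruth = generate_genome(
                [(member.sequence, gs.groups[0].group_id)], 400, seed=seed
            )
            if gtruth.genes[0].strand == "-":
                break
        gene = gtruth.genes[0]
        assert gene.strand == "-"
        hits = scan_genome(genome, list(gs.peptide_lists), GenomeScanParams(), 5)
        matching = [
            h
            for h in hits
            if h.best_group == gene.group_id
            and h.strand == "-"
            and h.genome_start <= gene.start
            and h.genome_end >= gene.end
        ]
        assert matching

    def test_random_dna_yields_no_assignments(self, rng, family_data):
        _, records, _ = family_data
        gs = ppr_cluster(records)
        genome = GenomeRecord("rand", "".join(rng.choice(list("ACGT"), 30000)))
        hits = scan_genome(genome, list(gs.peptide_lists), GenomeScanParams(), 5)
        assert all(h.best_group is None for h in hits)

    def test_scan_deterministic(self, rng):
        lists = _lists_for(_random_peptides(rng, 10))
        genome = GenomeRecord("g", "".join(rng.choice(list("ACGT"), 8000)))
        assert scan_genome(genome, lists) == scan_genome(genome, lists)

    def test_overlap_duplicates_collapsed(self, rng):
        # an ORF living entirely inside the overlap window appears in two
        # fragments but must be reported once
        params = GenomeScanParams(fragment_length=400, overlap=200, min_orf_residues=30)
        cassette = "TAA" + _codon_free_dna(rng, 35) + "TAA"  # 111 bases
        lead = 230
        genome_seq = "".join(rng.choice(list("ACGT"), lead)) + cassette
        genome_seq += "".join(rng.choice(list("ACGT"), 700 - len(genome_seq)))
        genome = GenomeRecord("g", genome_seq)
        # the cassette's interior sits inside fragments [0,400) and [200,600)
        raw = [
            (h.strand, h.genome_start, h.genome_end)
            for off, frag in fragment_genome(genome, params)
            for h in six_frame_orfs((off, frag), params, "g")
        ]
        target = ("+", lead + 3, lead + 3 + 105)
        assert raw.count(target) == 2
        hits = scan_genome(genome, _lists_for(("AAAAAA",)), params, 5)
        keys = [(h.strand, h.genome_start, h.genome_end) for h in hits]
        assert keys.count(target) == 1
        assert len(keys) == len(set(keys))


class TestSummarizeByClass:
    def _result(self, n_assigned: int, group: int = 1) -> AnnotationResult:
        assignments = tuple(
            ProteinAssignment(f"p{i}", group, 10, {group: 10})
            for i in range(n_assigned)
        )
        return AnnotationResult(assignments, 5)

    def test_uniform_counts_mean(self):
        results = [(f"org{i}", "coprophilic", self._result(4)) for i in range(4)]
        table = summarize_by_class(results)
        assert table.loc[0, "total"] == 4.0
        assert table.loc[0, "group_1"] == 4.0

    def test_mixed_counts_mean(self):
        counts = [1, 0, 2, 1]
        results = [(f"org{i}", "white_rot", self._result(c)) for i, c in enumerate(counts)]
        table = summarize_by_class(results)
        assert table.loc[0, "total"] == 1.0

    def test_unlabeled_organism_rejected(self):
        with pytest.raises(ValueError):
            summarize_by_class([("org", "", self._result(1))])

    def test_expected_empty_class_omitted_with_warning(self, caplog):
        results = [("org", "brown_rot", self._result(1))]
        with caplog.at_level("WARNING"):
            table = summarize_by_class(results, expected_classes=["brown_rot", "gray_rot"])
        assert list(table["class"]) == ["brown_rot"]
        assert any("gray_rot" in m for m in caplog.messages)


class TestPeptideAnnotatorEstimator:
    def test_fit_predict_recovers_family_labels(self, family_data):
        _, records, truth = family_data
        y = np.array([truth.labels[r.id] for r in records])
        est = PeptideAnnotator(min_score=10).fit(records, y)
        pred = est.predict(records)
        assert (pred == y).all()

    def test_from_peptide_lists_matches_function(self, family_data):
        _, records, _ = family_data
        gs = ppr_cluster(records)
        est = PeptideAnnotator.from_peptide_lists(list(gs.peptide_lists), min_score=5)
        result = est.annotate(records)
        direct = annotate_proteins(records, list(gs.peptide_lists), 5)
        assert result == direct
        scores = est.decision_function(records)
        assert scores.shape == (len(records), len(gs.groups))
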