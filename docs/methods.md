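# Methods

## Model

pepclass treats a protein family as a bag of conserved fixed-length
peptides rather than an alignable sequence. For peptide length `k`
(default 6) the *protein frequency* of a peptide is the number of input
proteins containing it at least once (presence, not occurrence count —
conservation is a property of the family, not of tandem repeats within
one sequence). A group's peptide list holds the `peptides_per_group`
most frequent peptides among its members, ranked by descending frequency
with ascending lexicographic order breaking ties; a protein's score
against a list is the number of distinct list peptides it contains, and
membership requires `score ≥ peptides_per_protein`.

Since every list entry has length `k`, scoring is implemented as the
intersection of the sequence's k-mer set with the list — identical to
naive substring counting (the test suite re-checks this equivalence with
an independent substring oracle).

### Group formation

The published description of the method fixes the contract — groups of
proteins sharing a bounded list of conserved peptides — but not the
search procedure, so the procedure here is a deterministic seed-and-refine
reconstruction, chosen so that every step is unit-testable:

1. Seed: the single most protein-frequent peptide over the working set
   (ties: lexicographically smallest); seed members are all proteins
   containing it.
2. Refine: derive the peptide list from the current members, then
   re-elect members as *all* working proteins scoring at or above the
   threshold. Repeat until the member set reaches a fixed point.
3. Termination: each refinement state pairs the derived list with the
   member set that list elects, so the membership-score contract holds
   for whichever state is kept. If the member set revisits an earlier
   state without stabilising (a cycle), the largest visited member set
   wins, earliest on ties; `max_iterations` (default 100) caps the loop.
4. A group is reported only with `≥ min_group_size` members (default 2 —
   one sequence cannot define shared conservation); it is then removed
   and the search repeats on the remainder. Group ids are 1, 2, 3, … in
   formation order; when no further group forms, the leftovers are
   unclassified.

The outcome is a strict partition (each protein in exactly one group or
unclassified) and is byte-deterministic for a fixed input order.

A consequence of seeding from a single peptide with `min_group_size = 2`:
two otherwise unrelated proteins that share one chance k-mer can form a
small group, because a 70-peptide list derived from two proteins is
trivially satisfied by those same two proteins. For 300-residue random
sequences the per-pair chance of a shared hexamer is ≈ 1.4 × 10⁻³, so
benchmarks with ~15 background proteins occasionally show one spurious
2-member group; planted-family recovery stays at adjusted Rand ≥ 0.97.
Raising `min_group_size` suppresses this at the cost of dropping genuine
small families.

### Parameters

| parameter | default | meaning |
|---|---|---|
| `peptide_length` | 6 | conserved unit (residues) |
| `peptides_per_protein` | 10 | membership score threshold |
| `peptides_per_group` | 70 | peptide-list cap |
| `min_group_size` | 2 | smallest reportable group |
| `min_length` | 51 | curation: shortest retained protein |
| `min_score` | 5 | annotation threshold (proteins and ORFs) |
| `fragment_length` / `overlap` | 2000 / 100 | genome fragmenting (bases) |
| `min_orf_residues` | 51 | shortest kept translated segment |
| `bin_width` | 20 | positional histogram bin (residues) |

The 6/10/70 operating point and the 51-residue curation floor are the
published settings for esterase-family classification; `min_score = 5`
for annotation is this package's default — well below the 10-peptide
membership criterion yet far above random hexamer collision noise (a
random 300-residue sequence shares ≥ 5 of 70 specific hexamers with
probability ≪ 10⁻¹⁰). `bin_width = 20` is likewise a package choice; both
are configurable.

## Curation

Input proteins are uppercased, `*` and whitespace stripped, and any
residue outside the 20 standard letters mapped to `X`; `X` never occurs
in a counted peptide or a peptide list, so unknown residues can only
suppress matches, never create them. Duplicates are removed by exact
full-sequence equality (pooled database hits share sequences under
different accessions), first occurrence kept; then sequences shorter
than `min_length` are dropped. Order fixed: deduplicate, then filter;
counts are logged at each step.

## Genome scanning

Genomes are split into fragments starting at offsets 0, 1900, 3800, …
(step = fragment − overlap); the last fragment runs to the genome end.
Each fragment is translated in six frames with the standard genetic
code; codons containing `N` (or otherwise outside the unambiguous code)
translate to `X` rather than being resolved or trusted as stops. Stop-free
segments of ≥ `min_orf_residues` are kept with no start-codon
requirement — this is a crude sensitivity-first screen, not gene
prediction — and segments truncated by a fragment edge are kept, since
the screen cannot see past the fragment. Coordinates are 0-based
half-open on the forward strand; re-translating `genome[start:end]`
(reverse-complemented for `−` hits) reproduces the reported peptide, a
round-trip the tests assert. Identical `(strand, start, end)` segments
re-found in the overlap are collapsed to one hit. Hits are scored like
proteins against every list and assigned to the unique argmax when it
reaches `min_score`; ties are reported unassigned and flagged ambiguous.

## Positional statistics

A peptide's position in a family is the median over member sequences of
its 1-based first-occurrence start (first occurrence because the median
is over sequences; the median itself because it is robust to length
variation and truncation). Even counts give the mean of the central
pair, kept fractional. Histogram bins partition positions as [1, w],
[w+1, 2w], …, each list peptide contributing once at its median. The
serine scan reports every 4-residue window with glycine first and serine
third (G-x-S-x), the context of the nucleophilic serine in
alpha/beta-hydrolases.

## Pairwise identity

Global alignment uses BLOSUM62 with gap open 10 and extension 0.5 (the
first position of a gap costs 10, later positions 0.5). Identity is
100 × identical pairs / gap-free columns; the denominator convention
(gapless columns rather than alignment length or shorter-sequence
length) was an open choice and is fixed here. Because several alignments
can share the optimal score with slightly different identities, each
pair is aligned in canonical lexicographic order, making
`identity(a, b) = identity(b, a)` exact. Different aligners and
conventions shift identities by a few percent; comparisons should use
one convention throughout.

## Synthetic data

`generate_families` draws one random consensus per group and copies it
to members, redrawing each residue outside the motif regions with
probability `background_substitution_rate` (default 0.5; replacements
drawn uniformly from the alphabet, so the effective divergence is
0.5 × 19/20 ≈ 0.475 per residue) and motif residues at
`motif_substitution_rate` (default 0). The default motif region,
residues [160, 200) of a 300-residue protein, mirrors the conservation
hotspot observed around the catalytic serine in the esterase families
and yields 35 guaranteed shared hexamers per group — comfortably above
the 10-peptide membership threshold; two 40-residue blocks would
saturate a 70-peptide list. `generate_families(..., require_capacity=t)`
fails loudly if the motif regions cannot guarantee `t` shared peptides.
Background proteins are fully random; record ids are shuffled and encode
nothing about the labels, which live only in the emitted truth object.

`generate_genome` reverse-translates each gene peptide with uniformly
random synonymous codons, flanks it with in-frame stop codons, places it
on a random strand and separates genes by `intergenic_length` random
bases; truth records the coding coordinates, and a round-trip assertion
re-translates every planted interval at generation time.

What the generator does *not* emulate: indels and length variation,
phylogenetic correlation between members, rate heterogeneity along the
sequence, codon-usage bias, introns, and genuine intergenic composition.
Passing the planted-recovery tests therefore demonstrates correctness of
the machinery under the model's own assumptions (block conservation in
divergent background), not performance on real, indel-rich families.

## Benchmark sizes and numerical choices

The test suite and the acceptance script run on 3 families × 20 members
(300 residues) plus 15 background proteins, 20 seeded replicates, and
synthetic genomes up to ~50 kb — sizes at which every contract is
checkable exactly against brute-force oracles while the whole suite runs
in seconds. All randomness flows from explicit seeds (no global state);
reports sort by documented keys; repeated runs are byte-identical, which
the acceptance script verifies by hashing.

## Known limitations

- Greedy group peeling is order-dependent by construction: a protein
  satisfying two groups' thresholds joins the earlier-formed group.
  Strict partition is asserted; overlapping membership is not modelled.
- The genome screen reports stop-to-stop segments, not gene models; a
  real gene split across fragments without fitting in either is missed,
  and genes longer than a fragment cannot be recovered whole.
- Small spurious groups among unrelated sequences (see above) are a
  known property of single-peptide seeding at `min_group_size = 2`.
- Identity values are convention-dependent (±few %); only the documented
  convention is reproduced exactly.
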