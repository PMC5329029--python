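# pepclass

Alignment-free classification of protein families by conserved short
peptides, with peptide-list annotation of proteins and raw genomes.

## The problem

Carbohydrate-active enzyme families such as the CE15 carbohydrate
esterases (glucuronoyl esterases, which cleave the ester bonds tying
glucuronoxylan to lignin) are too divergent for reliable annotation by
whole-sequence similarity alone, yet their functional core — e.g. the
region around the Ser–His–Glu catalytic triad — is strongly conserved in
short stretches. Peptide pattern recognition (PPR) exploits this: instead
of aligning whole sequences it groups proteins by the *hexapeptides*
(6-residue substrings) they share.

Each group `g` is defined by a **peptide list** `L_g`: the `m` hexamers
most widely shared among its members (default `m = 70`). A sequence `s`
scores

    score(s, L_g) = |{ p ∈ L_g : p is a substring of s }|,

and belongs to the group when `score ≥ t` (default `t = 10`). Groups are
discovered by seeding from the single most protein-frequent hexapeptide
and alternating *derive list from members* / *elect members by score*
until a fixed point, then peeling the group off and repeating. The same
lists annotate new proteins (assign to the top-scoring list above a
threshold) and raw genomes: the genome is cut into 2 000-base fragments
overlapping by 100, translated in all six reading frames, and every
stop-free segment of ≥ 51 residues is scored like a protein.

The package also provides positional statistics (the position of a
conserved hexamer is the *median* of its first-occurrence start across
the sequences containing it — robust to length variation and truncated
entries), a G-x-S-x catalytic-serine motif scan, global-alignment percent
identity matrices, and a synthetic-data generator that plants families
with known labels, motifs and gene coordinates so every stage is testable
without downloads.

## Worked example

```python
from pepclass import (FamilySpec, PPRClusterer, GenomeScanParams,
                      generate_families, generate_genome, scan_genome,
                      position_histogram)

# three planted 20-member families + 15 unrelated background proteins
spec = FamilySpec(seed=3, n_groups=3, members_per_group=20, n_background=15)
records, truth = generate_families(spec, require_capacity=10)

clu = PPRClusterer().fit(records)          # hexapeptides, t=10, m=70
print(clu.n_groups_, len(clu.group_set_.unclassified))

# where does conservation concentrate in group 1?
by_id = {r.id: r for r in records}
g1 = clu.group_set_.groups[0]
members = [by_id[m] for m in g1.member_ids]
hist = position_histogram(g1.peptide_list, members, bin_width=20)
print(hist.loc[hist.n_peptides.idxmax()].tolist())

# plant one group-1 gene in a genome and re-find it
genome, gtruth = generate_genome([(members[0].sequence, 1)], 500, seed=11)
for h in scan_genome(genome, list(clu.peptide_lists_), GenomeScanParams(), 5):
    if h.best_group is not None:
        print(h.genome_start, h.genome_end, h.strand, h.best_group,
              max(h.scores.values()))
```

Output:

```
3 15
[181.0, 200.0, 25.0]
503 1403 - 1 43
```

The clusterer recovers exactly the three planted families (the 15 random
background proteins stay unclassified); group 1's conserved hexamers peak
in the position bin 181–200, inside the planted 160–200 conservation
window; and the genome scan finds one ORF on the minus strand at bases
503–1403 — precisely the planted coordinates — assigned to group 1 with
43 of its 70 list peptides present.

The same workflow is available from the shell:

```bash
pepclass simulate families --seed 3 --out-dir sim/
pepclass cluster --in sim/families.fasta --out-dir run/
pepclass scan-genome --genome genome.fasta --peptides run/peptide_lists.tsv --out-dir scan/
pepclass run --in sim/families.fasta --out-dir full/   # whole pipeline
```

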