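"""Independent brute-force oracles for the test suite.

Everything here is written against the behavioural contract only and
deliberately shares no code with the package: its own genetic-code table,
its own reverse complement, naive substring scoring, naive fragmenting
and frame translation, a sort-based median, and an exhaustive affine-gap
alignment enumerator for tiny sequences.
"""

from __future__ import annotations

from math import inf

# Standard genetic code, written out independently.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def revcomp(dna: str) -> str:
    return "".join(COMPLEMENT[c] for c in reversed(dna))


def translate(dna: str) -> str:
    out = []
    for i in range(0, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        out.append(GENETIC_CODE.get(codon, "X"))
    return "".join(out)


def substring_score(sequence: str, peptides) -> int:
    """Distinct peptides of the list occurring as substrings of sequence."""
    return sum(1 for p in set(peptides) if p in sequence)


def first_positions(peptide: str, sequences) -> list[int]:
    """1-based first-occurrence positions over sequences containing peptide."""
    out = []
    for seq in sequences:
        idx = seq.find(peptide)
        if idx >= 0:
            out.append(idx + 1)
    return out


def sorted_median(values) -> float:
    """Middle element (odd n) or mean of the central pair (even n)."""
    xs = sorted(values)
    n = len(xs)
    if n % 2:
        return float(xs[n // 2])
    return (xs[n // 2 - 1] + xs[n // 2]) / 2.0


def six_frame_peptides(
    genome: str,
    fragment_length: int = 2000,
    overlap: int = 100,
    min_residues: int = 51,
) -> set[tuple[str, str]]:
    """Brute-force genome screen: the set of (strand, peptide) kept.

    Applies the same contract as the package — overlapping fragments,
    six frames per fragment, stop-free translated segments of at least
    min_residues — from scratch.
    """
    step = fragment_length - overlap
    offsets = [0]
    while offsets[-1] + fragment_length < len(genome):
        offsets.append(offsets[-1] + step)
    found: set[tuple[str, str]] = set()
    for off in offsets:
        frag = genome[off : off + fragment_length]
        if len(frag) < 3:
            continue
        for strand, read in (("+", frag), ("-", revcomp(frag))):
            for frame in range(3):
                aa = translate(read[frame:])
                for segment in aa.split("*"):
                    if len(segment) >= min_residues:
                        found.add((strand, segment))
    return found


def best_affine_alignment_score(
    a: str, b: str, substitution, gap_open: float = -10.0, gap_extend: float = -0.5
) -> float:
    """Exhaustive optimal global alignment score for tiny sequences.

    Enumerates every alignment (match/insert/delete paths); an opened
    gap's first position costs gap_open, later positions gap_extend.
    Exponential — keep len(a) + len(b) small.
    """
    best = -inf

    def rec(i: int, j: int, score: float, prev: str) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, score + substitution[a[i], b[j]], "M")
        if i < len(a):
            cost = gap_extend if prev == "D" else gap_open
            rec(i + 1, j, score + cost, "D")
        if j < len(b):
            cost = gap_extend if prev == "I" else gap_open
            rec(i, j + 1, score + cost, "I")

    rec(0, 0, 0.0, "")
    return best
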