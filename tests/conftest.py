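from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from pepclass import FamilySpec, PPRParams, ProteinRecord, generate_families
from pepclass.ppr import peptide_kmer_set

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: Fixture seed for the clean three-family benchmark.  The planted-recovery
#: example presumes no chance hexapeptide collisions between background
#: proteins; the fixture asserts that precondition rather than trusting it.
CLEAN_SEED = 3


@pytest.fixture(scope="session")
def published_params() -> PPRParams:
    """The published operating point: hexapeptides, threshold 10, list 70."""
    return PPRParams(peptide_length=6, peptides_per_protein=10, peptides_per_group=70)


@pytest.fixture(scope="session")
def family_data():
    """Three 20-member synthetic families plus 15 background proteins.

    Verifies the construction assumption of the recovery example: no
    hexapeptide shared between two background proteins or between a
    background protein and any family member.
    """
    spec = FamilySpec(seed=CLEAN_SEED, n_groups=3, members_per_group=20, n_background=15)
    records, truth = generate_families(spec, require_capacity=10)
    kmers = {r.id: peptide_kmer_set(r.sequence, 6) for r in records}
    background = [r.id for r in records if truth.labels[r.id] == -1]
    family_kmers = frozenset().union(
        *(kmers[r.id] for r in records if truth.labels[r.id] != -1)
    )
    for i, b in enumerate(background):
        assert not (kmers[b] & family_kmers), "fixture precondition violated"
        for other in background[i + 1 :]:
            assert not (kmers[b] & kmers[other]), "fixture precondition violated"
    return spec, records, truth


def make_records(sequences: list[str], prefix: str = "p") -> list[ProteinRecord]:
    return [ProteinRecord(f"{prefix}{i}", s) for i, s in enumerate(sequences, 1)]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
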