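import pytest

from strainref.genomes import GenomeRecord
from strainref.kmerdb import build_profile
from strainref.synthetic import mutate_genome, simulate_genome


@pytest.fixture(scope="session")
def ancestor_50kb():
    return simulate_genome(50_000, gc=0.5, seed=101, strain_id="anc50")


@pytest.fixture(scope="session")
def ancestor_5kb():
    return simulate_genome(5_000, gc=0.5, seed=102, strain_id="anc5")


@pytest.fixture(scope="session")
def mutant_1pct_50kb(ancestor_50kb):
    """1% substitution derivative plus the realized substitution count."""
    return mutate_genome(ancestor_50kb, 0.01, seed=103, strain_id="mut1pct")


@pytest.fixture
def toy_genome():
    return GenomeRecord("toy", "toy_species", ("ACGTACGTACGT",), coverage=50.0)


def make_genome(strain_id, seq, species="sp", coverage=50.0):
    if isinstance(seq, str):
        seq = (seq,)
    return GenomeRecord(strain_id, species, tuple(seq), coverage=coverage)


def profile_of(strain_id, seq, k=5):
    return build_profile(make_genome(strain_id, seq), k=k)
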