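import numpy as np
import pytest

from plastidkit.synthetic import simulate_genome, simulate_reads


@pytest.fixture(scope="session")
def small_genome():
    """A 20 kb circular genome used across database/detection tests."""
    return simulate_genome(20_000, seed=42, id="gA")


@pytest.fixture(scope="session")
def small_panel():
    """Three small genomes: two related accessions and one unrelated."""
    gA = simulate_genome(20_000, seed=1, id="gA")
    gB = simulate_genome(20_000, seed=2, id="gB")
    gC = simulate_genome(20_000, seed=3, id="gC")
    return [("taxA", "gA", gA), ("taxB", "gB", gB), ("taxC", "gC", gC)]


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_dna(rng, length):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
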