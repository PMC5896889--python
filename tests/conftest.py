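import pytest

from duplimap import sim


@pytest.fixture
def two_locus_map():
    """Minimal map: just the two causal loci on their chromosomes."""
    return sim.default_map()


@pytest.fixture
def unlinked_map():
    """Many unlinked loci (one per chromosome) for heterozygosity checks."""
    chroms = [(f"c{i:03d}", 1.0) for i in range(400)]
    loci = [(f"L{i:03d}", f"c{i:03d}", 0.5) for i in range(400)]
    return sim.LinkageMap(chroms, loci)


@pytest.fixture
def rec_rec():
    return sim.two_locus_recessive_recessive()
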