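import pytest

from promoterscope.synthetic import (
    default_motifs,
    make_promoter_genome,
    simulate_cage_tags,
)


@pytest.fixture(scope="session")
def motifs():
    return default_motifs()


@pytest.fixture(scope="session")
def small_dataset():
    """10 promoters per class with CAGE tags — shared read-only fixture."""
    genome, truth, genes = make_promoter_genome(10, seed=101)
    tags = simulate_cage_tags(truth, depth=100_000, seed=102)
    return genome, truth, genes, tags
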