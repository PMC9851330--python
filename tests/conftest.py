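import pytest

from phalife.model import ModelConfig
from phalife.synthetic import (FragmentTokenizer, SyntheticSpec,
                               generate_universe)
from phalife.vocabulary import (build_similarity_graph, build_vocabulary,
                                markov_cluster)


@pytest.fixture(scope="session")
def universe():
    """Default toy universe: 20 clusters, 5 markers at 5x enrichment,
    60 genomes per class."""
    return generate_universe(SyntheticSpec())


@pytest.fixture(scope="session")
def vocab(universe):
    """Vocabulary built through the real pipeline on synthetic alignments."""
    graph = build_similarity_graph(universe.alignment_edges())
    return build_vocabulary(markov_cluster(graph))


@pytest.fixture(scope="session")
def fragment_tokenizer(universe, vocab):
    return FragmentTokenizer(universe, vocab)


@pytest.fixture(scope="session")
def desk_config(vocab):
    return ModelConfig.desk(vocab.size)
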