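import numpy as np
import pytest

from ignorome.synthetic import (
    SyntheticConfig,
    generate_corpus,
    generate_feature_matrix,
    generate_gene_catalog,
    generate_publication_corpus,
)


def stage_corpus(config: SyntheticConfig):
    """Catalog, features and publication corpus without the (slower)
    ancillary tables; used where only the bipartite core matters."""
    rngs = [np.random.default_rng(s)
            for s in np.random.SeedSequence(config.seed).spawn(3)]
    catalog = generate_gene_catalog(config, rngs[0])
    features, fpkm = generate_feature_matrix(catalog, config, rngs[1])
    publications, links, truth = generate_publication_corpus(
        catalog, features, config, rngs[2]
    )
    return catalog, features, fpkm, publications, links, truth


@pytest.fixture(scope="session")
def small_corpus():
    """A complete small corpus with every ancillary table."""
    return generate_corpus(
        SyntheticConfig(n_genes=300, seed=2, generate_sequences=False)
    )


@pytest.fixture(scope="session")
def seq_catalog():
    """A small catalog with real CDS/protein sequences."""
    return generate_gene_catalog(SyntheticConfig(n_genes=40, seed=3))
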