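import numpy as np
import pytest

from lncfuse import FitConfig, RankConfig, SyntheticConfig, generate
from lncfuse.relations import EntityCatalog, RelationMatrix, build_graph


@pytest.fixture(scope="session")
def default_config():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def default_graph(default_config):
    graph, truth = generate(default_config)
    return graph, truth


@pytest.fixture(scope="session")
def default_ranks(default_config):
    return RankConfig(dict(default_config.ranks))


@pytest.fixture(scope="session")
def fit_cfg():
    return FitConfig(seed=7)


@pytest.fixture(scope="session")
def small_config():
    """Tiny graph so a full CV runs in a couple of seconds."""
    return SyntheticConfig(
        sizes={"lncRNA": 60, "miRNA": 40, "gene": 50, "cancer": 3, "prognosis": 3},
        ranks={"lncRNA": 3, "miRNA": 3, "gene": 3, "cancer": 3, "prognosis": 3},
        densities={
            ("lncRNA", "miRNA"): 0.08,
            ("lncRNA", "gene"): 0.05,
            ("lncRNA", "cancer"): 0.15,
            ("miRNA", "gene"): 0.08,
            ("miRNA", "cancer"): 0.30,
            ("gene", "cancer"): 0.18,
            ("gene", "prognosis"): 0.05,
        },
        holdout_fraction=0.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_graph(small_config):
    graph, truth = generate(small_config)
    return graph, truth


def random_tiny_graph(seed, sizes=(6, 5, 4)):
    """Three-type dense random graph for brute-force oracle tests."""
    rng = np.random.default_rng(seed)
    types = ["a", "b", "c"][: len(sizes)]
    catalogs = {
        t: EntityCatalog(t, tuple(f"{t}{i}" for i in range(n)))
        for t, n in zip(types, sizes)
    }
    relations = {}
    for i in range(len(types)):
        for j in range(i + 1, len(types)):
            vals = (rng.random((sizes[i], sizes[j])) < 0.4).astype(float)
            relations[(types[i], types[j])] = RelationMatrix(types[i], types[j], vals)
    # ensure the target block has at least one positive
    tgt = relations[("a", "b")]
    if tgt.nnz == 0:
        tgt.values[0, 0] = 1.0
    return build_graph(catalogs, relations, ("a", "b"))
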