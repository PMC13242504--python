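import numpy as np
import pytest

from grnbench import (
    GeneratorConfig,
    OptimizerConfig,
    SignedGraph,
    default_targets,
    generate_underlying,
    optimize_kingdom,
)
from grnbench.io import make_fixture


@pytest.fixture(scope="session")
def targets():
    return default_targets()


@pytest.fixture(scope="session")
def small_cfg(targets):
    # reduced search budget: plenty for a 20-node topology in unit tests
    return GeneratorConfig(max_iterations=400, n_restarts=1, rng_seed=1,
                           targets=targets)


@pytest.fixture(scope="session")
def underlying(small_cfg):
    return generate_underlying(small_cfg).graph


@pytest.fixture(scope="session")
def tiny_opt_cfg():
    return OptimizerConfig(n_candidates=3, n_iterations=5, M_L_grid=((3, 2),),
                           pool_size=200, rng_seed=7)


@pytest.fixture(scope="session")
def signed_bacteria(underlying, targets, tiny_opt_cfg):
    return optimize_kingdom(underlying, "bacteria", targets, tiny_opt_cfg).signed


@pytest.fixture
def toy_ffl():
    return make_fixture("toy_ffl")


@pytest.fixture
def toy_ffl_signed(toy_ffl):
    return SignedGraph(toy_ffl, {e: +1 for e in toy_ffl.edges})


def random_signed(n=6, p=0.35, seed=0, max_in=5):
    """Random totally signed simple digraph with bounded in-degree."""
    rng = np.random.default_rng(seed)
    g = make_fixture("random_small", seed=seed, n=n, p=p)
    for v in list(g.nodes):
        preds = sorted(g.predecessors(v))
        while len(preds) > max_in:
            u = preds.pop(rng.integers(len(preds)))
            g.remove_edge(u, v)
    signs = {e: (1 if rng.random() < 0.5 else -1) for e in g.sorted_edges()}
    return SignedGraph(g, signs)
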