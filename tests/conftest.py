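import numpy as np
import pandas as pd
import pytest

from ecorules.phylo import GLSContext, Phylogeny
from ecorules.synth import SyntheticScenario, simulate_traits, simulate_tree


@pytest.fixture(scope="session")
def small_tree() -> Phylogeny:
    """Hand-written 3-tip tree with known path lengths."""
    return Phylogeny.from_newick("(A:1,(B:0.5,C:0.5):0.5);")


@pytest.fixture(scope="session")
def star_tree() -> Phylogeny:
    return Phylogeny.from_newick("(A:1,B:1,C:1,D:1,E:1);")


@pytest.fixture(scope="session")
def yule_tree_100() -> Phylogeny:
    return simulate_tree(100, birth_rate=1.0, seed=42)


@pytest.fixture(scope="session")
def yule_ctx_100(yule_tree_100) -> GLSContext:
    return GLSContext.from_tree(yule_tree_100)


@pytest.fixture(scope="session")
def mixed_traits_100(yule_tree_100, yule_ctx_100):
    """Traits under the mixed causal model on the shared 100-tip tree."""
    sc = SyntheticScenario(n_tips=100, causal_model="mixed", seed=42)
    df, truth = simulate_traits(yule_tree_100, sc, ctx=yule_ctx_100)
    return df, truth


def strong_scenario(n_tips: int, causal_model: str, seed: int,
                    direction: str = "phenotype_response",
                    **kw) -> SyntheticScenario:
    """Scenario with strong, easily recoverable causal effects."""
    sc = SyntheticScenario(n_tips=n_tips, causal_model=causal_model,
                           direction=direction, seed=seed, **kw)
    sc.coefficients = dict(sc.coefficients)
    sc.coefficients.update({
        ("temperature", "log_mass"): -0.15,
        ("temperature", "log_beak"): 0.03,
        ("temperature", "log_tarsus"): -0.02,
        ("log_mass", "temperature"): -1.5,
        ("log_beak", "temperature"): 6.0,
        ("log_tarsus", "temperature"): -5.0,
    })
    return sc
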