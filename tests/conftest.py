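import dendropy
import numpy as np
import pandas as pd
import pytest

from beediv import synthetic as syn


def toy_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


@pytest.fixture(scope="session")
def small_system():
    """A 30-species pool with tree and complete traits."""
    tree, pool = syn.simulate_tree(30, seed=101)
    traits = syn.simulate_traits(tree, seed=102)
    return tree, pool, traits


@pytest.fixture(scope="session")
def site_network(small_system):
    """Sites plus communities simulated under the default ground truth."""
    tree, pool, traits = small_system
    sites = syn.simulate_sites(6, 20, seed=103)
    comm = syn.simulate_communities(sites, pool, tree, traits, seed=104)
    return sites, comm


@pytest.fixture(scope="session")
def balanced_tree_32():
    """Balanced ultrametric 32-tip tree, unit depth, for signal checks."""

    def build(labels, depth):
        if len(labels) == 1:
            return f"{labels[0]}:{depth}"
        half = len(labels) // 2
        step = depth / 2
        return f"({build(labels[:half], step)},{build(labels[half:], step)}):{step}"

    labels = [f"t{i:02d}" for i in range(32)]
    half = len(labels) // 2
    nwk = f"({build(labels[:half], 0.5)},{build(labels[half:], 0.5)});"
    return toy_tree(nwk)
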