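import numpy as np
import pytest

from owlaccel.phylo import GTRModel, NeutralModel
from owlaccel.simulate import default_neutral_model, fixture_tree
from owlaccel.trees import Phylogeny


@pytest.fixture(scope="session")
def owl_tree():
    return fixture_tree()


@pytest.fixture(scope="session")
def neutral(owl_tree):
    return default_neutral_model(owl_tree)


@pytest.fixture(scope="session")
def gtr():
    """A mildly asymmetric GTR model used across oracle tests."""
    return GTRModel(np.array([1.0, 3.0, 0.8, 1.2, 3.5, 1.0]),
                    np.array([0.28, 0.22, 0.22, 0.28]))


@pytest.fixture(scope="session")
def tree5():
    return Phylogeny.from_newick(
        "((a:0.1,b:0.2):0.1,((c:0.15,d:0.1):0.1,e:0.3):0.05);",
        foreground=("a", "c"))


@pytest.fixture(scope="session")
def model5(gtr, tree5):
    return NeutralModel(gtr, tree5)
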