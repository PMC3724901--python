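import numpy as np
import pytest

from refugia import divergence, trees


@pytest.fixture
def three_pop_model():
    """((A,B),C) population tree with unit samples, depths 2 and 1."""
    model = divergence.build_divergence_model(
        "((A,B),C);",
        depths=[2.0, 1.0],
        sample_counts={"A": 1, "B": 1, "C": 1},
        regions=("A", "B", "C"),
    )
    assignment = divergence.SampleAssignment(
        {"a": "A", "b": "B", "c": "C"}, ("A", "B", "C")
    )
    return model, assignment


@pytest.fixture
def single_pop_model():
    tree = trees.parse_newick("(P:1.0):0.0;", warn_missing_lengths=False)
    return divergence.PopulationTree(tree=tree, regions=("P",), sample_counts={"P": 2})


@pytest.fixture
def full_assignment():
    return divergence.assignment_from_counts(divergence.DEFAULT_SAMPLE_COUNTS)


def random_ultrametric_tree(n_tips: int, depth: float, seed: int):
    """Random coalescent-shaped ultrametric tree (test helper)."""
    import dendropy
    from dendropy.simulate import treesim
    import random as _random

    rng = _random.Random(seed)
    tns = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    t = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        taxon_namespace=tns,
        num_extant_tips=n_tips,
        rng=rng,
    )
    return trees.scale_to_age(t, depth)
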