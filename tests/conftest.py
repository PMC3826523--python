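import random

import pytest

from paralogon.loci import load_visual_opsin_table
from paralogon.model import ParalogonModel
from paralogon.simulate import MAIN_FAMILIES, simulate_opsin_paralogon
from paralogon.trees import GeneTree, SpeciesTree, build_gene_tree


@pytest.fixture(scope="session")
def opsin_table():
    """Curated cross-species visual opsin coordinates (point anchors)."""
    return load_visual_opsin_table()


@pytest.fixture(scope="session")
def opsin_scenario():
    """Deterministic replay of the scripted opsin-paralogon history."""
    return simulate_opsin_paralogon()


def fit_opsin_scenario(dataset, **overrides):
    params = dict(
        anchor_families=list(MAIN_FAMILIES),
        focal_species="human",
        fission_outgroup="chicken",
        rearrangement_outgroup="gar",
    )
    params.update(overrides)
    return ParalogonModel.from_simulation(dataset, **params).fit()


@pytest.fixture(scope="session")
def opsin_results(opsin_scenario):
    """Full pipeline fit of the scripted scenario (human focal genome)."""
    return fit_opsin_scenario(opsin_scenario)


@pytest.fixture(scope="session")
def oracle_species_tree():
    """Small labeled species tree for reconciliation oracle suites."""
    return SpeciesTree.from_newick(
        "((A,B)AB,((C,D)CD,E)CDE)Root;"
    )


def random_gene_tree(rng: random.Random, species, n_tips: int) -> GeneTree:
    """Random rooted binary gene tree with species drawn with replacement."""
    tips = [f"{rng.choice(species)}|t{i}" for i in range(n_tips)]

    def build(items):
        if len(items) == 1:
            return items[0]
        k = rng.randint(1, len(items) - 1)
        return (build(items[:k]), build(items[k:]))

    shuffled = tips[:]
    rng.shuffle(shuffled)
    return build_gene_tree(build(shuffled))
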