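import random

import pytest

from phyloslice.consensus import ConsensusSequence, Dataset
from phyloslice.registry import LocusRegistry
from phyloslice.taxonomy import TaxonomyTree


@pytest.fixture
def toy_registry():
    reg = LocusRegistry()
    reg.add_locus("rpL8", ["RPL8", "L8"])
    reg.add_locus("rpL9", ["L9"])
    reg.add_locus("rpL14", ["L14"])
    return reg


@pytest.fixture
def toy_tree():
    """root -> orderA{famA1(sp1, sp2), famA2(sp3)}, orderB{famB1(sp4)}."""
    tree = TaxonomyTree("toy")
    tree.add_node(1, "Root", "no rank", None)
    tree.add_node(10, "OrderA", "order", 1)
    tree.add_node(11, "FamA1", "family", 10)
    tree.add_node(111, "Species one", "species", 11)
    tree.add_node(112, "Species two", "species", 11)
    tree.add_node(12, "FamA2", "family", 10)
    tree.add_node(121, "Species three", "species", 12)
    tree.add_node(20, "OrderB", "order", 1)
    tree.add_node(21, "FamB1", "family", 20)
    tree.add_node(211, "Species four", "species", 21)
    tree.validate()
    return tree


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def make_random_tree(rng: random.Random, n_orders=2, n_families=2,
                     n_species=2) -> TaxonomyTree:
    tree = TaxonomyTree("random")
    tree.add_node(1, "Root", "no rank", None)
    for i in range(n_orders):
        order = 100 * (i + 1)
        tree.add_node(order, f"O{i}", "order", 1)
        for j in range(n_families):
            fam = order + 10 * (j + 1)
            tree.add_node(fam, f"F{i}{j}", "family", order)
            for k in range(n_species):
                tree.add_node(fam + k + 1, f"S{i}{j}{k}", "species", fam)
    tree.validate()
    return tree


def make_random_dataset(rng: random.Random, tree: TaxonomyTree,
                        loci=("locA", "locB"), fill=0.8,
                        min_len=30, max_len=90) -> Dataset:
    reg = LocusRegistry()
    for locus in loci:
        reg.add_locus(locus)
    ds = Dataset(reg, tree.label)
    for taxid in tree.species():
        for locus in loci:
            if rng.random() < fill:
                length = 3 * rng.randint(min_len // 3, max_len // 3)
                ds.put(ConsensusSequence(
                    taxid=taxid, locus=locus,
                    dna=random_dna(rng, length),
                    n_input=1, method="single", full_length=False))
    return ds
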