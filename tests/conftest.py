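import numpy as np
import pytest

from sedadna.simulate import SimulationConfig, make_taxonomy_and_refs, simulate_hit_table, simulate_reads
from sedadna.taxonomy import Taxonomy


@pytest.fixture()
def toy_taxonomy() -> Taxonomy:
    """root -> family -> two genera; genus 100 has two species, genus 101 one."""
    tax = Taxonomy()
    tax.add_node(1, 1, "no rank", "root")
    tax.add_node(10, 1, "family", "family_1")
    tax.add_node(100, 10, "genus", "genus_1")
    tax.add_node(101, 10, "genus", "genus_2")
    tax.add_node(1000, 100, "species", "species_1_1")
    tax.add_node(1001, 100, "species", "species_1_2")
    tax.add_node(1002, 101, "species", "species_2_1")
    tax.validate()
    return tax


@pytest.fixture(scope="session")
def sim_bundle():
    """One moderately sized simulated dataset shared across test modules:
    3 genera x 2 species, 20k reads at the default damage parameters."""
    taxonomy, refs = make_taxonomy_and_refs(3, 2, 5000, seed=1)
    config = SimulationConfig(
        taxon_abundances={sp: 1.0 for sp in refs}, n_reads=20_000, seed=2
    )
    reads, truth, metadata = simulate_reads(refs, config)
    hits = simulate_hit_table(reads, truth, refs, taxonomy, seed=1)
    return {
        "taxonomy": taxonomy,
        "refs": refs,
        "config": config,
        "reads": reads,
        "truth": truth,
        "metadata": metadata,
        "hits": hits,
    }


def random_taxonomy(rng: np.random.Generator, n_nodes: int) -> Taxonomy:
    """Random rooted tree: node i's parent is uniform over 0..i-1."""
    tax = Taxonomy()
    tax.add_node(0, 0, "no rank", "root")
    for i in range(1, n_nodes):
        tax.add_node(i, int(rng.integers(0, i)), "clade", f"n{i}")
    return tax


def brute_force_lca(tax: Taxonomy, nodes: set[int]) -> int:
    """Independent oracle: deepest common element of all root-paths."""
    paths = [tax.lineage(n) for n in nodes]
    common = set(paths[0])
    for p in paths[1:]:
        common &= set(p)
    return max(common, key=tax.depth)
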