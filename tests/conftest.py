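import numpy as np
import pytest
from hypothesis import settings

from gaoscope.synthetic_data import SyntheticConfig, generate_dataset
from gaoscope.taxonomy import TaxonNode, TaxonomyTree

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

RANK_SPINE = ["domain", "phylum", "class", "order", "family", "genus", "species"]


def random_tree(rng: np.random.Generator, n_nodes: int = 30) -> TaxonomyTree:
    """Random rooted tree: each node attaches to an earlier node, with a
    rank one step deeper than its parent's (or no_rank)."""
    nodes = [TaxonNode("n0", "n0", "root", "root")]
    depth = {"n0": -1}
    for i in range(1, n_nodes):
        parent = nodes[rng.integers(0, i)]
        d = min(depth[parent.taxon_id] + 1, len(RANK_SPINE) - 1)
        rank = "no_rank" if rng.random() < 0.2 else RANK_SPINE[d]
        nid = f"n{i}"
        nodes.append(TaxonNode(nid, parent.taxon_id, rank, f"taxon {i}"))
        depth[nid] = d
    return TaxonomyTree(nodes)


def brute_force_lca(tree: TaxonomyTree, taxa) -> str:
    """Independent oracle: last common element of the lineage intersection."""
    paths = [tree.lineage(t) for t in taxa]
    common = set(paths[0]).intersection(*map(set, paths[1:]))
    # the deepest common node is the last common entry along any lineage
    return [t for t in paths[0] if t in common][-1]


@pytest.fixture(scope="session")
def tiny_tree() -> TaxonomyTree:
    """root -> family F -> genera G1, G2 (G1 with species S1); family F2 -> G3."""
    return TaxonomyTree(
        [
            TaxonNode("r", "r", "root", "root"),
            TaxonNode("F", "r", "family", "FamF"),
            TaxonNode("G1", "F", "genus", "GenusOne"),
            TaxonNode("G2", "F", "genus", "GenusTwo"),
            TaxonNode("S1", "G1", "species", "SpeciesOne"),
            TaxonNode("F2", "r", "family", "FamF2"),
            TaxonNode("G3", "F2", "genus", "GenusThree"),
        ]
    )


@pytest.fixture(scope="session")
def default_dataset():
    return generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def default_bundle(default_dataset, tmp_path_factory):
    from gaoscope.synthetic_data import write_bundle

    outdir = tmp_path_factory.mktemp("bundle")
    return write_bundle(default_dataset, outdir)
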