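import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from traitnets.network_build import TraitNetwork


def make_network(edges, n_nodes, distances=None, names=None):
    """Build a TraitNetwork directly from an edge dict {(i, j): weight}.

    ``distances`` defaults to the edge weights interpreted as lengths on
    edges (and 0 elsewhere) so hand-worked path examples read naturally.
    """
    adj = np.zeros((n_nodes, n_nodes))
    dist = np.zeros((n_nodes, n_nodes))
    for (i, j), w in edges.items():
        adj[i, j] = adj[j, i] = abs(w)
        dist[i, j] = dist[j, i] = abs(w)
    if distances is not None:
        dist = np.asarray(distances, dtype=float)
    return TraitNetwork(
        trait_names=names or [chr(ord("A") + k) for k in range(n_nodes)],
        adjacency=adj,
        distances=dist,
        alpha=0.05,
        r_signs=np.sign(adj),
    )


@pytest.fixture
def triangle():
    """The worked 3-node example: AB 1.0, BC 0.8, AC 2.0 (lengths = weights)."""
    return make_network({(0, 1): 1.0, (1, 2): 0.8, (0, 2): 2.0}, 3)


@pytest.fixture
def trait_csv(tmp_path):
    """A small on-disk trait table with group labels and missing cells."""
    path = tmp_path / "traits.csv"
    path.write_text(
        "species,growth_form,LMA,N_mass,P_mass\n"
        "sp1,tree,100,20,1.2\n"
        "sp2,tree,80,NA,0.9\n"
        "sp3,shrub,120,25,1.5\n"
        "sp4,shrub,95,18,\n"
        "sp5,tree,110,22,1.1\n"
    )
    return path
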