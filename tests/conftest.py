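import numpy as np
import pytest

from griddiv import phylo, synthetic
from griddiv.grid import GridSpec


@pytest.fixture(scope="session")
def tree50():
    return synthetic.generate_phylogeny(50, seed=101)


@pytest.fixture(scope="session")
def tree100():
    return synthetic.generate_phylogeny(100, seed=202)


@pytest.fixture(scope="session")
def cov100(tree100):
    return phylo.phylo_covariance(tree100)[1]


@pytest.fixture(scope="session")
def grid10():
    return GridSpec(10, 10)


@pytest.fixture(scope="session")
def two_band_map(grid10):
    """10x10 map: biome_1 = columns 0-4, biome_2 = columns 5-9."""
    return synthetic.generate_biome_map(grid10, n_biomes=2, seed=0)


def ultrametric_error(tree):
    """Max spread of root-to-tip path lengths."""
    depths = []
    dist = {}
    for node in tree.preorder_node_iter():
        d = 0.0 if node.parent_node is None else dist[id(node.parent_node)] + (
            node.edge.length or 0.0
        )
        dist[id(node)] = d
        if node.is_leaf():
            depths.append(d)
    return max(depths) - min(depths)


def is_8_connected(cells, grid):
    """True if the cell set forms one 8-connected component."""
    from scipy import ndimage

    mask = np.zeros(grid.n_cells, bool)
    mask[np.asarray(cells, int)] = True
    _, n = ndimage.label(grid.to_array(mask), structure=np.ones((3, 3)))
    return n == 1
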