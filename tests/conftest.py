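import numpy as np
import pytest

from placodevm import (MechanicsParams, build_hex_tissue,
                       select_active_elements, tag_regions)
from placodevm.tissue_geometry import (JUNCTION, EdgeRecord, NodeRecord,
                                       TissueMesh)


@pytest.fixture(scope="session")
def default_mesh():
    """The headline tissue: 6 coronae (127 cells), cable after corona 4,
    7-cell active core."""
    mesh = build_hex_tissue(6)
    mesh = tag_regions(mesh, cable_after_corona=4)
    return select_active_elements(mesh, core_coronae=1)


@pytest.fixture(scope="session")
def small_mesh():
    """A reduced tissue (61 cells) with the same region topology as the
    default: an active core, free interior cells, a closed cable, and two
    exterior coronae."""
    mesh = build_hex_tissue(4)
    mesh = tag_regions(mesh, cable_after_corona=2)
    return select_active_elements(mesh, core_coronae=0)


@pytest.fixture
def params():
    return MechanicsParams()


def make_chain_mesh(positions, cable=True, rest_lengths=None):
    """A bare open chain of junctional nodes joined by consecutive edges.

    Used for single-spring and bending-chain scenarios that need no cells.
    """
    positions = np.asarray(positions, dtype=float)
    nodes = [NodeRecord(i, positions[i].copy(), "junctional")
             for i in range(len(positions))]
    edges = []
    for i in range(len(positions) - 1):
        l = rest_lengths[i] if rest_lengths is not None else float(
            np.hypot(*(positions[i + 1] - positions[i])))
        edges.append(EdgeRecord(i, (i, i + 1), JUNCTION, rest_length=l,
                                is_cable=cable))
    loop = list(range(len(positions))) if cable else []
    return TissueMesh(nodes=nodes, edges=edges, cells=[], cable_loop=loop,
                      centre=np.zeros(2), meta={"n_coronae": 0, "edge_length": 1.0})
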