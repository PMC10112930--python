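"""Mesh construction, tagging and serialization against brute-force oracles."""

import numpy as np
import pytest

from placodevm import build_hex_tissue, load_mesh, save_mesh, \
    select_active_elements, tag_regions
from placodevm.errors import MissingTagsError
from placodevm.tissue_geometry import (JUNCTION, SPOKE, cable_triplets,
                                       polygon_area)

# --- independent lattice oracle --------------------------------------------
# Pointy-top hexagon corners live on an integer lattice with steps of
# (sqrt(3)/2 * s, s/2); each cell's six corners are fixed integer offsets
# from its integer centre.  Counting unique corners / corner pairs this way
# never touches the package's construction code.
_CORNER_OFFSETS = [(0, 2), (-1, 1), (-1, -1), (0, -2), (1, -1), (1, 1)]


def _axial_cells(n):
    return [(q, r) for q in range(-n, n + 1)
            for r in range(max(-n, -q - n), min(n, -q + n) + 1)]


def _oracle_counts(n):
    corners = set()
    edges = set()
    for q, r in _axial_cells(n):
        ci = (2 * q + r, 3 * r)
        cell = [(ci[0] + dx, ci[1] + dy) for dx, dy in _CORNER_OFFSETS]
        corners.update(cell)
        for k in range(6):
            edges.add(frozenset((cell[k], cell[(k + 1) % 6])))
    return len(_axial_cells(n)), len(corners), len(edges)


@pytest.mark.parametrize("n", range(9))
def test_lattice_counts_match_bruteforce_enumeration(n):
    n_cells, n_corners, n_jedges = _oracle_counts(n)
    mesh = build_hex_tissue(n)
    assert len(mesh.cells) == n_cells == 3 * n * (n + 1) + 1
    junctional = [nd for nd in mesh.nodes if nd.kind == "junctional"]
    assert len(junctional) == n_corners == 6 * (n + 1) ** 2
    assert sum(e.kind == JUNCTION for e in mesh.edges) == n_jedges
    assert sum(e.kind == SPOKE for e in mesh.edges) == 6 * n_cells


def test_default_tissue_is_127_cells_with_294_nodes_420_edges():
    mesh = build_hex_tissue(6)
    assert len(mesh.cells) == 127
    assert sum(nd.kind == "junctional" for nd in mesh.nodes) == 294
    assert sum(e.kind == JUNCTION for e in mesh.edges) == 420


def test_single_hexagon_counts():
    mesh = build_hex_tissue(0)
    assert len(mesh.cells) == 1
    assert sum(nd.kind == "junctional" for nd in mesh.nodes) == 6
    assert sum(nd.kind == "cell-centre" for nd in mesh.nodes) == 1
    assert len(mesh.edges) == 12


def test_geometry_is_regular_and_at_rest():
    mesh = build_hex_tissue(2, edge_length=2.5)
    for e in mesh.edges:
        assert e.rest_length == 2.5
        assert mesh.edge_length(e) == pytest.approx(2.5, abs=1e-12)
    assert np.allclose(np.mean(mesh.positions, axis=0), 0.0, atol=1e-12)


def test_cell_polygons_are_counterclockwise():
    mesh = build_hex_tissue(2)
    for cell in mesh.cells:
        assert polygon_area(mesh.cell_polygon(cell)) > 0


@pytest.mark.parametrize("bad", [-1, 2.5])
def test_invalid_coronae_rejected(bad):
    with pytest.raises(ValueError):
        build_hex_tissue(bad)


def test_nonpositive_edge_length_rejected():
    with pytest.raises(ValueError):
        build_hex_tissue(2, edge_length=0.0)


# --- tagging ----------------------------------------------------------------

def test_default_tagging_splits_61_interior_66_exterior(default_mesh):
    assert sum(c.region in ("interior", "core") for c in default_mesh.cells) == 61
    assert sum(c.region == "exterior" for c in default_mesh.cells) == 66


def test_exactly_two_complete_coronae_outside_the_cable(default_mesh):
    exterior_coronae = sorted({c.corona_index for c in default_mesh.cells
                               if c.region == "exterior"})
    assert exterior_coronae == [5, 6]
    for c in default_mesh.cells:  # complete coronae: no mixed corona
        assert (c.region == "exterior") == (c.corona_index >= 5)


def test_cable_loop_is_closed_with_degree_two_nodes(default_mesh):
    loop = default_mesh.cable_loop
    cable = default_mesh.cable_edges()
    assert len(loop) == len(cable) == 54
    degree = {}
    for e in cable:
        for nid in e.endpoints:
            degree[nid] = degree.get(nid, 0) + 1
    assert set(degree) == set(loop)
    assert all(d == 2 for d in degree.values())
    pairs = {frozenset(e.endpoints) for e in cable}
    for i in range(len(loop)):
        assert frozenset((loop[i], loop[(i + 1) % len(loop)])) in pairs


def test_cable_loop_total_turning_is_plus_360_degrees(default_mesh):
    pos = default_mesh.positions
    loop = default_mesh.cable_loop
    turning = 0.0
    for i in range(len(loop)):
        a = pos[loop[i - 1]]
        b = pos[loop[i]]
        c = pos[loop[(i + 1) % len(loop)]]
        u, v = b - a, c - b
        turning += np.arctan2(u[0] * v[1] - u[1] * v[0], u @ v)
    assert turning == pytest.approx(2 * np.pi, abs=1e-9)


def test_node_tags_follow_sides(default_mesh):
    for nid in default_mesh.cable_loop:
        assert default_mesh.nodes[nid].region_tag == "cable"
    centre_cell = default_mesh.cells[0]
    assert centre_cell.corona_index == 0
    assert default_mesh.nodes[centre_cell.centre_node].region_tag in (
        "interior", "core")


def test_every_junction_edge_has_one_or_two_cells_and_rim_is_boundary():
    mesh = build_hex_tissue(6)
    edge_cells = mesh.junction_edge_cells()
    counts = [len(v) for v in edge_cells.values()]
    assert set(counts) <= {1, 2}
    # rim edges: 6*(2n+1) for n coronae
    assert counts.count(1) == 6 * 13


def test_cable_placement_must_leave_an_exterior_corona():
    mesh = build_hex_tissue(3)
    with pytest.raises(ValueError):
        tag_regions(mesh, cable_after_corona=3)


def test_tagging_is_translation_invariant():
    a = build_hex_tissue(3)
    b = a.copy()
    b.set_positions(b.positions + np.array([13.7, -4.2]))
    ta = tag_regions(a, 1)
    tb = tag_regions(b, 1)
    assert ta.cable_loop == tb.cable_loop
    assert [c.region for c in ta.cells] == [c.region for c in tb.cells]
    assert [n.region_tag for n in ta.nodes] == [n.region_tag for n in tb.nodes]
    for ea, eb in zip(ta.edges, tb.edges):
        assert (ea.is_cable, ea.rest_length) == (eb.is_cable, eb.rest_length)
        assert ta.edge_length(ea) == pytest.approx(tb.edge_length(eb), abs=1e-9)


# --- active core -------------------------------------------------------------

def test_default_active_core_is_seven_cells_72_edges(default_mesh):
    assert sum(c.region == "core" for c in default_mesh.cells) == 7
    active = [e for e in default_mesh.edges if e.is_active]
    assert len(active) == 72
    assert sum(e.kind == JUNCTION for e in active) == 30
    assert sum(e.kind == SPOKE for e in active) == 42


def test_single_cell_core():
    mesh = tag_regions(build_hex_tissue(3), 1)
    mesh = select_active_elements(mesh, core_coronae=0)
    assert sum(c.region == "core" for c in mesh.cells) == 1
    assert sum(e.is_active for e in mesh.edges) == 12


def test_extra_edges_are_flagged_and_validated():
    mesh = tag_regions(build_hex_tissue(3), 1)
    eid = next(e.id for e in mesh.edges if not e.is_cable)
    out = select_active_elements(mesh, core_coronae=0, extra_edges=[eid])
    assert out.edges[eid].is_active
    with pytest.raises(ValueError):
        select_active_elements(mesh, core_coronae=0, extra_edges=[10 ** 6])


def test_active_selection_requires_tags_and_valid_range():
    untagged = build_hex_tissue(3)
    with pytest.raises(MissingTagsError):
        select_active_elements(untagged, 0)
    tagged = tag_regions(untagged, 1)
    with pytest.raises(ValueError):
        select_active_elements(tagged, core_coronae=2)


# --- serialization -----------------------------------------------------------

def test_mesh_serialization_roundtrip_is_bit_exact(tmp_path, default_mesh):
    path = tmp_path / "mesh.json"
    save_mesh(default_mesh, path)
    back = load_mesh(path)
    assert np.array_equal(back.positions, default_mesh.positions)
    assert back.cable_loop == default_mesh.cable_loop
    assert back.meta == default_mesh.meta
    for e0, e1 in zip(default_mesh.edges, back.edges):
        assert (e0.endpoints, e0.kind, e0.rest_length, e0.modulus,
                e0.is_cable, e0.is_active) == \
               (e1.endpoints, e1.kind, e1.rest_length, e1.modulus,
                e1.is_cable, e1.is_active)
    for c0, c1 in zip(default_mesh.cells, back.cells):
        assert (c0.corona_index, c0.centre_node, c0.boundary_nodes,
                c0.region) == (c1.corona_index, c1.centre_node,
                               c1.boundary_nodes, c1.region)


def test_cable_triplets_closed_vs_open(default_mesh):
    from conftest import make_chain_mesh

    tp, tc, tn = cable_triplets(default_mesh)
    assert len(tc) == len(default_mesh.cable_loop)  # closed loop: all nodes
    chain = make_chain_mesh([(0, 0), (1, 0), (2, 0), (3, 0)])
    tp, tc, tn = cable_triplets(chain)
    assert list(tc) == [1, 2]  # open chain: interior nodes only
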