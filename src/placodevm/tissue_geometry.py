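"""Hexagonal tissue mesh: construction, region/cable tagging, serialization.

The tissue is a patch of regular hexagonal cells on a triangular lattice,
built corona by corona around a central cell (corona 0).  Each cell carries
six junctional corner nodes plus one central node joined to the corners by
radial "spoke" edges, so that a single cell resists both shear and area
changes through ordinary springs.  A closed loop of junction edges can be
tagged as the supracellular actomyosin cable; cells and nodes are then
labelled by which side of that loop they sit on, and a central group of
cells can be flagged as the actively constricting invagination pit.

Lengths are expressed in model units: one unit equals the initial
junctional edge rest length.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import MissingTagsError

SCHEMA_VERSION = 1

#: node kinds
JUNCTIONAL = "junctional"
CELL_CENTRE = "cell-centre"

#: edge kinds
JUNCTION = "junction"
SPOKE = "spoke"


@dataclass
class NodeRecord:
    """A point mass of the vertex model.

    ``region_tag`` is one of ``interior``/``exterior``/``cable`` once
    :func:`tag_regions` has run, ``None`` on a freshly built mesh.
    """

    id: int
    position: np.ndarray
    kind: str
    region_tag: str | None = None

    def copy(self) -> "NodeRecord":
        return NodeRecord(self.id, np.array(self.position, dtype=float),
                          self.kind, self.region_tag)


@dataclass
class EdgeRecord:
    """A linear spring between two nodes.

    ``modulus`` is the per-edge base spring constant (1 for every edge at
    construction); the mechanics layer multiplies it by the cable or
    default modulus from the parameter set.
    """

    id: int
    endpoints: tuple[int, int]
    kind: str
    rest_length: float
    modulus: float = 1.0
    is_cable: bool = False
    is_active: bool = False

    def copy(self) -> "EdgeRecord":
        return EdgeRecord(self.id, tuple(self.endpoints), self.kind,
                          self.rest_length, self.modulus, self.is_cable,
                          self.is_active)


@dataclass
class CellRecord:
    """A polygonal cell: central node plus cyclically ordered corners (CCW)."""

    id: int
    corona_index: int
    centre_node: int
    boundary_nodes: list[int]
    region: str | None = None

    def copy(self) -> "CellRecord":
        return CellRecord(self.id, self.corona_index, self.centre_node,
                          list(self.boundary_nodes), self.region)


@dataclass
class TissueMesh:
    """The full simulation substrate.

    ``cable_loop`` lists the cable's junctional nodes in counter-clockwise
    cyclic order (empty until :func:`tag_regions`).  ``meta`` records the
    construction parameters and, after calibration, a per-round log.
    """

    nodes: list[NodeRecord]
    edges: list[EdgeRecord]
    cells: list[CellRecord]
    cable_loop: list[int] = field(default_factory=list)
    centre: np.ndarray = field(default_factory=lambda: np.zeros(2))
    meta: dict = field(default_factory=dict)

    # -- convenience ------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def positions(self) -> np.ndarray:
        """(N, 2) array of node positions, indexed by node id."""
        pos = np.empty((len(self.nodes), 2), dtype=float)
        for n in self.nodes:
            pos[n.id] = n.position
        return pos

    def set_positions(self, positions: np.ndarray) -> None:
        positions = np.asarray(positions, dtype=float)
        if positions.shape != (len(self.nodes), 2):
            raise ValueError("positions must have shape (n_nodes, 2)")
        for n in self.nodes:
            n.position = positions[n.id].copy()

    def copy(self) -> "TissueMesh":
        return TissueMesh(
            nodes=[n.copy() for n in self.nodes],
            edges=[e.copy() for e in self.edges],
            cells=[c.copy() for c in self.cells],
            cable_loop=list(self.cable_loop),
            centre=np.array(self.centre, dtype=float),
            meta=json.loads(json.dumps(self.meta)),
        )

    def edge_length(self, edge: EdgeRecord) -> float:
        a, b = edge.endpoints
        return float(np.hypot(*(self.nodes[b].position - self.nodes[a].position)))

    def cable_edges(self) -> list[EdgeRecord]:
        return [e for e in self.edges if e.is_cable]

    def cable_circumference(self) -> float:
        return sum(self.edge_length(e) for e in self.cable_edges())

    def cell_polygon(self, cell: CellRecord) -> np.ndarray:
        return np.array([self.nodes[i].position for i in cell.boundary_nodes])

    def cell_area(self, cell: CellRecord) -> float:
        return polygon_area(self.cell_polygon(cell))

    def junction_edge_cells(self) -> dict[int, list[int]]:
        """Map junction-edge id -> ids of the 1 or 2 cells sharing it."""
        pair_to_edge = {}
        for e in self.edges:
            if e.kind == JUNCTION:
                pair_to_edge[frozenset(e.endpoints)] = e.id
        out: dict[int, list[int]] = {eid: [] for eid in pair_to_edge.values()}
        for c in self.cells:
            bn = c.boundary_nodes
            for k in range(len(bn)):
                eid = pair_to_edge[frozenset((bn[k], bn[(k + 1) % len(bn)]))]
                out[eid].append(c.id)
        return out


def polygon_area(points: np.ndarray) -> float:
    """Signed (shoelace) area of a polygon given as an (n, 2) array."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_hex_tissue(n_coronae: int, edge_length: float = 1.0) -> TissueMesh:
    """Build a hexagonal patch of 3*n*(n+1)+1 regular hexagonal cells.

    Cells sit on a triangular lattice (pointy-top hexagons), centred on the
    origin, with corona index 0 for the central cell.  Every edge is built
    at its rest length (junction edges and spokes both have rest length
    ``edge_length``), so the fresh mesh is a zero-force, zero-energy
    configuration of the passive springs.
    """
    if int(n_coronae) != n_coronae or n_coronae < 0:
        raise ValueError(f"n_coronae must be a non-negative integer, got {n_coronae}")
    n = int(n_coronae)
    s = float(edge_length)
    if not s > 0:
        raise ValueError(f"edge_length must be positive, got {edge_length}")

    sqrt3 = math.sqrt(3.0)
    # lattice basis for pointy-top hexagons (centre spacing sqrt(3)*s)
    a1 = (sqrt3 * s, 0.0)
    a2 = (sqrt3 * s / 2.0, 1.5 * s)

    def corona_of(q: int, r: int) -> int:
        return (abs(q) + abs(r) + abs(q + r)) // 2

    coords = [(q, r)
              for q in range(-n, n + 1)
              for r in range(max(-n, -q - n), min(n, -q + n) + 1)]
    coords.sort(key=lambda qr: (corona_of(*qr), qr))

    nodes: list[NodeRecord] = []
    edges: list[EdgeRecord] = []
    cells: list[CellRecord] = []
    vertex_ids: dict[tuple[float, float], int] = {}
    edge_ids: dict[frozenset, int] = {}

    def new_node(x: float, y: float, kind: str) -> int:
        nid = len(nodes)
        nodes.append(NodeRecord(nid, np.array([x, y], dtype=float), kind))
        return nid

    def junction_node(x: float, y: float) -> int:
        key = (round(x / s, 6), round(y / s, 6))
        nid = vertex_ids.get(key)
        if nid is None:
            nid = new_node(x, y, JUNCTIONAL)
            vertex_ids[key] = nid
        return nid

    def add_edge(a: int, b: int, kind: str) -> int:
        key = frozenset((a, b))
        eid = edge_ids.get(key)
        if eid is None:
            eid = len(edges)
            edges.append(EdgeRecord(eid, (a, b), kind, rest_length=s))
            edge_ids[key] = eid
        return eid

    for cell_id, (q, r) in enumerate(coords):
        cx = q * a1[0] + r * a2[0]
        cy = q * a1[1] + r * a2[1]
        corners = []
        for k in range(6):
            ang = math.pi / 2.0 + k * math.pi / 3.0  # CCW from the top corner
            corners.append(junction_node(cx + s * math.cos(ang),
                                         cy + s * math.sin(ang)))
        centre_id = new_node(cx, cy, CELL_CENTRE)
        for k in range(6):
            add_edge(corners[k], corners[(k + 1) % 6], JUNCTION)
            add_edge(centre_id, corners[k], SPOKE)
        cells.append(CellRecord(cell_id, corona_of(q, r), centre_id, corners))

    return TissueMesh(
        nodes=nodes, edges=edges, cells=cells,
        cable_loop=[], centre=np.zeros(2),
        meta={"n_coronae": n, "edge_length": s,
              "cable_after_corona": None, "core_coronae": None},
    )


# ---------------------------------------------------------------------------
# tagging
# ---------------------------------------------------------------------------

def tag_regions(mesh: TissueMesh, cable_after_corona: int = 4) -> TissueMesh:
    """Tag the cable loop and the interior/exterior compartments.

    The cable is the closed interface between the cells of corona index
    ``<= cable_after_corona`` and the rest of the tissue.  With the default
    tissue (6 coronae) and the default placement after corona 4, exactly
    two complete coronae of cells lie outside the cable, standing in for
    the epidermis that surrounds the placode.  Returns a new mesh; the
    input is not modified.
    """
    c = int(cable_after_corona)
    if c != cable_after_corona or c < 0:
        raise ValueError("cable_after_corona must be a non-negative integer")
    n = mesh.meta.get("n_coronae")
    if n is None:
        raise MissingTagsError("mesh lacks construction metadata")
    if c >= n:
        raise ValueError(
            f"cable_after_corona={c} leaves no exterior corona (tissue has "
            f"coronae 0..{n})")

    m = mesh.copy()
    edge_cells = m.junction_edge_cells()
    corona = {cell.id: cell.corona_index for cell in m.cells}

    for e in m.edges:
        e.is_cable = False
        if e.kind != JUNCTION:
            continue
        cs = [corona[cid] for cid in edge_cells[e.id]]
        if len(cs) == 2 and min(cs) <= c < max(cs):
            e.is_cable = True

    # walk the cable into a single cyclic node list
    adjacency: dict[int, list[int]] = {}
    for e in m.edges:
        if e.is_cable:
            a, b = e.endpoints
            adjacency.setdefault(a, []).append(b)
            adjacency.setdefault(b, []).append(a)
    for nid, nbrs in adjacency.items():
        if len(nbrs) != 2:
            raise MissingTagsError(
                f"cable node {nid} has {len(nbrs)} incident cable edges")
    start = min(adjacency)
    loop = [start, min(adjacency[start])]
    while True:
        a, b = adjacency[loop[-1]]
        nxt = a if a != loop[-2] else b
        if nxt == start:
            break
        loop.append(nxt)
    if len(loop) != len(adjacency):
        raise MissingTagsError("cable edges do not form a single closed loop")
    loop_pts = np.array([m.nodes[i].position for i in loop])
    if polygon_area(loop_pts) < 0:  # orient counter-clockwise
        loop = [loop[0]] + loop[:0:-1]
    m.cable_loop = loop

    for cell in m.cells:
        cell.region = "interior" if cell.corona_index <= c else "exterior"

    node_cells: dict[int, list[int]] = {}
    for cell in m.cells:
        for nid in cell.boundary_nodes:
            node_cells.setdefault(nid, []).append(cell.id)
    cable_set = set(loop)
    cell_by_id = {cell.id: cell for cell in m.cells}
    for node in m.nodes:
        if node.kind == CELL_CENTRE:
            continue
        if node.id in cable_set:
            node.region_tag = "cable"
        else:
            node.region_tag = cell_by_id[node_cells[node.id][0]].region
    for cell in m.cells:
        m.nodes[cell.centre_node].region_tag = cell.region

    m.meta["cable_after_corona"] = c
    return m


def select_active_elements(mesh: TissueMesh, core_coronae: int = 1,
                           extra_edges: list[int] | tuple[int, ...] = ()) -> TissueMesh:
    """Flag the actively constricting pit: core cells plus optional edges.

    Cells with corona index ``<= core_coronae`` (default: the central cell
    and its first corona, i.e. seven cells) become the ``core``; all their
    junction edges and spokes are marked active so that a constant
    contractile tension can later be applied to them.  ``extra_edges``
    lets callers add further edge ids, mirroring the handful of extra
    constricting junctions seen next to the pit in vivo.  Returns a new
    mesh.
    """
    cc = int(core_coronae)
    if cc != core_coronae or cc < 0:
        raise ValueError("core_coronae must be a non-negative integer")
    cable_c = mesh.meta.get("cable_after_corona")
    if cable_c is None:
        raise MissingTagsError("tag_regions must run before selecting the active core")
    if cc > cable_c:
        raise ValueError(
            f"core_coronae={cc} exceeds the cable placement (after corona {cable_c})")
    m = mesh.copy()
    valid_ids = {e.id for e in m.edges}
    for eid in extra_edges:
        if eid not in valid_ids:
            raise ValueError(f"extra edge id {eid} not in mesh")

    pair_to_edge = {frozenset(e.endpoints): e for e in m.edges}
    for cell in m.cells:
        if cell.corona_index <= cc:
            cell.region = "core"
            bn = cell.boundary_nodes
            for k in range(6):
                pair_to_edge[frozenset((bn[k], bn[(k + 1) % 6]))].is_active = True
                pair_to_edge[frozenset((cell.centre_node, bn[k]))].is_active = True
    for eid in extra_edges:
        m.edges[eid].is_active = True
    m.meta["core_coronae"] = cc
    return m


def cable_triplets(mesh: TissueMesh) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(prev, node, next) node-id arrays for every bending site on the cable.

    For a closed loop every cable node is a bending site; for an open
    chain (no cable edge joins the two ends) only interior nodes are.
    """
    loop = mesh.cable_loop
    if len(loop) < 3:
        return (np.empty(0, dtype=np.int64),) * 3
    cable_pairs = {frozenset(e.endpoints) for e in mesh.edges if e.is_cable}
    closed = frozenset((loop[-1], loop[0])) in cable_pairs
    idx = range(len(loop)) if closed else range(1, len(loop) - 1)
    prev = np.array([loop[i - 1] for i in idx], dtype=np.int64)
    node = np.array([loop[i] for i in idx], dtype=np.int64)
    nxt = np.array([loop[(i + 1) % len(loop)] for i in idx], dtype=np.int64)
    return prev, node, nxt


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def mesh_to_dict(mesh: TissueMesh) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "meta": mesh.meta,
        "centre": [float(mesh.centre[0]), float(mesh.centre[1])],
        "nodes": [{"id": n.id, "position": [float(n.position[0]), float(n.position[1])],
                   "kind": n.kind, "region_tag": n.region_tag} for n in mesh.nodes],
        "edges": [{"id": e.id, "endpoints": list(e.endpoints), "kind": e.kind,
                   "rest_length": e.rest_length, "modulus": e.modulus,
                   "is_cable": e.is_cable, "is_active": e.is_active}
                  for e in mesh.edges],
        "cells": [{"id": c.id, "corona_index": c.corona_index,
                   "centre_node": c.centre_node,
                   "boundary_nodes": list(c.boundary_nodes), "region": c.region}
                  for c in mesh.cells],
        "cable_loop": list(mesh.cable_loop),
    }


def mesh_from_dict(doc: dict) -> TissueMesh:
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValueError(f"unsupported mesh schema version {doc.get('schema_version')}")
    nodes = [NodeRecord(d["id"], np.array(d["position"], dtype=float),
                        d["kind"], d["region_tag"]) for d in doc["nodes"]]
    edges = [EdgeRecord(d["id"], tuple(d["endpoints"]), d["kind"], d["rest_length"],
                        d["modulus"], d["is_cable"], d["is_active"])
             for d in doc["edges"]]
    cells = [CellRecord(d["id"], d["corona_index"], d["centre_node"],
                        list(d["boundary_nodes"]), d["region"]) for d in doc["cells"]]
    return TissueMesh(nodes=nodes, edges=edges, cells=cells,
                      cable_loop=list(doc["cable_loop"]),
                      centre=np.array(doc["centre"], dtype=float),
                      meta=dict(doc["meta"]))


def save_mesh(mesh: TissueMesh, path: str | Path) -> None:
    Path(path).write_text(json.dumps(mesh_to_dict(mesh)))


def load_mesh(path: str | Path) -> TissueMesh:
    return mesh_from_dict(json.loads(Path(path).read_text()))
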