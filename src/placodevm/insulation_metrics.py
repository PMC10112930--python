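"""Radial-movement readout and the barrier-normalised insulation index.

The model's output is the average radial movement of nodes toward the
tissue centre between the calibrated ground state and the contracted
state.  Nodes are stratified by which side of the cable loop they occupy;
the movement of the outside nodes under a given barrier, divided by the
same quantity with no barrier at all, quantifies how much mechanical
influence leaks across the cable ("normalised movement"), and
``decrease = 1 - normalised movement`` is the insulation readout.
"""

from __future__ import annotations

import numpy as np
import shapely

from .equilibration import SimulationResult
from .errors import MissingTagsError, UndefinedNormalizationError
from .tissue_geometry import CELL_CENTRE, JUNCTION, TissueMesh

#: CSV column order of the sweep summary
SUMMARY_COLUMNS = ["k_bend", "mu_cable", "mean_radial_outside",
                   "mean_radial_inside", "n_outside", "n_inside",
                   "normalized_movement", "decrease"]


def classify_nodes(mesh: TissueMesh) -> np.ndarray:
    """Per-node side label: ``inside``, ``outside`` or ``cable``.

    Junctional non-cable nodes are classified by point-in-polygon
    containment against the cable loop; cell-centre nodes inherit their
    cell's side.
    """
    if not mesh.cable_loop:
        raise MissingTagsError("mesh has no tagged cable loop")
    pos = mesh.positions
    poly = shapely.Polygon(pos[mesh.cable_loop])
    labels = np.empty(len(mesh.nodes), dtype=object)
    cable = set(mesh.cable_loop)
    junctional = [n.id for n in mesh.nodes
                  if n.kind != CELL_CENTRE and n.id not in cable]
    inside = shapely.contains_xy(poly, pos[junctional, 0], pos[junctional, 1])
    for nid, is_in in zip(junctional, inside):
        labels[nid] = "inside" if is_in else "outside"
    for nid in cable:
        labels[nid] = "cable"
    for cell in mesh.cells:
        labels[cell.centre_node] = (
            "outside" if cell.region == "exterior" else "inside")
    return labels


def rim_node_ids(mesh: TissueMesh) -> set[int]:
    """Junctional nodes on the outer tissue rim (edges with one incident cell)."""
    edge_cells = mesh.junction_edge_cells()
    rim: set[int] = set()
    for e in mesh.edges:
        if e.kind == JUNCTION and len(edge_cells[e.id]) == 1:
            rim.update(e.endpoints)
    return rim


def core_node_ids(mesh: TissueMesh) -> set[int]:
    """Junctional nodes belonging to actively constricting (core) cells."""
    out: set[int] = set()
    for cell in mesh.cells:
        if cell.region == "core":
            out.update(cell.boundary_nodes)
    return out


def side_node_ids(mesh: TissueMesh, side: str, exclude_core: bool = False,
                  outermost_only: bool = False) -> list[int]:
    """Junctional node ids on one side of the cable.

    ``exclude_core`` drops nodes of actively constricting cells (their
    motion reflects the constriction itself, mirroring the in-vivo
    exclusion rule); ``outermost_only`` restricts the outside set to the
    tissue rim.
    """
    labels = classify_nodes(mesh)
    centre_ids = {n.id for n in mesh.nodes if n.kind == CELL_CENTRE}
    ids = [n.id for n in mesh.nodes
           if labels[n.id] == side and n.id not in centre_ids]
    if exclude_core:
        core = core_node_ids(mesh)
        ids = [i for i in ids if i not in core]
    if outermost_only:
        rim = rim_node_ids(mesh)
        ids = [i for i in ids if i in rim]
    return ids


def radial_displacement(result: SimulationResult, node_ids,
                        centre: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node inward radial movement and its mean.

    ``dr = |x(0) - centre| - |x(final) - centre|``; positive values mean
    the node moved toward the centre.
    """
    ids = np.asarray(list(node_ids), dtype=int)
    if ids.size == 0:
        raise ValueError("node_ids must be non-empty")
    c = np.asarray(centre, dtype=float)
    r0 = np.hypot(*(result.initial_positions[ids] - c).T)
    r1 = np.hypot(*(result.final_positions[ids] - c).T)
    dr = r0 - r1
    return dr, float(dr.mean())


def insulation_index(barrier_result: SimulationResult,
                     baseline_result: SimulationResult,
                     mesh: TissueMesh,
                     outermost_only: bool = False,
                     eps: float = 1e-9) -> dict:
    """Outside-node movement of a barrier run relative to the no-barrier run.

    Both results must come from the same mesh topology under the same
    active forcing; the baseline is the run with ``mu_cable = mu_default``
    and ``k_bend = 0``.
    """
    outside = side_node_ids(mesh, "outside", outermost_only=outermost_only)
    _, barrier_mean = radial_displacement(barrier_result, outside, mesh.centre)
    _, baseline_mean = radial_displacement(baseline_result, outside, mesh.centre)
    if abs(baseline_mean) <= eps:
        raise UndefinedNormalizationError(
            f"baseline outside movement {baseline_mean:.3g} is too small to "
            "normalise by")
    ratio = barrier_mean / baseline_mean
    return {"normalized_movement": ratio, "decrease": 1.0 - ratio}
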