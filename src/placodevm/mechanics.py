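"""Forces and energy of the vertex model.

Three ingredients act on the nodes:

* **passive springs** on every edge, with linear (Hookean) restoring force
  of magnitude ``modulus * |l - l0|`` along the edge.  Cable edges use the
  elevated modulus ``mu_cable``, all other edges ``mu_default``;
* **bending** at consecutive cable segments: the energy ``(k/2)(theta-pi)^2``
  penalises deviation of the inter-edge angle from straight, giving the
  restoring force magnitude ``k*(theta - pi)`` that aligns adjacent cable
  edges.  Forces are the exact gradient, so the three participating nodes
  conserve linear and angular momentum;
* **active contraction**: a constant tension ``f_active`` pulling the two
  endpoints of each flagged edge together, the model of junctional
  actomyosin constriction at the pit.

``total_energy`` is the scalar whose negative gradient is ``total_force``;
it is used for diagnostics (gradient-flow trajectories must not increase
it) and for cross-checking the analytic forces against finite differences.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateGeometryError
from .tissue_geometry import EdgeRecord, TissueMesh, cable_triplets

_TINY = 1e-12


@dataclass(frozen=True)
class MechanicsParams:
    """Physical constants of the model (model units throughout).

    mu_default : spring constant of ordinary edges.
    mu_cable   : spring constant of cable edges (the swept stiffness mu).
    k_bend     : bending coefficient k on consecutive cable edges.
    f_active   : contractile tension on edges flagged active.
    eta        : viscous friction factor of the over-damped dynamics.
    """

    mu_default: float = 1.0
    mu_cable: float = 1.0
    k_bend: float = 0.0
    f_active: float = 0.0
    eta: float = 1.0
    #: regularisation of the discrete bending penalty: each angle term is
    #: weighted by smoothstep(l / bend_cutoff) of its two segment lengths,
    #: so the penalty (and its 1/l force divergence) fades out when a cable
    #: segment collapses -- a merged corner is no longer a penalised angle.
    #: Geometry with all segments longer than the cutoff is unaffected.
    bend_cutoff: float = 0.02

    def __post_init__(self):
        if not (self.mu_default > 0 and self.mu_cable > 0 and self.eta > 0):
            raise ValueError("mu_default, mu_cable and eta must be positive")
        if self.k_bend < 0 or self.f_active < 0 or self.bend_cutoff < 0:
            raise ValueError("k_bend, f_active and bend_cutoff must be "
                             "non-negative")

    def with_(self, **kw) -> "MechanicsParams":
        return replace(self, **kw)

    @classmethod
    def from_dict(cls, d: dict) -> "MechanicsParams":
        return cls(**{k: float(v) for k, v in d.items()})


# ---------------------------------------------------------------------------
# single-element forces (reference implementations, used by tests and docs)
# ---------------------------------------------------------------------------

def spring_force(edge: EdgeRecord, positions: np.ndarray
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Hookean force pair on the two endpoints of one edge."""
    a, b = edge.endpoints
    d = positions[b] - positions[a]
    l = float(np.hypot(*d))
    if l < _TINY:
        raise DegenerateGeometryError(f"edge {edge.id} has zero length")
    f_a = edge.modulus * (l - edge.rest_length) / l * d
    return f_a, -f_a


def bending_force(prev: np.ndarray, node: np.ndarray, nxt: np.ndarray,
                  k_bend: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Exact-gradient bending forces on a (prev, node, next) cable triplet.

    The interior angle theta at ``node`` lives in (0, 2*pi); the energy is
    ``(k/2)(theta - pi)^2``.  The returned forces sum to zero and exert no
    net torque.
    """
    u = np.asarray(prev, dtype=float) - np.asarray(node, dtype=float)
    v = np.asarray(nxt, dtype=float) - np.asarray(node, dtype=float)
    lu2 = float(u @ u)
    lv2 = float(v @ v)
    if lu2 < _TINY**2 or lv2 < _TINY**2:
        raise DegenerateGeometryError("zero-length cable segment at bending site")
    theta = _interior_angle(u, v)
    g = k_bend * (theta - np.pi)
    # d(theta)/d(prev) = -perp(u)/|u|^2, d(theta)/d(next) = perp(v)/|v|^2
    f_prev = g * np.array([-u[1], u[0]]) / lu2
    f_next = -g * np.array([-v[1], v[0]]) / lv2
    return f_prev, -(f_prev + f_next), f_next


def _interior_angle(u: np.ndarray, v: np.ndarray) -> float:
    phi = float(np.arctan2(u[0] * v[1] - u[1] * v[0], u @ v))
    return phi if phi >= 0 else phi + 2 * np.pi


def active_force(edge: EdgeRecord, positions: np.ndarray, f_active: float
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Constant-tension force pair pulling the endpoints together."""
    a, b = edge.endpoints
    d = positions[b] - positions[a]
    l = float(np.hypot(*d))
    if l < _TINY:
        raise DegenerateGeometryError(f"edge {edge.id} has zero length")
    f_a = f_active / l * d
    return f_a, -f_a


# ---------------------------------------------------------------------------
# whole-mesh assembly
# ---------------------------------------------------------------------------

def assemble_arrays(mesh: TissueMesh, params: MechanicsParams,
                    with_active: bool = True) -> dict:
    """Flatten mesh + parameters into the arrays the solvers operate on."""
    ei = np.array([e.endpoints[0] for e in mesh.edges], dtype=np.int64)
    ej = np.array([e.endpoints[1] for e in mesh.edges], dtype=np.int64)
    rest = np.array([e.rest_length for e in mesh.edges], dtype=float)
    mod = np.array([e.modulus * (params.mu_cable if e.is_cable else params.mu_default)
                    for e in mesh.edges], dtype=float)
    tension = np.array(
        [params.f_active if (with_active and e.is_active) else 0.0
         for e in mesh.edges], dtype=float)
    tp, tc, tn = cable_triplets(mesh)
    return {"ei": ei, "ej": ej, "rest": rest, "mod": mod, "tension": tension,
            "trip_prev": tp, "trip_node": tc, "trip_next": tn,
            "k_bend": float(params.k_bend),
            "l_reg": float(params.bend_cutoff)}


def total_force(mesh: TissueMesh, params: MechanicsParams,
                positions: np.ndarray | None = None,
                with_active: bool = True) -> np.ndarray:
    """Total force field (N, 2): springs + cable bending + active tension.

    The grand total over all nodes is zero because every constituent force
    pair/triplet is internally balanced.
    """
    pos = mesh.positions if positions is None else np.asarray(positions, dtype=float)
    arr = assemble_arrays(mesh, params, with_active)
    F = np.zeros_like(pos)

    d = pos[arr["ej"]] - pos[arr["ei"]]
    l = np.hypot(d[:, 0], d[:, 1])
    bad = np.flatnonzero(l < _TINY)
    if bad.size:
        raise DegenerateGeometryError(f"edge {int(bad[0])} has zero length")
    coef = (arr["mod"] * (l - arr["rest"]) + arr["tension"]) / l
    fe = coef[:, None] * d
    np.add.at(F, arr["ei"], fe)
    np.add.at(F, arr["ej"], -fe)

    if arr["k_bend"] > 0 and arr["trip_node"].size:
        u = pos[arr["trip_prev"]] - pos[arr["trip_node"]]
        v = pos[arr["trip_next"]] - pos[arr["trip_node"]]
        lu2 = np.einsum("ij,ij->i", u, u)
        lv2 = np.einsum("ij,ij->i", v, v)
        if (lu2 < _TINY**2).any() or (lv2 < _TINY**2).any():
            raise DegenerateGeometryError("zero-length cable segment at bending site")
        lu = np.sqrt(lu2)
        lv = np.sqrt(lv2)
        wu, dwu = _smoothstep(lu, arr["l_reg"])
        wv, dwv = _smoothstep(lv, arr["l_reg"])
        phi = np.arctan2(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0],
                         np.einsum("ij,ij->i", u, v))
        theta = np.where(phi >= 0, phi, phi + 2 * np.pi)
        dev = theta - np.pi
        g = arr["k_bend"] * dev * wu * wv
        e_site = 0.5 * arr["k_bend"] * dev**2
        f_prev = ((g / lu2)[:, None] * np.stack([-u[:, 1], u[:, 0]], axis=1)
                  - (e_site * dwu * wv / lu)[:, None] * u)
        f_next = ((-g / lv2)[:, None] * np.stack([-v[:, 1], v[:, 0]], axis=1)
                  - (e_site * wu * dwv / lv)[:, None] * v)
        np.add.at(F, arr["trip_prev"], f_prev)
        np.add.at(F, arr["trip_next"], f_next)
        np.add.at(F, arr["trip_node"], -(f_prev + f_next))
    return F


def _smoothstep(l: np.ndarray, l_reg: float):
    """Weight w(l) fading the angle penalty below l_reg, and dw/dl."""
    if l_reg <= 0:
        return np.ones_like(l), np.zeros_like(l)
    t = np.clip(l / l_reg, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t), 6.0 * t * (1.0 - t) / l_reg


def total_energy(mesh: TissueMesh, params: MechanicsParams,
                 positions: np.ndarray | None = None,
                 with_active: bool = True) -> float:
    """Scalar energy whose negative gradient is :func:`total_force`.

    ``sum mod/2 (l-l0)^2  +  sum (k/2)(theta-pi)^2  +  sum f_active * l``.
    """
    pos = mesh.positions if positions is None else np.asarray(positions, dtype=float)
    arr = assemble_arrays(mesh, params, with_active)
    d = pos[arr["ej"]] - pos[arr["ei"]]
    l = np.hypot(d[:, 0], d[:, 1])
    if (l < _TINY).any():
        raise DegenerateGeometryError("zero-length edge")
    e = float(np.sum(0.5 * arr["mod"] * (l - arr["rest"]) ** 2)
              + np.sum(arr["tension"] * l))
    if arr["k_bend"] > 0 and arr["trip_node"].size:
        u = pos[arr["trip_prev"]] - pos[arr["trip_node"]]
        v = pos[arr["trip_next"]] - pos[arr["trip_node"]]
        wu, _ = _smoothstep(np.hypot(u[:, 0], u[:, 1]), arr["l_reg"])
        wv, _ = _smoothstep(np.hypot(v[:, 0], v[:, 1]), arr["l_reg"])
        phi = np.arctan2(u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0],
                         np.einsum("ij,ij->i", u, v))
        theta = np.where(phi >= 0, phi, phi + 2 * np.pi)
        e += float(np.sum(0.5 * arr["k_bend"] * (theta - np.pi) ** 2 * wu * wv))
    return e
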