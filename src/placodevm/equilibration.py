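"""Over-damped relaxation and iterative ground-state calibration.

Nodal motion follows the first-order gradient flow ``eta * dx_i/dt = F_i``,
integrated by explicit Euler with a fixed step.  A configuration counts as
relaxed when the largest per-node force magnitude drops below
``force_tol``.

Because the bending penalty pulls the initially zig-zag cable toward a
circle, a tissue with ``k_bend > 0`` is *not* force-free as built.  The
ground-state calibration relaxes the passive tissue, adopts each cable
edge's equilibrium length as its new rest length, and repeats until the
rest lengths stop changing.  This removes all stored spring energy from
the cable itself at equilibrium, giving a consistent reference state from
which active contraction is launched for any (mu, k) pair.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from . import _kernels
from .errors import DivergenceError, MissingTagsError, NonConvergenceError
from .mechanics import MechanicsParams, assemble_arrays
from .tissue_geometry import TissueMesh


@dataclass(frozen=True)
class SolverControls:
    """Integration and convergence controls (model time/force units).

    ``dt`` must respect the explicit-Euler stability bound
    ``dt <= stability_factor * eta / K`` with ``K`` the largest stiffness
    scale among ``mu_default``, ``mu_cable``, ``k_bend`` (and 1).
    """

    dt: float = 1e-3
    t_max: float = 5000.0
    force_tol: float = 1e-8
    calib_tol: float = 1e-6
    max_calib_rounds: int = 5000
    snapshot_every: int = 0  # steps between stored snapshots; 0 = none
    stability_factor: float = 0.1
    #: "euler": over-damped gradient flow (the model's dynamics);
    #: "fire" / "lbfgs": minimisers that find the same equilibria faster
    method: str = "euler"
    #: pin the outer tissue rim (sensitivity check; the default boundary
    #: condition is a free rim)
    pin_rim: bool = False

    def __post_init__(self):
        if not (self.dt > 0 and self.t_max > 0 and self.force_tol > 0
                and self.calib_tol > 0 and self.max_calib_rounds >= 1
                and self.snapshot_every >= 0 and self.stability_factor > 0):
            raise ValueError("invalid solver controls")
        if self.method not in ("euler", "fire", "lbfgs"):
            raise ValueError(f"unknown method {self.method!r}")

    def with_(self, **kw) -> "SolverControls":
        return replace(self, **kw)

    @classmethod
    def for_params(cls, params: MechanicsParams, **kw) -> "SolverControls":
        """Controls with dt set to the stability bound for these parameters."""
        c = kw.get("stability_factor", 0.1)
        kw.setdefault("dt", stable_dt(params, c))
        return cls(**kw)


def stable_dt(params: MechanicsParams, stability_factor: float = 0.1,
              min_cable_length: float = 1.0) -> float:
    """Largest explicit-Euler step allowed by the documented stability rule.

    ``dt <= stability_factor * eta / K`` where K is the largest stiffness
    scale in the system: the spring moduli, and the bending penalty whose
    effective stiffness grows as ``4 * k_bend / l^2`` when cable segments
    of length l shorten (capped at the regularisation cutoff, below which
    the penalty fades out).
    """
    if params.bend_cutoff > 0 and min_cable_length < params.bend_cutoff:
        # a segment is collapsing: the fade-out weight's curvature
        # ~ k * pi^2 / cutoff^2 dominates the local stiffness
        k_eff = 30.0 * params.k_bend / params.bend_cutoff ** 2
    else:
        k_eff = 4.0 * params.k_bend / max(min_cable_length, 1e-6) ** 2
    stiff = max(params.mu_default, params.mu_cable, k_eff, 1.0)
    return stability_factor * params.eta / stiff


def _min_length(arr: dict, pos: np.ndarray) -> float:
    """Shortest current bending segment, setting the bending stiffness scale."""
    tp, tc, tn = arr["trip_prev"], arr["trip_node"], arr["trip_next"]
    if tc.size == 0:
        return 1.0
    lu = np.hypot(*(pos[tp] - pos[tc]).T)
    lv = np.hypot(*(pos[tn] - pos[tc]).T)
    return float(max(min(lu.min(), lv.min()), 1e-6))


@dataclass
class SimulationResult:
    """Outcome of one relaxation run."""

    initial_positions: np.ndarray
    final_positions: np.ndarray
    snapshots: list[tuple[float, np.ndarray]]
    converged: bool
    final_max_force: float
    steps_taken: int
    dt: float

    @property
    def time(self) -> float:
        return self.steps_taken * self.dt


def relax(mesh: TissueMesh, params: MechanicsParams, controls: SolverControls,
          with_active: bool = True) -> SimulationResult:
    """Integrate the over-damped dynamics until equilibrium or ``t_max``.

    The mesh is not mutated.  Active tensions are applied only when
    ``with_active``.  Hitting ``t_max`` without reaching ``force_tol``
    returns a result with ``converged=False``; non-finite positions raise
    :class:`DivergenceError`.

    With ``method="euler"`` the requested ``dt`` is clamped to the
    stability bound computed from the parameters and the current cable
    geometry; the step actually used is reported in the result.  The
    ``"fire"`` and ``"lbfgs"`` methods locate the same equilibria far
    faster (quenched fictitious dynamics and quasi-Newton minimisation
    respectively) but their trajectories are not the over-damped flow.
    """
    arr = assemble_arrays(mesh, params, with_active)
    arr["mobile"] = _mobility_mask(mesh, controls)
    return _relax_arrays(mesh.positions, arr, params, controls)


def _mobility_mask(mesh: TissueMesh, controls: SolverControls) -> np.ndarray:
    mobile = np.ones(len(mesh.nodes), dtype=float)
    if controls.pin_rim:
        edge_cells = mesh.junction_edge_cells()
        for e in mesh.edges:
            if e.kind == "junction" and len(edge_cells[e.id]) == 1:
                mobile[list(e.endpoints)] = 0.0
    return mobile


def _relax_arrays(positions: np.ndarray, arr: dict, params: MechanicsParams,
                  controls: SolverControls) -> SimulationResult:
    pos = np.ascontiguousarray(positions, dtype=float)
    initial = pos.copy()
    if controls.method == "lbfgs":
        return _lbfgs_relax(pos, initial, arr, params, controls)

    snapshots: list[tuple[float, np.ndarray]] = []
    if controls.snapshot_every > 0:
        snapshots.append((0.0, pos.copy()))

    steps_done = 0
    t = 0.0
    dt = controls.dt
    converged = False
    maxf = math.inf
    while t < controls.t_max:
        # the stability bound tightens if cable segments shorten mid-run,
        # so the step is re-derived from the current geometry every chunk
        bound = stable_dt(params, controls.stability_factor,
                          _min_length(arr, pos))
        dt = min(controls.dt, bound)
        if controls.method == "fire":
            # fictitious unit masses: inertial stability scale is 1/sqrt(K)
            k_max = controls.stability_factor * params.eta / bound
            step = 0.1 / math.sqrt(k_max)
        else:
            step = dt
        remaining = max(int(round((controls.t_max - t) / step)), 0)
        budget = min(controls.snapshot_every or 100_000, remaining)
        if budget <= 0:
            break
        args = (pos, arr["ei"], arr["ej"], arr["rest"], arr["mod"],
                arr["tension"], arr["trip_prev"], arr["trip_node"],
                arr["trip_next"], arr["k_bend"], arr["l_reg"], arr["mobile"])
        if controls.method == "fire":
            nsteps, maxf, status = _kernels.fire_relax(
                *args, step, 10.0 * step, controls.force_tol, budget)
        else:
            nsteps, maxf, status = _kernels.euler_relax(
                *args, 1.0 / params.eta, step, controls.force_tol, budget)
        steps_done += nsteps
        t += nsteps * step
        if status == _kernels.DIVERGED:
            raise DivergenceError(
                f"non-finite or degenerate geometry at step {steps_done}")
        if controls.snapshot_every > 0 and nsteps > 0:
            snapshots.append((t, pos.copy()))
        if status == _kernels.CONVERGED:
            converged = maxf <= controls.force_tol
            break
    return SimulationResult(
        initial_positions=initial, final_positions=pos.copy(),
        snapshots=snapshots, converged=converged,
        final_max_force=float(maxf), steps_taken=steps_done, dt=dt)


def _lbfgs_relax(pos: np.ndarray, initial: np.ndarray, arr: dict,
                 params: MechanicsParams,
                 controls: SolverControls) -> SimulationResult:
    """Quasi-Newton equilibrium search with a FIRE polish.

    L-BFGS handles the ill-conditioned landscapes that arise when stiff
    bending shortens cable segments, but its line search bottoms out near
    machine precision of the energy (max residual force ~1e-5 on stiff
    tissues); a short FIRE run then pushes the residual to ``force_tol``.
    """
    from scipy.optimize import minimize

    n = pos.shape[0]
    ka = (arr["ei"], arr["ej"], arr["rest"], arr["mod"], arr["tension"],
          arr["trip_prev"], arr["trip_node"], arr["trip_next"],
          arr["k_bend"], arr["l_reg"], arr["mobile"])
    F = np.zeros_like(pos)

    ke = ka[:-1]  # compute_energy takes no mobility mask

    def fun(x):
        p = x.reshape(n, 2)
        energy = _kernels.compute_energy(p, *ke)
        maxf = _kernels.compute_forces(p, F, *ka)
        if maxf < 0.0 or not np.isfinite(energy):
            raise DivergenceError(
                "degenerate or non-finite configuration during minimisation")
        return energy, -F.ravel()

    x = pos.ravel().copy()
    evals = 0
    maxf = _kernels.compute_forces(pos, F, *ka)
    if maxf < 0.0 or not math.isfinite(maxf):
        raise DivergenceError("degenerate or non-finite starting configuration")
    for _ in range(40):
        if maxf <= controls.force_tol or evals >= 500_000:
            break
        res = minimize(fun, x, jac=True, method="L-BFGS-B",
                       options={"maxiter": 20_000, "maxfun": 50_000,
                                "ftol": 1e-18, "gtol": 1e-14, "maxcor": 30})
        evals += res.nfev
        x = res.x
        maxf = _kernels.compute_forces(x.reshape(n, 2), F, *ka)
        if res.nfev <= 3 and maxf > controls.force_tol:
            break  # line search cannot improve further at this precision
    final = np.ascontiguousarray(x.reshape(n, 2))
    polish = 0
    while maxf > controls.force_tol and polish < 10:
        # FIRE polish, re-deriving the step whenever segments shorten
        bound = stable_dt(params, controls.stability_factor,
                          _min_length(arr, final))
        dt0 = 0.1 / math.sqrt(controls.stability_factor * params.eta / bound)
        nsteps, maxf, status = _kernels.fire_relax(
            final, *ka, dt0, 10.0 * dt0, controls.force_tol, 100_000)
        evals += nsteps
        polish += 1
        if status == _kernels.DIVERGED:
            raise DivergenceError("divergence during FIRE polish")
        if status == _kernels.CONVERGED:
            break
    return SimulationResult(
        initial_positions=initial, final_positions=final, snapshots=[],
        converged=bool(maxf <= controls.force_tol),
        final_max_force=float(maxf), steps_taken=evals, dt=0.0)


def calibrate_ground_state(mesh: TissueMesh, params: MechanicsParams,
                           controls: SolverControls) -> TissueMesh:
    """Iteratively reset cable rest lengths to their relaxed lengths.

    Each round relaxes the passive tissue (active forces off), then adopts
    every cable edge's equilibrium length as its new rest length; rounds
    stop when the largest relative rest-length change is at most
    ``calib_tol``.  Returns a new mesh whose stored positions are the
    relaxed ground state; a per-round log is kept under
    ``mesh.meta["calibration_log"]``.
    """
    if not any(e.is_cable for e in mesh.edges):
        raise MissingTagsError("calibration requires a tagged cable")
    work = mesh.copy()
    log: list[dict] = []
    if params.k_bend > 0:
        # Direct solve of the fixed point.  At convergence every cable
        # spring sits at its (adopted) rest length and exerts no force, so
        # the calibrated state is exactly a minimum of the energy with the
        # cable springs removed -- which is also why the ground state does
        # not depend on mu_cable.  Jump there first; the literal
        # adopt-and-relax loop below then verifies and polishes.
        free = work.copy()
        for e in free.edges:
            if e.is_cable:
                e.modulus = 0.0
        # best effort: the cable-free system is softer (worse conditioned)
        # than the full one, so a stall here is polished by the loop below
        free_arr = assemble_arrays(free, params, with_active=False)
        free_arr["mobile"] = _mobility_mask(free, controls)
        pre = _relax_arrays(free.positions, free_arr, params,
                            controls.with_(method="lbfgs"))
        work.set_positions(pre.final_positions)
        max_rel = 0.0
        for e in work.edges:
            if e.is_cable:
                cur = work.edge_length(e)
                if cur < 1e-8:
                    raise NonConvergenceError(
                        f"cable edge {e.id} collapsed during calibration")
                max_rel = max(max_rel, abs(cur - e.rest_length) / e.rest_length)
                e.rest_length = cur
        log.append({"round": 0, "stage": "cable-free solve",
                    "max_rel_change": max_rel,
                    "circumference": work.cable_circumference(),
                    "max_force": pre.final_max_force,
                    "steps": pre.steps_taken})
    for rnd in range(1, controls.max_calib_rounds + 1):
        res = relax(work, params, controls, with_active=False)
        if not res.converged:
            raise NonConvergenceError(
                f"relaxation hit t_max={controls.t_max} in calibration round "
                f"{rnd} (max force {res.final_max_force:.3g})")
        work.set_positions(res.final_positions)
        max_rel = 0.0
        for e in work.edges:
            if e.is_cable:
                cur = work.edge_length(e)
                max_rel = max(max_rel, abs(cur - e.rest_length) / e.rest_length)
                e.rest_length = cur
        log.append({"round": rnd, "max_rel_change": max_rel,
                    "circumference": work.cable_circumference(),
                    "max_force": res.final_max_force,
                    "steps": res.steps_taken})
        if max_rel <= controls.calib_tol:
            work.meta["calibration_log"] = log
            work.meta["calibrated_at"] = {"mu_cable": params.mu_cable,
                                          "k_bend": params.k_bend}
            return work
    raise NonConvergenceError(
        f"calibration did not settle in {controls.max_calib_rounds} rounds "
        f"(last max relative rest-length change {log[-1]['max_rel_change']:.3g})")


def run_contraction(calibrated_mesh: TissueMesh, params: MechanicsParams,
                    controls: SolverControls) -> SimulationResult:
    """Relax with active tensions on, deforming the calibrated ground state."""
    return relax(calibrated_mesh, params, controls, with_active=True)


# ---------------------------------------------------------------------------
# result serialization (plain JSON, positions as nested lists)
# ---------------------------------------------------------------------------

def save_result(result: SimulationResult, path: str | Path) -> None:
    doc = {
        "initial_positions": result.initial_positions.tolist(),
        "final_positions": result.final_positions.tolist(),
        "converged": result.converged,
        "final_max_force": result.final_max_force,
        "steps_taken": result.steps_taken,
        "dt": result.dt,
    }
    Path(path).write_text(json.dumps(doc))


def save_snapshots(result: SimulationResult, mesh: TissueMesh,
                   out_dir: str | Path, prefix: str = "snapshot") -> list[Path]:
    """Write each stored snapshot as a numbered mesh JSON file."""
    from .tissue_geometry import save_mesh

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, (_, positions) in enumerate(result.snapshots):
        frame = mesh.copy()
        frame.set_positions(positions)
        path = out_dir / f"{prefix}_{i:04d}.json"
        save_mesh(frame, path)
        paths.append(path)
    return paths


def load_result(path: str | Path) -> SimulationResult:
    doc = json.loads(Path(path).read_text())
    return SimulationResult(
        initial_positions=np.array(doc["initial_positions"], dtype=float),
        final_positions=np.array(doc["final_positions"], dtype=float),
        snapshots=[], converged=doc["converged"],
        final_max_force=doc["final_max_force"],
        steps_taken=doc["steps_taken"], dt=doc["dt"])
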