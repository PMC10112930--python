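"""Orchestration of the in-silico insulation experiment.

For each (k_bend, mu_cable) pair: build and tag the default tissue,
calibrate its ground state at those barrier properties, launch the active
core, and measure the radial movement of the outside nodes.  Every run is
normalised against a single no-barrier baseline (mu_cable = mu_default,
k_bend = 0) computed with identical active forcing, so the normalised
decrease isolates the effect of the barrier alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .equilibration import (SimulationResult, SolverControls,
                            calibrate_ground_state, load_result,
                            run_contraction, save_result)
from .insulation_metrics import (SUMMARY_COLUMNS, radial_displacement,
                                 side_node_ids)
from .mechanics import MechanicsParams
from .tissue_geometry import (TissueMesh, build_hex_tissue, load_mesh,
                              save_mesh, select_active_elements, tag_regions)

#: default active tension, calibrated so the baseline (no-barrier) run
#: roughly halves the 7-cell core area: a clearly visible invagination pit
F_ACTIVE_DEFAULT = 0.4

#: solver controls for desk-scale sweeps (dt is set per parameter pair)
SWEEP_FORCE_TOL = 1e-7
SWEEP_CALIB_TOL = 1e-6


@dataclass
class SweepSpec:
    """The (k, mu) grid and the shared tissue/mechanics/solver settings.

    The default mu grid brackets the two headline stiffness values 1 and
    100 on a log scale; the same active forcing and controls are reused
    across all runs so the baseline normalisation isolates the barrier.
    """

    k_values: tuple = (1.0, 10.0, 100.0)
    mu_values: tuple = (1.0, 3.0, 10.0, 30.0, 100.0)
    n_coronae: int = 6
    cable_after_corona: int = 4
    core_coronae: int = 1
    edge_length: float = 1.0
    extra_active_edges: tuple = ()
    params: MechanicsParams = field(
        default_factory=lambda: MechanicsParams(f_active=F_ACTIVE_DEFAULT))
    controls: SolverControls | None = None  # None -> stability-bound dt per run
    out_dir: Path | None = None

    def __post_init__(self):
        mu = tuple(float(m) for m in self.mu_values)
        if any(b <= a for a, b in zip(mu, mu[1:])):
            raise ValueError("mu_values must be strictly increasing")
        self.mu_values = mu
        self.k_values = tuple(float(k) for k in self.k_values)
        if self.out_dir is not None:
            self.out_dir = Path(self.out_dir)

    def build_mesh(self) -> TissueMesh:
        mesh = build_hex_tissue(self.n_coronae, self.edge_length)
        mesh = tag_regions(mesh, self.cable_after_corona)
        return select_active_elements(mesh, self.core_coronae,
                                      self.extra_active_edges)

    def controls_for(self, params: MechanicsParams) -> SolverControls:
        if self.controls is not None:
            return self.controls
        return SolverControls.for_params(
            params, force_tol=SWEEP_FORCE_TOL, calib_tol=SWEEP_CALIB_TOL,
            method="lbfgs")


def run_single(k_bend: float, mu_cable: float, spec: SweepSpec,
               mesh: TissueMesh | None = None,
               tag: str | None = None) -> tuple[SimulationResult, TissueMesh]:
    """Calibrate and contract the tissue at one (k, mu) pair.

    Returns the contraction result and the calibrated mesh.  If the spec
    has an output directory, both are persisted there as JSON.
    """
    if mesh is None:
        mesh = spec.build_mesh()
    params = spec.params.with_(k_bend=k_bend, mu_cable=mu_cable)
    controls = spec.controls_for(params)
    try:
        calibrated = calibrate_ground_state(mesh, params, controls)
        result = run_contraction(calibrated, params, controls)
    except Exception as err:
        raise type(err)(f"(k={k_bend}, mu={mu_cable}): {err}") from err
    if spec.out_dir is not None:
        spec.out_dir.mkdir(parents=True, exist_ok=True)
        name = tag or f"k{k_bend:g}_mu{mu_cable:g}"
        save_mesh(calibrated, spec.out_dir / f"mesh_{name}.json")
        save_result(result, spec.out_dir / f"run_{name}.json")
    return result, calibrated


def _summary_row(k_bend: float, mu_cable: float, mesh: TissueMesh,
                 result: SimulationResult, baseline_outside_mean: float) -> dict:
    outside = side_node_ids(mesh, "outside")
    inside = side_node_ids(mesh, "inside", exclude_core=True)
    _, mean_out = radial_displacement(result, outside, mesh.centre)
    _, mean_in = radial_displacement(result, inside, mesh.centre)
    ratio = mean_out / baseline_outside_mean
    return {"k_bend": k_bend, "mu_cable": mu_cable,
            "mean_radial_outside": mean_out, "mean_radial_inside": mean_in,
            "n_outside": len(outside), "n_inside": len(inside),
            "normalized_movement": ratio, "decrease": 1.0 - ratio}


def run_sweep(spec: SweepSpec) -> pd.DataFrame:
    """Baseline run plus one run per (k, mu) pair; one summary row each.

    The first row is the baseline itself (k_bend = 0, mu_cable =
    mu_default, normalised movement exactly 1).  Failed pairs are skipped
    and recorded in ``df.attrs["failures"]``.
    """
    mesh = spec.build_mesh()
    baseline_result, baseline_mesh = run_single(
        0.0, spec.params.mu_default, spec, mesh=mesh, tag="baseline")
    outside = side_node_ids(baseline_mesh, "outside")
    _, baseline_mean = radial_displacement(baseline_result, outside,
                                           baseline_mesh.centre)
    rows = [_summary_row(0.0, spec.params.mu_default, baseline_mesh,
                         baseline_result, baseline_mean)]
    failures: list[dict] = []
    for k in spec.k_values:
        for mu in spec.mu_values:
            try:
                result, calibrated = run_single(k, mu, spec, mesh=mesh)
            except Exception as err:  # record the gap, keep sweeping
                failures.append({"k_bend": k, "mu_cable": mu, "error": str(err)})
                continue
            rows.append(_summary_row(k, mu, calibrated, result, baseline_mean))
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    df.attrs["failures"] = failures
    if spec.out_dir is not None:
        spec.out_dir.mkdir(parents=True, exist_ok=True)
        df.to_csv(spec.out_dir / "summary.csv", index=False)
        _write_log(spec.out_dir / "run.log", df, failures)
    return df


def _write_log(path: Path, df: pd.DataFrame, failures: list[dict]) -> None:
    lines = ["insulation sweep summary", df.to_string(index=False)]
    if failures:
        lines.append("FAILED CELLS:")
        lines += [json.dumps(f) for f in failures]
    Path(path).write_text("\n".join(lines) + "\n")


def rebuild_summary(out_dir: str | Path) -> pd.DataFrame:
    """Recompute the summary table from the persisted per-run files.

    A decoupled cross-check of the sweep bookkeeping: loads every
    ``mesh_*.json`` / ``run_*.json`` pair and re-derives each row from the
    stored positions alone.
    """
    out_dir = Path(out_dir)
    base_mesh = load_mesh(out_dir / "mesh_baseline.json")
    base_result = load_result(out_dir / "run_baseline.json")
    outside = side_node_ids(base_mesh, "outside")
    _, baseline_mean = radial_displacement(base_result, outside, base_mesh.centre)
    rows = [_summary_row(0.0, 1.0, base_mesh, base_result, baseline_mean)]
    for mesh_path in sorted(out_dir.glob("mesh_k*.json")):
        name = mesh_path.stem[len("mesh_"):]
        k, mu = (float(x[1:] if x[0] in "km" else x)
                 for x in name.replace("mu", "m").split("_"))
        mesh = load_mesh(mesh_path)
        result = load_result(out_dir / f"run_{name}.json")
        rows.append(_summary_row(k, mu, mesh, result, baseline_mean))
    df = pd.DataFrame(rows, columns=SUMMARY_COLUMNS)
    return df.sort_values(["k_bend", "mu_cable"], ignore_index=True)


def plot_decrease(df: pd.DataFrame, path: str | Path) -> None:
    """Decrease-vs-mu curves, one line per bending coefficient."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for k, grp in df[df.k_bend > 0].groupby("k_bend"):
        ax.plot(grp.mu_cable, grp.decrease, "o-", label=f"k = {k:g}")
    ax.set_xscale("log")
    ax.set_xlabel("cable spring constant $\\mu$")
    ax.set_ylabel("decrease in outside radial movement\n(normalised to no barrier)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def load_sweep_spec(config: dict) -> SweepSpec:
    """Build a SweepSpec from a plain (YAML-derived) mapping."""
    kw: dict = {}
    for key in ("k_values", "mu_values", "extra_active_edges"):
        if key in config:
            kw[key] = tuple(config[key])
    for key in ("n_coronae", "cable_after_corona", "core_coronae"):
        if key in config:
            kw[key] = int(config[key])
    if "edge_length" in config:
        kw["edge_length"] = float(config["edge_length"])
    mech = dict(config.get("mechanics", {}))
    mech.setdefault("f_active", F_ACTIVE_DEFAULT)
    kw["params"] = MechanicsParams.from_dict(mech)
    if "controls" in config:
        kw["controls"] = SolverControls(**config["controls"])
    return SweepSpec(**kw)
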