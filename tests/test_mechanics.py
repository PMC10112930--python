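"""Force laws against finite-difference and closed-form oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from placodevm import (MechanicsParams, active_force, bending_force,
                       build_hex_tissue, select_active_elements, spring_force,
                       tag_regions, total_energy, total_force)
from placodevm.errors import DegenerateGeometryError
from placodevm.tissue_geometry import EdgeRecord

finite_xy = st.tuples(st.floats(-5, 5), st.floats(-5, 5))


def _bend_energy(p, n, q, k):
    """Independent bending-energy oracle used for finite differences."""
    u = np.asarray(p) - np.asarray(n)
    v = np.asarray(q) - np.asarray(n)
    phi = np.arctan2(u[0] * v[1] - u[1] * v[0], u @ v)
    theta = phi if phi >= 0 else phi + 2 * np.pi
    return 0.5 * k * (theta - np.pi) ** 2


# --- spring -------------------------------------------------------------------

def test_spring_force_examples():
    pos = np.array([[0.0, 0.0], [2.0, 0.0]])
    edge = EdgeRecord(0, (0, 1), "junction", rest_length=1.0, modulus=1.0)
    fa, fb = spring_force(edge, pos)
    assert np.allclose(fa, [1.0, 0.0]) and np.allclose(fb, [-1.0, 0.0])
    edge_at_rest = EdgeRecord(0, (0, 1), "junction", rest_length=2.0)
    fa, fb = spring_force(edge_at_rest, pos)
    assert np.allclose(fa, 0) and np.allclose(fb, 0)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(a=finite_xy, b=finite_xy, l0=st.floats(0.1, 3), mu=st.floats(0.1, 10))
def test_spring_force_pair_is_action_reaction(a, b, l0, mu):
    pos = np.array([a, b], dtype=float)
    if np.hypot(*(pos[1] - pos[0])) < 1e-6:
        return
    fa, fb = spring_force(EdgeRecord(0, (0, 1), "junction", l0, mu), pos)
    assert np.allclose(fa + fb, 0, atol=1e-12)
    # magnitude is mu * |l - l0|
    l = np.hypot(*(pos[1] - pos[0]))
    assert np.hypot(*fa) == pytest.approx(mu * abs(l - l0), rel=1e-12)


def test_spring_force_zero_length_is_degenerate():
    pos = np.zeros((2, 2))
    with pytest.raises(DegenerateGeometryError):
        spring_force(EdgeRecord(0, (0, 1), "junction", 1.0), pos)


# --- bending ------------------------------------------------------------------

def test_bending_force_vanishes_when_collinear():
    f = bending_force([0, 0], [1, 0], [2, 0], k_bend=10.0)
    assert all(np.allclose(fi, 0, atol=1e-12) for fi in f)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(p=finite_xy, n=finite_xy, q=finite_xy, k=st.floats(0.1, 100))
def test_bending_force_matches_central_difference_gradient(p, n, q, k):
    p, n, q = (np.array(v, dtype=float) for v in (p, n, q))
    if min(np.hypot(*(p - n)), np.hypot(*(q - n))) < 0.2:
        return
    u, v = p - n, q - n
    phi = np.arctan2(u[0] * v[1] - u[1] * v[0], u @ v)
    theta = phi if phi >= 0 else phi + 2 * np.pi
    if min(theta, 2 * np.pi - theta) < 1e-2:  # branch cut at fully folded
        return
    forces = bending_force(p, n, q, k)
    h = 1e-6
    pts = [p, n, q]
    for which in range(3):
        for dim in range(2):
            step = np.zeros(2)
            step[dim] = h
            plus = [v + step if i == which else v for i, v in enumerate(pts)]
            minus = [v - step if i == which else v for i, v in enumerate(pts)]
            num = -(_bend_energy(*plus, k) - _bend_energy(*minus, k)) / (2 * h)
            scale = max(1.0, abs(num))
            assert forces[which][dim] == pytest.approx(num, abs=1e-5 * scale)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(p=finite_xy, n=finite_xy, q=finite_xy, k=st.floats(0.1, 100))
def test_bending_forces_sum_to_zero_and_exert_no_torque(p, n, q, k):
    p, n, q = (np.array(v, dtype=float) for v in (p, n, q))
    if min(np.hypot(*(p - n)), np.hypot(*(q - n))) < 0.2:
        return
    fp, fn, fq = bending_force(p, n, q, k)
    assert np.allclose(fp + fn + fq, 0, atol=1e-9)
    torque = sum(x[0] * f[1] - x[1] * f[0]
                 for x, f in ((p, fp), (n, fn), (q, fq)))
    assert torque == pytest.approx(0, abs=1e-9)


# --- active -------------------------------------------------------------------

def test_active_force_examples():
    pos = np.array([[0.0, 0.0], [1.0, 0.0]])
    edge = EdgeRecord(0, (0, 1), "junction", 1.0, is_active=True)
    fa, fb = active_force(edge, pos, 0.5)
    assert np.allclose(fa, [0.5, 0]) and np.allclose(fb, [-0.5, 0])
    fa, fb = active_force(edge, pos, 0.0)
    assert np.allclose(fa, 0) and np.allclose(fb, 0)


# --- whole mesh ---------------------------------------------------------------

def _tagged(n=2, cable_after=0, perturb=0.0, seed=0):
    mesh = select_active_elements(tag_regions(build_hex_tissue(n), cable_after), 0)
    if perturb:
        rng = np.random.default_rng(seed)
        mesh.set_positions(mesh.positions
                           + rng.normal(0, perturb, size=(mesh.n_nodes, 2)))
    return mesh


def test_constructed_ground_state_is_force_and_energy_free(default_mesh):
    params = MechanicsParams()  # k=0, f_active=0
    F = total_force(default_mesh, params)
    assert np.hypot(F[:, 0], F[:, 1]).max() <= 1e-9
    assert total_energy(default_mesh, params) <= 1e-12


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_total_force_sums_to_zero(seed):
    rng = np.random.default_rng(seed)
    mesh = _tagged(perturb=0.2, seed=seed)
    params = MechanicsParams(mu_cable=float(rng.uniform(1, 50)),
                             k_bend=float(rng.uniform(0, 50)),
                             f_active=float(rng.uniform(0, 1)))
    F = total_force(mesh, params)
    assert np.allclose(F.sum(axis=0), 0, atol=1e-10)


def test_total_force_is_minus_gradient_of_total_energy():
    mesh = _tagged(n=1, perturb=0.15)
    params = MechanicsParams(mu_cable=7.0, k_bend=3.0, f_active=0.4)
    F = total_force(mesh, params)
    pos = mesh.positions
    h = 1e-6
    for nid in range(mesh.n_nodes):
        for dim in range(2):
            pp = pos.copy()
            pm = pos.copy()
            pp[nid, dim] += h
            pm[nid, dim] -= h
            num = -(total_energy(mesh, params, pp)
                    - total_energy(mesh, params, pm)) / (2 * h)
            scale = max(1.0, abs(num))
            assert F[nid, dim] == pytest.approx(num, abs=1e-5 * scale)


def test_force_field_rotation_equivariance():
    mesh = _tagged(perturb=0.2, seed=3)
    params = MechanicsParams(mu_cable=10.0, k_bend=5.0, f_active=0.3)
    F = total_force(mesh, params)
    ang = 0.7
    R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
    F_rot = total_force(mesh, params, mesh.positions @ R.T)
    assert np.allclose(F_rot, F @ R.T, atol=1e-9)
    F_shift = total_force(mesh, params, mesh.positions + np.array([3.0, -2.0]))
    assert np.allclose(F_shift, F, atol=1e-10)


def test_neutral_cable_parameters_match_untagged_mesh_bitwise():
    tagged = _tagged(perturb=0.2, seed=4)
    untagged = build_hex_tissue(2)
    untagged.set_positions(tagged.positions)
    params = MechanicsParams(mu_cable=1.0, k_bend=0.0)
    F_tagged = total_force(tagged, params, with_active=False)
    F_plain = total_force(untagged, params, with_active=False)
    assert np.array_equal(F_tagged, F_plain)


def test_stretched_edge_energy_increment():
    mesh = build_hex_tissue(0)
    params = MechanicsParams()
    e0 = total_energy(mesh, params)
    pos = mesh.positions
    # move one junctional node radially so a single spoke doubles in length
    edge = next(e for e in mesh.edges if e.kind == "spoke")
    centre, tip = edge.endpoints
    pos2 = pos.copy()
    direction = (pos[tip] - pos[centre])
    pos2[tip] = pos[centre] + 2.0 * direction
    de = total_energy(mesh, params, pos2) - e0
    # the spoke contributes exactly 0.5; its two junction edges also stretch
    d = pos2[tip] - pos[centre]
    spoke_term = 0.5 * (np.hypot(*d) - 1.0) ** 2
    assert spoke_term == pytest.approx(0.5, abs=1e-12)
    assert de >= 0.5


def test_kernel_forces_agree_with_reference_route():
    from placodevm import _kernels
    from placodevm.mechanics import assemble_arrays

    mesh = _tagged(perturb=0.2, seed=5)
    params = MechanicsParams(mu_cable=20.0, k_bend=8.0, f_active=0.4)
    pos = np.ascontiguousarray(mesh.positions)
    arr = assemble_arrays(mesh, params, with_active=True)
    F = np.zeros_like(pos)
    maxf = _kernels.compute_forces(
        pos, F, arr["ei"], arr["ej"], arr["rest"], arr["mod"], arr["tension"],
        arr["trip_prev"], arr["trip_node"], arr["trip_next"], arr["k_bend"],
        arr["l_reg"], np.ones(mesh.n_nodes))
    F_ref = total_force(mesh, params)
    assert np.allclose(F, F_ref, atol=1e-12)
    assert maxf == pytest.approx(np.hypot(F_ref[:, 0], F_ref[:, 1]).max(),
                                 rel=1e-12)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        MechanicsParams(mu_default=0)
    with pytest.raises(ValueError):
        MechanicsParams(k_bend=-1)
    with pytest.raises(ValueError):
        MechanicsParams(eta=0)
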