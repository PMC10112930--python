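"""Numba kernels for the inner integration loop.

The explicit-Euler gradient flow runs for 1e5-1e6 steps per relaxation, so
the per-step force evaluation is compiled.  The formulas mirror
:mod:`placodevm.mechanics` exactly (same spring, bending and tension laws);
a unit test asserts agreement between the two routes.
"""

import math

import numpy as np
from numba import njit

#: status codes returned by _euler
CONVERGED = 0
STEP_BUDGET = 1
DIVERGED = 2


@njit(cache=True)
def _smoothstep(l, l_reg):
    """Angle-penalty weight w(l) and dw/dl (fades out below l_reg)."""
    if l_reg <= 0.0 or l >= l_reg:
        return 1.0, 0.0
    t = l / l_reg
    return t * t * (3.0 - 2.0 * t), 6.0 * t * (1.0 - t) / l_reg


@njit(cache=True)
def compute_forces(pos, F, ei, ej, rest, mod, tension,
                   tprev, tnode, tnext, k_bend, l_reg, mobile):
    """Fill F with the total force field; return max |F_i| (or -1 if degenerate).

    ``mobile`` is a per-node 0/1 mask: forces on pinned nodes are zeroed
    (they neither move nor count toward the convergence residual).
    """
    n = pos.shape[0]
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
    for e in range(ei.shape[0]):
        a = ei[e]
        b = ej[e]
        dx = pos[b, 0] - pos[a, 0]
        dy = pos[b, 1] - pos[a, 1]
        l = math.sqrt(dx * dx + dy * dy)
        if l < 1e-12:
            return -1.0
        c = (mod[e] * (l - rest[e]) + tension[e]) / l
        F[a, 0] += c * dx
        F[a, 1] += c * dy
        F[b, 0] -= c * dx
        F[b, 1] -= c * dy
    if k_bend > 0.0:
        for t in range(tnode.shape[0]):
            p = tprev[t]
            c0 = tnode[t]
            q = tnext[t]
            ux = pos[p, 0] - pos[c0, 0]
            uy = pos[p, 1] - pos[c0, 1]
            vx = pos[q, 0] - pos[c0, 0]
            vy = pos[q, 1] - pos[c0, 1]
            lu2 = ux * ux + uy * uy
            lv2 = vx * vx + vy * vy
            if lu2 < 1e-24 or lv2 < 1e-24:
                return -1.0
            lu = math.sqrt(lu2)
            lv = math.sqrt(lv2)
            wu, dwu = _smoothstep(lu, l_reg)
            wv, dwv = _smoothstep(lv, l_reg)
            phi = math.atan2(ux * vy - uy * vx, ux * vx + uy * vy)
            theta = phi if phi >= 0.0 else phi + 2.0 * math.pi
            dev = theta - math.pi
            g = k_bend * dev * wu * wv
            e_site = 0.5 * k_bend * dev * dev
            cu = e_site * dwu * wv / lu
            cv = e_site * wu * dwv / lv
            fpx = -g * uy / lu2 - cu * ux
            fpy = g * ux / lu2 - cu * uy
            fqx = g * vy / lv2 - cv * vx
            fqy = -g * vx / lv2 - cv * vy
            F[p, 0] += fpx
            F[p, 1] += fpy
            F[q, 0] += fqx
            F[q, 1] += fqy
            F[c0, 0] -= fpx + fqx
            F[c0, 1] -= fpy + fqy
    mx = 0.0
    for i in range(n):
        F[i, 0] *= mobile[i]
        F[i, 1] *= mobile[i]
        m = F[i, 0] * F[i, 0] + F[i, 1] * F[i, 1]
        if not m >= 0.0:  # NaN guard
            return math.nan
        if m > mx:
            mx = m
    return math.sqrt(mx)


@njit(cache=True)
def compute_energy(pos, ei, ej, rest, mod, tension, tprev, tnode, tnext,
                   k_bend, l_reg):
    """Total energy matching compute_forces (springs + bending + tension)."""
    e = 0.0
    for k in range(ei.shape[0]):
        dx = pos[ej[k], 0] - pos[ei[k], 0]
        dy = pos[ej[k], 1] - pos[ei[k], 1]
        l = math.sqrt(dx * dx + dy * dy)
        d = l - rest[k]
        e += 0.5 * mod[k] * d * d + tension[k] * l
    if k_bend > 0.0:
        for t in range(tnode.shape[0]):
            p = tprev[t]
            c0 = tnode[t]
            q = tnext[t]
            ux = pos[p, 0] - pos[c0, 0]
            uy = pos[p, 1] - pos[c0, 1]
            vx = pos[q, 0] - pos[c0, 0]
            vy = pos[q, 1] - pos[c0, 1]
            wu, _ = _smoothstep(math.sqrt(ux * ux + uy * uy), l_reg)
            wv, _ = _smoothstep(math.sqrt(vx * vx + vy * vy), l_reg)
            phi = math.atan2(ux * vy - uy * vx, ux * vx + uy * vy)
            theta = phi if phi >= 0.0 else phi + 2.0 * math.pi
            e += 0.5 * k_bend * (theta - math.pi) ** 2 * wu * wv
    return e


@njit(cache=True)
def fire_relax(pos, ei, ej, rest, mod, tension, tprev, tnode, tnext,
               k_bend, l_reg, mobile, dt0, dt_max, force_tol, max_steps):
    """FIRE energy minimisation (fictitious inertia, adaptive step), in place.

    Finds the same equilibria as the over-damped flow at a fraction of the
    force evaluations; used for ground-state calibration and sweeps where
    only the final configuration matters.  Returns (steps, max_force,
    status) like :func:`euler_relax`.
    """
    n = pos.shape[0]
    F = np.zeros_like(pos)
    v = np.zeros_like(pos)
    maxf = compute_forces(pos, F, ei, ej, rest, mod, tension,
                          tprev, tnode, tnext, k_bend, l_reg, mobile)
    if maxf < 0.0 or not math.isfinite(maxf):
        return 0, maxf, DIVERGED
    dt = dt0
    alpha = 0.1
    n_pos = 0
    steps = 0
    while steps < max_steps:
        if maxf <= force_tol:
            return steps, maxf, CONVERGED
        p = 0.0
        for i in range(n):
            p += v[i, 0] * F[i, 0] + v[i, 1] * F[i, 1]
        if p > 0.0:
            n_pos += 1
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        elif steps > 0:
            n_pos = 0
            dt *= 0.5
            alpha = 0.1
            for i in range(n):
                v[i, 0] = 0.0
                v[i, 1] = 0.0
        vnorm = 0.0
        fnorm = 0.0
        for i in range(n):
            v[i, 0] += dt * F[i, 0]
            v[i, 1] += dt * F[i, 1]
            vnorm += v[i, 0] * v[i, 0] + v[i, 1] * v[i, 1]
            fnorm += F[i, 0] * F[i, 0] + F[i, 1] * F[i, 1]
        if fnorm > 0.0:
            mix = alpha * math.sqrt(vnorm / fnorm)
            for i in range(n):
                v[i, 0] = (1.0 - alpha) * v[i, 0] + mix * F[i, 0]
                v[i, 1] = (1.0 - alpha) * v[i, 1] + mix * F[i, 1]
        for i in range(n):
            pos[i, 0] += dt * v[i, 0]
            pos[i, 1] += dt * v[i, 1]
        steps += 1
        maxf = compute_forces(pos, F, ei, ej, rest, mod, tension,
                              tprev, tnode, tnext, k_bend, l_reg, mobile)
        if maxf < 0.0 or not math.isfinite(maxf):
            return steps, maxf, DIVERGED
    status = CONVERGED if maxf <= force_tol else STEP_BUDGET
    return steps, maxf, status


@njit(cache=True)
def euler_relax(pos, ei, ej, rest, mod, tension, tprev, tnode, tnext,
                k_bend, l_reg, mobile, inv_eta, dt, force_tol, max_steps):
    """Integrate eta * dx/dt = F by explicit Euler, in place.

    Returns (steps_taken, final_max_force, status).  Stops as soon as the
    maximum per-node force magnitude drops to force_tol.
    """
    F = np.zeros_like(pos)
    maxf = compute_forces(pos, F, ei, ej, rest, mod, tension,
                          tprev, tnode, tnext, k_bend, l_reg, mobile)
    if maxf < 0.0 or not math.isfinite(maxf):
        return 0, maxf, DIVERGED
    steps = 0
    while steps < max_steps:
        if maxf <= force_tol:
            return steps, maxf, CONVERGED
        scale = dt * inv_eta
        for i in range(pos.shape[0]):
            pos[i, 0] += scale * F[i, 0]
            pos[i, 1] += scale * F[i, 1]
        steps += 1
        maxf = compute_forces(pos, F, ei, ej, rest, mod, tension,
                              tprev, tnode, tnext, k_bend, l_reg, mobile)
        if maxf < 0.0 or not math.isfinite(maxf):
            return steps, maxf, DIVERGED
    status = CONVERGED if maxf <= force_tol else STEP_BUDGET
    return steps, maxf, status
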