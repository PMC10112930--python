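# Methods

## The model

`placodevm` simulates a flat epithelial primordium (a placode) as a 2D
vertex model.  Each of the 127 hexagonal cells carries six junctional
corner nodes and one central node; corners are joined to each other and to
the centre by linear (Hookean) springs, so a single cell resists shear and
area change without explicit area or perimeter terms.  All lengths are in
model units (1 = initial junctional edge length); forces and times are in
the corresponding nondimensional units.

A closed loop of junction edges — the interface between the cells of
corona ≤ 4 and the two outermost coronae — represents the supracellular
actomyosin cable that rings the placode.  Cable edges carry two extra
properties:

* an elevated spring constant `mu_cable` (swept 1…100; ordinary edges have
  `mu_default = 1`), and
* a bending penalty between consecutive cable segments, with energy
  `(k/2)(θ − π)²` per cable node and restoring force magnitude
  `k(θ − π)`, which aligns adjacent segments the way junctions along the
  cable are aligned in vivo.  Forces are the exact analytic gradient, so
  each bending triplet conserves linear and angular momentum.

Apical constriction at the forming invagination pit is modelled by a
constant contractile tension `f_active` on every edge (junctional and
spoke) of the seven central cells; an `extra_edges` list lets users add
further constricting junctions.  Nodal motion is over-damped,
`η dx_i/dt = F_i`, with friction `η = 1`.

## Ground-state calibration

With `k > 0` the freshly built tissue is not force-free: the initially
zig-zag cable straightens, circularises, and shortens.  Following the
rest-length adoption procedure, the tissue is relaxed without active
forces and every cable edge's equilibrium length becomes its new rest
length, repeated until the rest lengths stop changing (relative change ≤
`calib_tol`, default 1e-6).

Two facts about this fixed point shape the implementation:

1. **It is independent of `mu_cable`.**  At the fixed point every cable
   spring sits at its rest length and exerts no force, so the calibrated
   configuration is exactly a minimum of the energy *with the cable
   springs removed*.  This is what makes the ground state consistent as
   the cable stiffness is swept.  `calibrate_ground_state` exploits it: it
   first minimises the cable-free energy directly, then runs the literal
   adopt-and-relax loop, which confirms convergence in about one round.
   (The literal loop alone approaches the fixed point only sublinearly —
   thousands of rounds at `k = 100` — because tangential redistribution of
   cable nodes is a nearly flat direction of the effective landscape.)
2. **The calibrated state is not zero-energy.**  A closed loop has total
   turning 2π, so the bending energy has an irreducible floor
   ≥ k(2π)²/(2n) for an n-segment cable, balanced at equilibrium by
   residual stretch in non-cable edges.  What the calibration zeroes is
   the cable's *spring* energy.  With `k = 0` the ground state is exactly
   zero-energy.

## Regularisation of the bending penalty

The unweighted angle penalty `k(θ − π)` is degenerate in discrete form:
collapsing a cable segment merges two corners and deletes an angle term,
which can lower the energy with a non-vanishing gradient, so no
equilibrium exists (observed at `k = 10, mu_cable = 1` under the default
forcing: a corner edge collapses to ~1e-8 with residual force ~3e2).
Each angle term is therefore weighted by `smoothstep(l / bend_cutoff)` of
its two segment lengths (`bend_cutoff = 0.02`): a merged corner smoothly
stops being a penalised angle, removing the 1/l force divergence while
leaving every configuration whose segments exceed the cutoff bit-for-bit
unchanged.  Ground states keep their shortest cable segment ≈ 0.033,
above the cutoff; only collapsing corners during strong contraction enter
the regularised regime.  The analytic gradient includes the weight terms
and is finite-difference-tested on both sides of the cutoff.

## Solvers and numerical choices

* **Explicit Euler** (default `method="euler"`) realises the over-damped
  flow; trajectory-level statements (energy monotonicity, the closed-form
  two-node spring relaxation) hold for this method.  The step is clamped
  to `dt ≤ c·η/K` with `c = 0.1` and `K` the largest stiffness scale —
  spring moduli, `4k/l²` for the shortest bending segment, or
  `30k/cutoff²` once a segment is inside the regularised regime — and is
  re-derived from the current geometry every integration chunk, since
  collapsing corners tighten the bound mid-run.
* **FIRE** (`method="fire"`) and **L-BFGS with a FIRE polish**
  (`method="lbfgs"`, used by the sweeps) find the same equilibria at a
  small fraction of the force evaluations.  L-BFGS handles the
  ill-conditioned post-collapse landscapes but its line search stalls
  near the energy's machine precision (max residual force ~1e-5 on stiff
  tissues); the FIRE polish then pushes the residual below `force_tol`.
  A test asserts Euler and FIRE agree on the final configuration.
* Equilibrium means max per-node force ≤ `force_tol` (1e-8 default;
  1e-7 for the sweeps).  Convergence failures return
  `converged = False` rather than raising, except inside calibration
  where they abort the run.
* The pipeline contains no randomness: repeated runs are bit-identical.

Default sweep problem size: 3 bending coefficients × 5 cable stiffnesses
+ 1 baseline on the 127-cell tissue (~6–7 minutes on one CPU).

## The insulation readout

After calibration, the active core contracts to a new equilibrium and the
radial movement `Δr = |x(0) − c| − |x(final) − c|` (positive = toward the
tissue centre) is averaged over junctional nodes strictly outside the
cable (an `outermost_only` option restricts to the outer rim instead,
since "peripheral" is ambiguous; both sets are implemented).  The inside
mean excludes nodes of actively constricting cells, mirroring the in-vivo
exclusion rule.  Dividing the outside mean by its value in a no-barrier
baseline run (`mu_cable = mu_default`, `k = 0`, same forcing) gives the
normalised movement; `decrease = 1 − normalised movement` is the
insulation index.  The summary table reports the baseline as an explicit
first row (its normalised movement is 1 by construction).

With the calibrated defaults the baseline run halves the core area
(50.1% reduction at `f_active = 0.4`, the documented calibration for a
clearly visible pit), and the decrease rises monotonically with
`mu_cable` for every `k` in {1, 10, 100}.

## Synthetic vertex tracks

The track generator emulates the time-lapse quantification: vertices
inside the cable polygon drift 2 µm toward the pit over one 10 min 30 s
movie window, outside vertices do not drift, and every sample carries
isotropic Gaussian positional noise (0.3 µm s.d., a typical vertex
localisation error at ~0.22 µm/px).  Start positions are sampled from the
polygon's doubled bounding box, rejected within 3 µm of the pit (tracked
vertices are near, but not part of, the pit), and labelled by polygon
containment.  Everything is determined by a single seed.

What the generator does **not** emulate: vertex-track dropouts, drift of
the whole field of view, anisotropic motion along junctions, or the
spatial decay of displacement with distance from the pit.  Passing the
closed-loop recovery tests therefore shows the estimator is unbiased
under idealised motion, not that it is robust to real imaging artefacts.

The analysis measures `|x(t0) − pit| − |x(t0+window) − pit|` per track
(end sample = last sample inside the window), averages by side after
discarding `cable` and `excluded` tracks, and attaches a seeded
nonparametric bootstrap CI (2000 resamples) to the inside−outside
difference — a quantitative extension of an analysis that is qualitative
in origin.  A `SimulationResult` can be exported as two-sample tracks and
fed through the identical code path.

## Known limitations

* Regular hexagonal initial condition only; no T1 transitions, division,
  or extrusion — strong contraction is accommodated purely elastically.
* Constant-tension active edges can in principle collapse (tension
  exceeding spring resistance); the defaults stay well clear.
* The linear spring law and the spoke-based area resistance are choices
  within the stated model family; only the cable's relative properties
  (μ, k) are swept, so conclusions are about the barrier, not absolute
  moduli.
* The bending regularisation cutoff (0.02) is a numerical parameter; the
  insulation readout is insensitive to it because ground states never
  enter the regularised regime.
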