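# Methods

## Model

`spindlesim` simulates a minimal active network of dynamic microtubules and
two-unit crosslinking motors in a confined volume, together with the
quantification pipeline used to characterize the emerging organization
(monopolar asters, bipolar spindles, multipolar or unfocused networks).

### Microtubules

Microtubules are inextensible semiflexible fibers, discretized as vertex
chains with target segmentation 0.5 µm (vertex count `max(2, ceil(L/0.5)+1)`,
so actual segments never exceed the target — this also bounds the neighbor
search radius).  The minus end is static; the plus end follows a two-state
model with growth speed `v_g`, shrinkage speed `v_s`, catastrophe rate
`k_cat` and rescue rate `k_res`.  In the bounded-growth regime
(`v_s·k_cat − v_g·k_res > 0`) the steady-state mean length and lifetime are

    L   = v_g·v_s / (v_s·k_cat − v_g·k_res)
    tau = (v_g + v_s) / (v_s·k_cat − v_g·k_res)

Only (`v_g`, `L`, `tau`) triples are fixed by the scenarios; the package
inverts them at `k_res = 0` (`params_from_targets`), giving
(v_s = 375 nm/s, k_cat = 0.012/s) for the slow-growth scenario
(v_g = 30 nm/s, L = 2.5 µm, tau = 90 s) and (v_s ≈ 92 nm/s, k_cat = 0.024/s)
for the fast-growth one (120 nm/s, 5 µm, 96 s).  Any `k_res > 0` solution of
the same triple is an equivalent parameterization that the config accepts.
With `k_res = 0` the stationary length distribution is exponential with
mean L (property-tested by a KS test).

New filaments appear at constant rate ν with isotropic 3D orientation and
initial length 0.01 µm, uniformly inside a small central volume
(1×1×0.2 µm³ box, or a 1 µm × 1 µm cylinder for cylindrical containers);
filaments are removed when they shrink below 0.005 µm.  The steady-state
filament number is ν·tau.

### Motors

A crosslink complex joins two binding units by a Hookean spring (rest
length 0.05 µm, stiffness 100 pN/µm, no angular constraint).  Unit kinds:

* **motor** — walks with the linear force–velocity law
  `v = v_m (1 + f⃗·d̂ / f_stall)`, clamped to [0, |v_m|] (assisting loads
  saturate at `v_m`, super-stall loads at zero); at a filament end it dwells
  and keeps unbinding at its rate.
* **diffusive** — one-dimensional lattice diffusion (D, 8 nm lattice) whose
  loaded drift is `D·ΔU/(a·k_B·T)` with `ΔU = f·a`, i.e. `D·f/k_B T`.
* **end binder** — binds only within 0.03 µm of the minus end, static.

All units unbind at the Bell rate `k_off·exp(f/f_unbind)`, with `f` the
spring tension when doubly bound.  Binding happens at rate `k_on` per unit
when within 0.05 µm of a fiber (to the nearest fiber point; end binders only
inside their end zone; `parallel_only` species refuse antiparallel second
attachments).  Free complexes diffuse in the container with
D_free = 10 µm²/s; since their positions only matter when a binding coin
fires, the accumulated displacement is applied lazily at those moments.

Archetypes follow the published designs: kinesin-5 (2 × +30 nm/s motor
units, k_off 0.1/s, run length 300 nm), HSET (−80 nm/s nonprocessive motor,
k_off 5/s, run length 16 nm + diffusive unit D = 0.1 µm²/s, k_off 0.01/s),
a symmetric minus motor (2 × −v units, k_off 0.1/s), dynein/end-NuMA
(−1200 nm/s motor + minus-end binder, optionally parallel-only) and
dynein/diffusive-NuMA (−120 nm/s motor + diffusive unit).

Values not printed anywhere were chosen once: `f_stall = 5 pN` and
`f_unbind = 3 pN` (single-motor scale), `k_on = 10/s`.  The binding rate
deserves a note: a figure legend mentions a minus-motor binding rate of
0.1/s for one phase-space panel, but a global 0.1/s at 50 nm capture range
cannot produce the described regime of 5–20 motors per microtubule with
dense crosslinking — the bound fraction would be well below 1%.  10/s
reproduces that regime and is a standard choice for this model class; it is
exposed per species in the config.

### Mechanics

Each fiber vertex moves overdamped with isotropic drag
`γ = 3π·η·s·c` (viscosity η = 0.05 Pa·s, drag factor c = 1) under bending
elasticity (κ = 20 pN·µm², discretized as the second-difference quadratic
form `κ/(2s³)·Σ|Δ²x|²`), short-range steric repulsion between distinct
fibers (Hookean, range 50 nm, 100 pN/µm), crosslink spring forces, harmonic
confinement (100 pN/µm) realizing reflecting boundaries, and thermal forces
(kT = 4.2 pN·nm).

The integrator is a linearized backward-Euler step solved matrix-free by
conjugate gradients: `(diag(γ/dt) + A)·δ = F(x) + (γ/dt)·ξ`, where `A`
assembles the exact per-fiber bending stiffness, a rank-one `k·ûûᵀ` term
per crosslink/steric element and the confinement diagonal, preconditioned
by the exact per-fiber (diagonal + bending) banded LDLᵀ factorization.
This is essential, not a refinement: crosslink and steric springs
(relaxation time γ/k ≈ 2 ms) are stiff at dt = 10 ms, and any purely
diagonal (locally damped) treatment suppresses the *collective* mobility of
crosslinked fiber clusters by a factor ≈ 1 + dt·K/γ per attached spring —
which quietly kills pole coalescence while leaving every isolated two-fiber
test correct.  Solver tolerance/iteration cap (3·10⁻³, 16) were fixed after
verifying that network observables (link tensions, motor end occupancy) are
insensitive to much stricter settings.

Bound diffusive units are integrated by the exact Ornstein–Uhlenbeck
solution of diffusion against the crosslink spring along the fiber (their
relaxation time kT/(D·k) ≈ 0.4 ms is far below dt); this preserves the
"slippery anchor" property of the NuMA-like unit, which a naive Euler
update destroys by numerically sustaining multi-pN loads on a unit that
should yield.  Unloaded behavior reduces to plain diffusion (MSD = 2Dt)
and small loads to the drift `D·f/k_B T`; the public `diffusive_step`
operation additionally offers the literal biased lattice-hop sampler for
unit-scale use.

Inextensibility after the mechanics step is enforced by a SHAKE-style
minimal-displacement projection (pairwise symmetric bond-length
corrections, Gauss–Seidel sweeps to 10⁻³ relative).  The minimal-
displacement property matters twice over: an end-anchored arc-length
resampling would suppress the longitudinal force and diffusion response of
the fiber (making poleward transport nearly impossible), and even a
COM-corrected resampling slowly diffuses away thermal curvature by cutting
corners, which biases the sampled persistence length upward.  Growth and
shrinkage are applied separately, by arc-length resampling anchored at the
minus end during the topology rebuild, so the minus end is stationary
under pure polymerization dynamics.  Free-fiber diffusion, drag-limited
drift, rotation under a couple, the antiparallel sliding speed of a
crosslinked pair, and the equilibrium tangent correlations of a soft fiber
(against the discrete-chain closed form coth β − 1/β) all reproduce their
expectations quantitatively.

The per-step schedule is: plus-end dynamics → nucleation → topology rebuild
(removals, resampling, insertions) → release of attachments the plus end
passed → Bell unbinding + motor stepping/lattice diffusion → binding (free
complexes, then second units) → implicit mechanics step → reprojection.
Neighbor queries (binding and sterics) use a uniform spatial hash over
segments, cached between steps and rebuilt when established fibers have
moved more than half the coverage slack.  All randomness comes from three
`numpy` Generators spawned from the run seed; kernels (numba) consume no
randomness, so runs are reproducible bit-for-bit for a given seed.

Default dt = 10 ms; the desk-scale mini scenarios use 20 ms, which was
verified to leave the crosslinked-pair sliding speed unchanged to three
digits.  A diagnostic aborts the run (returning the partial trajectory) if
a single step ever displaces a vertex by more than a segment.

## Quantification

* **Density maps** — minus/plus end positions deposited as unit-mass 2D
  Gaussians (σ = 0.25 µm) integrated over 0.5 µm grid cells, accumulated
  over a frame window (the final 51 frames by default); the map total
  equals the number of deposited points.
* **Ratio map** — minus intensities below 5% of the map maximum are zeroed,
  then `Ratio = I_minus / (1 + I_plus)` (which reduces to `I_minus` where
  `I_plus = 0`).
* **Pole detection** — strict local maxima of the ratio map above a
  density threshold (8 at full scale), merged if closer than 3 grid cells
  (keeping the higher value; ties resolved toward the lower grid index).
  The per-pole minus-end count is the per-frame count histogram value in
  the pole's pixel.
* **Pole statistics** — pole counts sampled every 1.7 min (each from a
  51-frame sliding map window); mean/SD over the final 13 min.  The
  network state is classified as monopolar (mean ∈ [0.5, 1.5), SD < 0.5),
  bipolar (mean ∈ [1.5, 2.5), SD < 0.75), unfocused (mean ends per pole
  below a floor of 5) or multipolar.
* **Link topology** — every doubly-bound crosslink is classified into
  H_parallel / H_antiparallel / X / T / V: an attachment within 0.03 µm
  (inclusive) of either filament end is an "end"; V = both ends, T = one
  end, otherwise H when |cos θ| ≥ 0.5 between local tangents (sign splits
  parallel/antiparallel) and X below.  The five classes partition the
  census.
* **Speckles, kymographs and flux** — material points at Poisson arc-length
  positions advect with the fiber lattice and die with their fiber;
  kymographs stack per-frame 1D projections onto the pole–pole axis (0.1 µm
  bins; principal-axis fallback when fewer than two poles).  The flux speed
  is the median |axial slope| of per-track linear fits, sign-resolved per
  half-spindle.
* **Spindle width** — fiber crossings of the plane perpendicular to the
  pole–pole axis at its midpoint contribute their lateral coordinates;
  the width is the central 90% range (an operationalization of a visual
  measurement; for a uniform bundle of lateral span w it returns 0.9·w).
  The √N scaling coefficient is fit by least squares on `w = c·√N`.

## Synthetic fixtures and mini scenarios

Each analysis stage has a generator with known ground truth: planted pole
clouds (tight minus-end clusters off grid-cell edges, plus ends enriched
between poles for k ≥ 2 or on an outward ring for an aster), an enumerated
link-geometry suite incl. the inclusive 0.03 µm boundary, event-driven
single-motor ensembles (exponential dwell; run = speed × dwell), and
drifting speckle fields.  These emulate the *geometry* of the real
observables, not their dynamics: passing planted-data tests validates the
measurement pipeline, not the emergent biology.

Mini spindle scenarios scale box area, nucleation rate and motor counts
together (15×15×0.2 µm³, ν = 1/s, ~90 microtubules at steady state, 800
motors per species, 12 min), preserving the motors-per-microtubule ratio of
the full-scale conditions.  Because pole-map intensities scale with the
microtubule number, the mini analysis scales the detection threshold and
the ends-per-pole floor by the same factor 4 (threshold 8 → 2, floor
5 → 1.25).  Problem sizes used by the automated checks: 1e5-run motor
ensembles, 1e4-filament dynamics ensembles, a 15-min motor-free run at full
Fig-1 conditions, and 12-min mini spindle runs.

## Known limitations

* Full-scale emergent numbers (stable pole count 2 with ~61 ends per pole,
  the printed link-fraction percentages, ~30 nm/s flux, √N width scaling)
  require the full 33-min, 3200–19000-motor, 30–40-replicate experiments
  and are not recomputed by the desk-scale checks.
* The mini scenarios robustly reproduce the qualitative link-topology
  signatures that distinguish the motor designs — T-dominant censuses for
  dynein/diffusive-NuMA (≈55% end-to-side links), V-dominant for the
  symmetric minus motor (≈60% end-to-end), H-dominant with essentially no V
  for HSET (≈88% side-to-side) — and the stability/focusing ordering
  between HSET and dynein/diffusive-NuMA.  What they do *not* reproduce
  within their 12 minutes is the final coalescence of minus-end clusters
  into one or two dominant poles: the desk-scale networks end with several
  weak clusters (classified multipolar/unfocused), so the bipolar and
  monopolar end states of the balanced and minus-motor-dosed conditions are
  not reached.  The corresponding tests are left failing rather than
  weakened; pole coalescence is the slowest process in the model and the
  least certain to survive a 4-fold scale-down.
* Free parameters not printed in the source material (`f_stall`,
  `f_unbind`, `k_on`, spring stiffness, steric and drag constants) shift
  the balance between antiparallel sliding and minus-end capture; all are
  exposed in the config for sensitivity work.
* The inextensibility projection is a reparametrization, not a constrained
  minimization; drag is isotropic per vertex (no slender-body anisotropy,
  no hydrodynamic coupling).
* The implicit solve linearizes spring directions within a step; steric
  contacts are treated as bilateral within the solve (their one-sided force
  is exact, the stiffness sign is not), which slightly overdamps contact
  separation.
* Unbound-complex diffusion uses clamped (not reflected) walls at the
  sampling instants.
* The importer for Cytosim-style text reports recovers positions and link
  records only, best-effort.
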