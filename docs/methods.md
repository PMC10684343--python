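# Methods

This note documents the model implemented by `multicargo`, the numerical
choices behind it, and what the test suite does and does not demonstrate.

## Model and assumptions

A cargo is a rigid body of half-width `L` with `N` identical,
non-interacting legs.  While bound (`1 ≤ n ≤ N` legs attached) its centre
is *defined* as the arithmetic mean of the bound-leg positions — a force
balance with equal linkage stiffnesses.  Two consequences are used
throughout:

* a binding/unbinding event at position `y` displaces the centre by
  `(y − x_a)/(n + 1)` / `−(y − x_a)/(n − 1)`;
* the bound-leg distribution `P_b(u | n)` of offsets `u = x_l − x_a` has
  **exactly zero mean** for every `n`, by construction.

Free legs are assumed to re-equilibrate on the cargo surface much faster
than they bind (`t_d ≪ t_b`), so binding positions are drawn from the
static shape factor `S_H` — a uniform window of half-width `L` (a disk of
radius `L` in 2D) — weighted by the local binding rate `κ₁(y)`.  Bound
legs are immobile; unbinding occurs at `κ₂(x_l)`.  A third event type
displaces all bound legs by `Δx` at rate `k̄₃` and represents
deterministic substrate motion; only the product `k̄₃Δx` (the drift
velocity) is physical, and `Δx` defaults to 0.05 L when only the velocity
is specified (one tubulin dimer, −8 nm, in the tip frame).

Units: lengths in `L`, times in `t_c = 1/κ₂`; the tip-tracking
application uses nm and s.

## Mean-field layer

At fixed centre position the leg count is a birth–death chain with
`b_n = (N − n)∫κ₁S_H` and `d_n = n∫κ₂P_b`.  From it come

* the mean dwell time `T = Σ_n (1/d_n) Π_{j<n} b_j/d_j` (first passage
  from `n = 1` to 0), cross-checked in the tests against an independent
  linear solve of the absorbing generator;
* `P_n(x)` in two modes: `reflecting` (stationary distribution of the
  chain restricted to `{1..N}`, closed form, the default) and
  `quasi_stationary` (leading left eigenvector with absorption, i.e.
  conditioned on survival).  The two differ by ≲ 0.05 total variation for
  uniform rates at `N = 10`; the gap is the "long-lived cargo"
  approximation and both are exposed.

Event-weighted displacement moments assemble the drift `S₁(x)` and noise
intensity `S₂(x)`; `D_eff = S₂/2`, `v_eff = S₁ − ∂ₓD_eff` (centred
differences, one-sided at open ends).  Unbinding from `n = 1` is terminal:
it contributes to `d₁` and to `k_off = 1/T` but no displacement (the
`1/(n − 1)` factor is never evaluated at `n = 1`).

**Bound-leg distributions.**  `P_b` is not derivable in closed form.
Three representations are provided: a *uniform surrogate* (`P_b = S_H`),
*empirical* per-`n` time-weighted histograms from simulation, and a
*fitted* symmetric two-parameter family `p(u) ∝ (1 − |u/L|^a)^b`
(renormalized numerically at every parameter value).  The surrogate
overestimates the probability of legs near the cargo extremities and
therefore overestimates `D_eff`; the empirical/fitted forms reproduce the
simulated long-time diffusivity.  Near a substrate edge the naive
surrogate clipped by the edge would acquire a nonzero mean — violating
the zero-mean property above — and fabricate an outward unbinding drift;
the edge-aware variant (uniform on `[−b, b]`, `b = min(L, |x_edge − x_a|)`)
restores the constraint and with it the restoring velocity at the edge.

**Quadratures.**  Window integrals use 64-point Gauss–Legendre per
segment, split at profile support edges and breakpoints; empirical `P_b`
integrals use the trapezoid rule on the histogram grid.  On periodic
domains profiles are evaluated at wrapped coordinates (smooth profiles
assumed there).

**Fixed points.**  Zeros of `S₁` on the table grid, refined by Brent's
method on the full quadrature.  Values of `|S₁|` below
`max(1e-12, 1e-9·max|S₁|)` are treated as exactly zero so that quadrature
round-off (~1e-17) in flat profile tails does not create spurious roots.

**Approximations.**  The small-cargo expansion
`S₁ ≈ Σ_n P_n[(N−n)L²κ₁′/(3(n+1)) − (n/(n−1))κ₂ I(n)] + k̄₃Δx` requires
`L ≪ |κ₁′/κ₁″|`; on the steep flank of the canonical bump this holds only
for `L ≲ 0.25`, which is where the tests compare it against the full
quadrature (20% agreement) and verify the monotone approach to the
`N → ∞` plateau `L²κ₁′/3` (15% tolerance: the residual is the finite
`κ₂/κ̄₁` ratio entering `P_n`, not a numerical error).  The substrate-edge
formula uses the stated `J_±` truncated first moments of `P_b`; the exact
integration limits are one of the genuinely open conventions and were
fixed as: `J₊` integrates from the interior up to the edge, `J₋` from the
edge inward.

## Stochastic engine

Exact Gillespie simulation: exponential waiting times from the total
propensity, event selection proportional to rates, binding positions by
rejection sampling against the global profile maximum over the window
(exact for any profile; efficiency ≥ 1/3 for the canonical bump).  Window
integrals of κ₁ use a dense antiderivative table (16384 cells) rather than
per-event quadrature.  Positions are unwrapped; periodic domains wrap only
the rate-profile argument.  Each trajectory carries its own RNG stream
spawned from the master seed (`numpy` `SeedSequence`), making ensembles
bit-reproducible.  Initial binding positions are configurable: fixed,
uniform over the domain (default, matching the uniform re-injection used
by the coarse-grained layers), or ∝ κ₁.

In 2D the logic is identical on a disk footprint.  The binding propensity
needs the disk average of κ₁ around the centre; it is precomputed once per
model by FFT convolution of the rate field with the normalized disk kernel
on a 512² periodic grid and interpolated bilinearly.  Binding *positions*
are rejection-sampled exactly, so only the event-time intensity carries
the grid discretization.  The 2D engine supports uniform unbinding rates
and x-direction collective steps (all scenarios used here satisfy both).

## Coarse-grained layers

*Langevin*: Euler–Maruyama in the Itô convention (no Stratonovich
correction), `S₁/S₂` linearly interpolated from the tables, `S₂` clamped
at zero, Wiener increments by inverse-transform sampling.
Detachment/rebinding is emulated by teleporting walkers to a uniform
position with rate `k_ran(x) = 1/t_dwell(x)` (thinning).  `dt ≤ 0.1 t_c`
enforced; halving `dt` changes the stationary density by < 0.05 total
variation at test scale.

*Fokker–Planck*: conservative flux form on a uniform periodic grid
(default 256–512 cells), central differences; mass is conserved to
round-off by the telescoping flux sum.  Time-dependent solutions use
stiff BDF integration.  The attachment term `k_on(x)` of the continuity
equation is not fixed by the model; the `source_sink` mode closes it with
a spatially uniform source balancing the total sink flux `∫k_off P` —
mirroring the Langevin teleportation — and reports the stationary density,
obtained by implicit-Euler marching (factored operator, `dt = 1 t_c`)
until the relative change per `t_c` falls below 1e-8.  This closure is
validated only through agreement with the Gillespie stationary density
(total variation ≈ 0.03 at 2×10⁴ cargo for the canonical bump).

## Trajectory analysis

All histograms (bound-leg offsets, leg-count occupancy, stationary
density) are time-weighted.  MSDs are ensemble averages over survivors
aligned at first binding; diffusivities are weighted least-squares slopes
in a short window (0.05–0.8 `t_c`) and a long window (2 `t_c` up to the
simulated horizon).  Their errors `ζ` are **delete-one-block jackknife**
estimates over trajectories: MSD values at different lags share
trajectories, and the naive fit covariance understates the slope error
several-fold.  Survivor conditioning is a real (size-independent) bias of
this estimator at late lags — it weights leg-count states by survival —
which is why the long window must stay where hundreds of survivors
remain; at `N = 2` (mean dwell 1.5 `t_c`) this caps the usable window at
≈ 5–8 `t_c`.

Empirical drift/noise fields come in two routes: binning per-event centre
displacements by pre-event position (`S₁ = Σδ/T_bin`, `S₂ = Σδ²/T_bin`,
Poisson-type errors `√Σδ²/T`), or plugging empirical `P_n` and `P_b` into
the mean-field formulas.  Smoothing is a centred moving average (5 bins in
1D; each point with its 4 nearest neighbours in 2D, applied before the
polar decomposition).  Smoothing correlates neighbouring bins, so
significance tests on region averages use unsmoothed fields.

## Tip tracking

EB-mediated rate profiles in the co-moving tip frame: an exponential comet
`κ(x) = lattice + (tip − lattice)·e^{(x−x_edge)/ℓ}` for `x ≤ x_edge`, zero
beyond the tip, for both binding (enhanced at the tip) and unbinding
(reduced at the tip).  The shipped parameter file
`eb_tip_params_synthetic.yaml` is a constructed, order-of-magnitude
realistic example (comet 100 nm, binding 50/5 s⁻¹ tip/lattice, unbinding
10/50 s⁻¹, `v_MT` 50 nm/s) — replace it with measured rates for
quantitative work.  A cargo *tip-tracks* when the drift generated by
binding/unbinding can counter-balance the growth velocity, i.e. when the
full `S₁(x)` (frame term included) has a stable zero behind the tip;
`scan_tip_tracking` classifies a `(N, 2L)` grid this way with either the
mean-field engine (edge-aware surrogate `P_b`) or Gillespie ensembles.
With the synthetic parameters the drive rises with `N` and plateaus around
`N ≈ 6–8`, grows ≈ quadratically with cargo size for small cargo, and the
force estimate `F = k_BT·v_eff/D_eff` near the stable point is of order
0.01–1 pN at 310 K — an order below single-motor stall forces.

## What the synthetic scenarios do and do not show

The test scenarios (uniform rates; the central high-binding-rate bump;
substrate edges; the synthetic EB comet; the 2D radial bump) exercise
every qualitative regime of the model: pure diffusion with two-timescale
structure, drift toward high-affinity regions, edge mechanics, processive
tip tracking, and the 2D vector-field decomposition.  They do not
emulate: leg–leg exclusion or cooperativity, finite leg-diffusion
timescales (time-dependent shape factors), measured EB kinetics,
microtubule-lattice discreteness, or experimental localization noise.
Passing tests therefore demonstrate internal consistency of the
event-level model with its coarse-grainings under the stated assumptions,
not agreement with any particular experimental data set.

## Problem sizes

Default test ensembles are 10³–2×10⁴ trajectories (the corresponding
published-scale figures use 10⁴–2.5×10⁵); statistical assertions use
estimator-derived standard errors, so they are scale-aware.  Mean-field
tables use grids of 121–256 points with spacing ≤ L/10.
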