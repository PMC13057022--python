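# Methods

## Model

The dendritic tree is represented as a soma-rooted list of compartments
(`CompartmentTree`): each compartment has a parent, a length (µm) and a tip
coordinate; the soma is a single root compartment.  SWC reconstructions are
collapsed so that all soma samples become one root and axon subtrees are
dropped — the model describes dendritic cargo, and there are no abundance
measurements for soma or axon, so the soma acts only as a pass-through node
with floor-level demand and no labelled protein of its own.

Two pools live on the tree.  Belt-bound cargo `u_i` moves between
neighbouring compartments with forward rate `a` (away from soma) and
backward rate `b`, and detaches irreversibly with rate `c_i` into the
synaptic pool `u*_i`, which degrades with rate `d_i`.  Degradation acts on
the synaptic pool only — belt-bound protein is assumed protected — and
reattachment of synaptic protein onto the belt is represented by a rate
that is fixed at zero in all analyses.  The joint system is linear and
time-invariant: `d[u; u*]/dt = M [u; u*]`, with the transport block nearly
tridiagonal (each branch point adds one off-diagonal pair per child) and
column sums equal to `-c` (cargo leaves the belt only by detachment).

Local synaptic demand is a raw per-window value (dimensionless, the scale
fixed by the fitted `Ctau` and `dvB`); per compartment it is inherited from
the window, floored at `1e-7` and normalised to the demand distribution
`ũ*` (sums to 1).  Rates follow from demand as in the README equations.
Only the ratio `b/a` per edge is constrained by demand matching; the sum is
a free speed scale set to `a + b = k_traffic` per edge, default
`k_traffic = 1e-2 s⁻¹`.  That default keeps trafficking four orders of
magnitude faster than the fitted detachment/degradation scale (~1e-6 s⁻¹),
so the belt stays in quasi-steady state, while remaining demand-independent
and bounded.  `k_traffic` is treated as fixed, not fitted: the data
constrain the ratio structure, not the absolute belt speed, and the
published parameter sets do not include a speed scale.

## Units and integration

Time is in seconds internally (`Day 7 = 604 800 s`); half-lives are
reported in days (`t½ = ln 2 / d / 86 400`).  Because the system is LTI,
the default integrator is dense matrix-exponential propagation
(`scipy.linalg.expm` per time step), exact to machine precision and fast
enough (~5 ms for the 61-compartment, 122-state reference cable) to sit in
the optimiser's inner loop.  An independent `BDF` route (rtol 1e-8,
atol 1e-12, analytic Jacobian) is kept for cross-checks; tests require the
two routes and the closed-form two-pool solution to agree to ≤1e-6
relative.  Tiny negative values from roundoff (below `100·atol`) are
clamped to zero.

## Window mapping and normalisation

Experimental windows are mapped onto compartments by nearest distance from
the soma: signed distance along a configurable axis (default +Z apical,
−Z basal — the hippocampal-layer convention) or path distance along the
dendrite for geometries without a natural axis.  Ties go to the more distal
window; compartments beyond the outermost window clamp to it.  After
mapping, every compartment carries a label (the soma its own fixed label).

A window value `V_seg` is a window total; its per-compartment share
`x_i = V_seg/(L_seg Σ V_seg)` is therefore the within-window mean density.
Initial conditions split the normalised Day-0 profile `x̃` into
`u0 = mProp·x̃` and `u*0 = (1−mProp)·x̃`.  The Day-7 target is
`ỹ_i = y_i/((1−mProp) Σ y_i)` with `y_i = T_seg/(L_seg Σ V_seg)`, and the
model quantity compared against it is the identically normalised synaptic
pool `p̂_i = p^f7_i/((1−mProp) Σ p^f7)`.  This pairing is the package's
normalisation convention: both sides sum to `1/(1−mProp)`, and it is the
unique choice under which data generated by the forward model yields zero
cost at the generating parameters (measured puncta are proportional to the
synaptic pool, so the experiment's arbitrary intensity scale must cancel on
both sides).  The fit objective is the plain summed squared difference;
the SD-weighted χ² is computed as a diagnostic only (it requires nonzero
per-window SDs, which noiseless synthetic data lack).

The apparent per-window half-life is `aT½ = Δt·ln 2 / ln(D0/D7)` — the
unique value consistent with reading each window's decline as isolated
exponential decay.  Windows that gained protein return NaN with a warning,
since growth contradicts the pure-decay premise.

## Fitting

The hybrid schedule is PSO → GA → Nelder–Mead: swarm exploration
(inertia 0.72, cognitive/social 1.49, velocities clamped to the box), a
real-coded GA seeded with the swarm's best points (tournament selection
k = 3, BLX-0.5 blend crossover p = 0.9, Gaussian mutation σ = 5 % of the
bound range at gene rate 0.2, elitism 1), with the incumbent polished by
Nelder–Mead every 10 generations for 100 iterations, plus a final polish.
Population sizes are `N_PSO = max(15, 5·N_par)` and `N_GA = 2·N_par`
floored at 6 (the formula's literal value of 2 for a single-parameter refit
cannot sustain tournament selection).  Rate-like parameters (Ctau, dvA,
dvB, demands) are searched in log10 space and the bounded ratios (F, mProp)
in logit space, since plausible values span up to eighteen decades.
Nelder–Mead runs unconstrained in the transformed space with candidates
clipped to the box inside the objective, and its result is only accepted if
it improves the incumbent, so polish can never worsen the best point.

One master seed drives everything; PSO and GA draw from independently
spawned substreams, making fits bit-reproducible for fixed config and
data.  The full published schedule (50 PSO rounds, 2000 GA rounds) is the
default `FitConfig` budget; tests, examples and the acceptance script use a
reduced budget (10 PSO / 100 GA rounds, same structure) on reduced
morphologies — with one or two free parameters on a smooth noiseless
objective, the reduced budget already converges to the global minimum to
optimiser precision.

Three standard model versions mirror the published fits: (1) one demand
per anatomical region plus one global degradation rate (7 free parameters
on a 3-region layout), (2) per-region demand and degradation (9), and
(3) per-window demand with the linear degradation model `d = dvA +
dvB·demand` (25 on a 20-window layout).  Age transfer re-fits only the
degradation parameters with everything else frozen at the base fit.

## Synthetic data generator

The generator emulates the windowed pulse-chase design: a soma-rooted
morphology (cable, binary tree, or apical/basal with windows on both sides
of the soma), 10–20 axial windows, a demand profile (uniform, U-shaped
like CA1 stratum radiatum, or a rising-then-dipping monotone profile like
the dentate-gyrus sections), Day-0 window values proportional to the
time-0 synaptic pool (`(1−mProp)·x̃`, with `x̃ ∝ demand` — the assumption
that measured density correlates with local demand), and Day-7 values
obtained by forward simulation at the truth parameters, aggregated per
window.  Noise is multiplicative Gaussian with fractional SD `noise_sd`,
truncated at zero — an imaging-style noise law chosen because the
experiments report only per-window SDs, not a noise model; the SD column
stores `noise_sd ×` the noiseless value.

What the generator does *not* emulate: optical point-spread, puncta
segmentation, labelling chemistry, within-window heterogeneity of demand,
and any Day-0 measurement noise.  Passing recovery tests therefore show
that the inference machinery is correct and well-conditioned under the
model's own assumptions, not that real imaging data satisfy those
assumptions.

A known conditioning property: because windows inherit one value for all
member compartments, the cost has an aggregation floor set by within-window
variation of the simulated pool.  On coarse geometries (few windows, few
compartments per window) this floor can bias shallow parameters — on a
4-window cable the single-parameter `mProp` minimum sits ~15 % off truth —
while the 20-window × 3-compartment reference layout recovers `mProp` and
`F` to ≲0.1 %.  Recovery experiments should use window counts comparable
to the experimental designs (10–20).

## Numerical choices and edge cases

- Demand floor `1e-7` (the smallest fitted demand value) avoids zero-rate
  transport bottlenecks at zero-demand windows.
- Detachment `0/0` (F = 1 with zero demand) is defined as 0 with a warning.
- Discretization splits each topological branch into
  `⌈length/max_len⌉` equal pieces (the granule-cell convention uses
  `max_len = 3.7 µm`), conserving total cable length exactly.
- Equidistant window ties resolve to the more distal window,
  deterministically.
- SWC round-trips are bit-exact for the package's own dialect because
  compartment lengths are always recomputed from the written coordinates.
- All-zero Day-0 tables, empty tables, non-tree SWC graphs and
  out-of-domain parameters raise immediately with named errors.

## Limitations

- The model is deterministic mass-action; no stochastic single-motor or
  tug-of-war mechanics.
- Local (dendritic) translation is ignored by design: only protein labelled
  at Day 0 is tracked, with no synthesis influx.
- Reattachment is exposed as a parameter but fixed at zero, matching the
  analyses this package reproduces.
- Absolute trafficking speed is not identifiable from two-time-point window
  data; conclusions about `a`, `b` concern their ratios.
- The published per-window compartment counts of the original CA1
  reconstruction are not reproduced; counts always derive from the supplied
  morphology.
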