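# Methods

## The model

During early spinal-cord neurogenesis in zebrafish, neurons of a given
subtype first appear in a sparse, long-distance spacing pattern; later
neurons fill the gaps.  Differentiating neurons (and the Vsx1+
non-apical progenitors whose terminal divisions produce the recorded
daughter pairs) transiently extend two long basal protrusions — one
anterior, one posterior — that carry Delta and can activate Notch in
cells several diameters away.  This package implements the hypothesis
quantitatively: lateral inhibition delivered at a distance by transient
protrusions, on a 1D row of cells.

Per cell, with `N` and `D` the amounts of active Notch and Delta:

    dN/dt = R_N · D_in^k / (a + D_in^k) − μN
    dD/dt = R_D / (1 + b·N^h)           − ρD
    D_in  = α · Σ_soma D + β · Σ_protrusions D

and the per-step probability of committing to differentiation is a
decreasing Hill function of Notch,

    P_diff = p · N_th^q / (N_th^q + N^q).

A committed cell extends both arms at constant speed `l_max / T_ext`
(each arm's cap `l_max` is drawn independently from the genotype's
normal), so every arm caps at `T_ext`; arms then retract 1.7× faster
(wild type), and the cell differentiates — and leaves the signaling
pool — when both arms reach zero.  Committed cells send Delta but do
not receive (protrusions are assumed to carry negligible free receptor,
e.g. through cis-inhibition).  A protrusion contacts every cell whose
soma interval overlaps either arm segment; reception is soma-only.

Integration is explicit Euler at `dt = 0.01` with additive Gaussian
noise on both concentrations each step and clamping at zero.  The
protrusion phase clock is continuous, so cap crossings and completion
between Euler steps are honored exactly.

## Parameters

Geometry and kinetics are the measured values:

| quantity | value | note |
|---|---|---|
| cell diameter | Normal(11.10, 4.51) μm | redrawn if ≤ 1 μm |
| row size | 50 cells, 100 replicates | study scale |
| WT `l_max` | Normal(42.6, 20.2) μm | per arm, redrawn if ≤ 0.5 μm |
| WT `T_ext` | 0.05 time units | retraction in `T_ext/1.7` |
| lamc1 `l_max` | Normal(12.3, 4.7) μm | Laminin-depleted mutant |
| lamc1 `T_ext` | 0.05·(12.3/42.6)·1.4 ≈ 0.0202 | extension 1.4× slower per μm |
| lamc1 retraction | 1.1 × extension time | ≈ 2.6× slower than WT per μm |
| Euler `dt` | 0.01 | |

The signaling constants are not measured quantities; they were chosen
in the bistable mutual-inhibition regime and then calibrated so the
wild-type protrusion-only run reproduces the observed sequential-
spacing distribution (54.5 ± 18.9 μm), the calibration the original
sensitivity analysis shows is jointly constrained with the protrusion
kinetics.  Shipped defaults (`data/default_config.yaml`):

    R_N = 80   R_D = 20   a = 0.01   k = 2   b = 100   h = 2
    μ = 2      ρ = 20     p = 0.01   N_th = 0.2   q = 6
    noise_frac = 0.01

The structure matters more than the individual numbers:

* **Fast inhibition onset.** `R_N/μ = 40 ≫ N_th`, and trans-activation
  saturates at small incoming Delta (`a = 0.01` with the uninhibited
  Delta level `R_D/ρ = 1`), so a contacted progenitor's Notch crosses
  the trigger threshold within a fraction of one arm-extension time.
* **Slow release.** Notch decays at `μ = 2`, so a cell stays refractory
  for roughly `ln(N*/N_th)/μ ≈ 2.5` time units after its inhibitor
  retracts — a window long compared with the typical wait `dt/p = 1`
  of an uninhibited cell.  This asymmetry (instant lock, slow unlock)
  is what converts transient protrusions into a spacing pattern: the
  next event in time is almost always a cell outside every recent
  protrusion's reach.
* **Sharp trigger.** `q = 6` keeps partially inhibited cells (Notch in
  the decay tail) quiet, so the spacing boundary is crisp; `p = 0.01`
  keeps near-simultaneous commitments within one arm-extension time
  rare (those collisions are what put events closer than one
  protrusion length).

Per-step noise uses the diffusion (Euler–Maruyama) scaling, s.d.
`noise_frac · R · sqrt(dt)`: the realized fluctuation amplitude is then
independent of the step size and stays at the ~1% relative scale also
used for the initial conditions.  A per-step s.d. of `noise_frac · R`
would accumulate to ~30% of the level scale at `dt = 0.01` and erase
the Notch threshold.

Signaling modes map to the contact weights: `protrusion_only`
(α=0, β=1, the headline model), `soma_plus_protrusion`, `soma_only`.
For soma-involving modes the weight `soma_alpha` defaults to 0.5, the
patterning value found by scanning (α, p) for the soma-only mode: at
α = 1 the saturating trans-activation locks a homogeneous high-Notch
state in which no cell ever differentiates (a known limitation of this
parameterization), while α ≤ 0.2 is indistinguishable from random.  At
α = 0.5 the classic short-range alternation appears: sequential events
concentrate at 1–2 cell diameters and the mean spacing (~22–32 μm)
falls well below the random null (~41 μm).

## Time units

The simulation clock is bridged to hours by equating one wild-type
protrusion life cycle (`T_ext·(1 + 1/1.7) ≈ 0.0794` units) with the
measured 6.8 h in-vivo protrusion lifetime — the only timescale shared
by both domains (`HOURS_PER_TIME_UNIT ≈ 85.6`).  Time-conditioned
pairwise statistics (e.g. Δx given Δt < 1 h) use this bridge.

## Nulls and the analytic limit

The random-differentiation null permutes the order of differentiation
over a fresh row (uniformly random permutation; ordinal times) and
touches no signaling code, so its sequential-spacing distribution
(≈ 41.6 ± 21.5 μm at 100×50 with an 80 μm window) depends only on the
row geometry.  `randomize_event_table` builds per-stretch randomized
comparators from any event table, by default redrawing positions
uniformly over the stretch's observed span (a time-shuffling variant is
behind a flag; the spatial redraw is the default because the published
comparison is about spatial proportions).

The closed-form limiting model brackets the simulated behavior: if
protrusions inhibited instantaneously, the next event would be uniform
on `(d + l_max, L)` giving `E[dx] = (d+L)/2 + l_max/2`; if they were
too slow to matter, uniform on `(d, L)` giving `(d+L)/2 = 45 μm` at the
derivation's `d = 10`, `L = 80`.  Real tissue interpolates:
`dx̄ = 45 + φ·l̄max` with `φ ∈ [0, 0.5]`.  `infer_phi` inverts this
without clamping (out-of-band values are flagged); for the mutant's
printed means it gives φ = 0.024, and for the wild type's 54.0/42.6 it
gives 0.211 (the source text rounds this to 0.22; both raw values are
exposed).  The analytic default `d = 10 μm` follows the derivation even
though the simulator's empirical mean diameter is 11.10 μm; both are
configurable.

## Synthetic in-vivo recordings

`synthetic` generates event tables shaped like the Vsx1:GFP time-lapse
data: stretches of 250–400 μm watched for 8 h, events emitted as
daughter pairs (two records sharing a pair id and birth time, one
half-soma apart) at the study's density (presets: 34 stretches/~13
events each ≈ 449; 50 stretches/~14 each ≈ 721).  Two regimes supply
ground truth for validating the statistics end to end: `random`
(uniform positions and times) and `inhibition`, a Matérn-style
spatiotemporal thinning that rejects candidates within
`inhibition_range` μm of any event active within `refractory_time` h.
The thinning generator is deliberately independent of the mechanistic
simulator, so the two give separate routes to the same statistics.

What the generator does **not** emulate: GFP intensity time courses,
imaging noise, cell migration, left/right anatomical correlations, or
any density gradient along the cord.  Tests passing on these tables
therefore validate the statistics pipeline and the qualitative
spacing signatures, not the biology of any particular recording.

## Statistics

All statistics operate on event tables (`stretch_id`, `cell_id`,
`position_um`, `time`, `genotype`, `pair_id`).  Daughter-pair records
are collapsed to one analysis event at the pair midpoint and shared
birth time before anything else — the unit of observation is the pair.
Residual exact time ties are broken by position order.

* `sequential_dx`: |Δposition| between consecutive-in-time events
  within a stretch, retained iff ≤ the 80 μm window (a transition that
  jumps farther contributes nothing; there is no searching onward).
* `proportion_within`: fraction of consecutive transitions ≤ 42.6 μm
  (the mean wild-type protrusion length), pooled and per stretch.
* `pairwise_dxdt` / `spearman_rho`: all unordered within-stretch pairs;
  rank correlation with average-rank ties.  For simulated data the
  correlation is evaluated on pairs within the 80 μm analysis window,
  the same spatial restriction applied to the sequential statistics;
  without it the many long-range uncorrelated pairs dilute ρ by half.
* `conditional_dx_distribution`, `binned_mean_dt`,
  `estimate_inhibition_range`: the Δt-conditioned spacing distribution
  and the mean-Δt-per-10-μm-bin curve, from which the spatial reach of
  inhibition is read as the initial contiguous run of elevated bins.
* `ks_compare`: two-sample Kolmogorov–Smirnov on raw dx values.

## Numerical and degenerate-input choices

* Negative concentrations are clamped to zero after every step.
* Diameters ≤ 1 μm and arm caps ≤ 0.5 μm are redrawn (this lifts the
  sampled mean ~1% and narrows the s.d. slightly; visible as the
  random-null mean sitting ~0.7 μm above 40.9).
* Replicate seeds are spawned from the master seed via numpy
  `SeedSequence`, so experiments are reproducible and replicates
  independent.
* A replicate that has not finished within `max_steps` (10⁶) Euler
  steps aborts with the last differentiation time — the guard that
  catches deadlocked parameter sets (e.g. soma-only at α = 1).
* Stretches with fewer than two events yield empty summaries with a
  warning, not errors.

## Known limitations

* The magnitude of the pairwise rank correlation for the short-
  protrusion genotype is weaker here (≈ −0.05) than the source's
  −0.12: with a 12.3 μm reach, few within-window pairs fall inside the
  inhibited range.  The sign, significance, and the reduced spatial
  range of the coupling are reproduced.
* The wild-type spacing histogram is flat-topped between ~50 μm and the
  80 μm window edge rather than declining after a 60 μm peak; the mode
  bin varies between 50–80 μm across seeds.
* Soma-only signaling at full weight (α = 1) deadlocks under this
  parameterization (see above); the checker peak at α = 0.5 sits at
  1–2 cell diameters rather than ~3.
* The 1D row has open ends; cells at the boundary have fewer potential
  inhibitors, a minor effect at the 80 μm analysis scale.
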