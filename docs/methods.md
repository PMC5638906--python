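# Methods

## Model

The network is a spatially localized mean-field model: one excitatory and
one inhibitory population with threshold-linear rate dynamics and
Tsodyks–Markram short-term plasticity (STP) on all four recurrent
connections. The full state is 10-dimensional (2 rates + 4 × (x, u)).
Times are in seconds, rates in Hz; gains G_E = G_I = 1, so the absolute
synaptic efficacies J_E, J_I carry all developmental scaling of connection
strength.

Assumptions worth making explicit:

- The transfer function is rectified: f(h) = max(0, h − θ). This keeps
  rates non-negative and makes the origin (the "rest state") an exact fixed
  point whenever θ > 0 and external drive is absent. Parameter sets with
  θ ≤ 0 are rejected by `rest_state`.
- STP parameters depend only on the presynaptic population (as in the stage
  table), yet the implementation keeps all four (x, u) pairs. This leaves
  room for connection-specific STP later; the equivalence with the reduced
  6-D formulation under shared parameters is enforced by a test oracle to
  1e−9.
- External inputs default to zero: the developmental rise in background
  activity is folded into the stage thresholds θ_E, θ_I rather than
  modelled as a separate drive.
- Degenerate parameters (τ ≤ 0, U outside (0, 1], negative J) are rejected
  at construction rather than handled downstream.

## Stage parameters

`data/stages.json` holds the full parameter table for P3, P10, P14 and P20
(units: s for every time constant, Hz for thresholds, dimensionless U and
J). `load_stage` returns these values exactly; anything modified
(substitutions, blockades) is relabelled `custom` or suffixed so a registry
label always implies registry values.

## Perturbation protocols

Two perturbation types exist and are deliberately kept distinct:

- **Standard impulse protocol** (`run_impulse_protocol`, default): a
  rectangular external pulse e_E = 30 Hz lasting 1 ms delivered at t = 0
  while the network rests. Through the rate equation a pulse of width w
  increments the E rate by ≈ (30 − θ_E)(1 − e^{−w/τ_E}), i.e. ~0.7 Hz at P3
  down the stage ladder to ~2.9 Hz at P20 — a small, threshold-crossing
  kick whose effective size co-varies with the maturation of τ_E. The
  1-ms width is the package's convention for "a single-shock, delta-like
  stimulus"; it is what all stage-comparison, blockade and substitution
  results use.
- **Rate reset** (`apply_impulse`, `mode="reset"`): the E (or I) rate is
  set to a value instantaneously with STP untouched. This is the
  convention for perturbation-domain maps, where the initial condition
  itself is the object of study.

## Cluster detection

A cluster is a regenerative network spike. On a trajectory with a
perturbation marker:

- onset = perturbation time; baseline = summed activity A_sum = E_r + I_r
  just before it (the injected pulse window is excluded from the peak
  search);
- a cluster exists when the peak exceeds baseline + ε_det (0.5 Hz) *and*
  the post-pulse activity is not a pure monotone decay (this separates a
  real burst from the passive decay of the direct input response, e.g.
  under glutamatergic blockade);
- termination = the first time after the peak at which A_sum enters the
  ε_term band around the terminal fixed point's A_sum, with ε_term = 1 Hz.
  The terminal fixed point is read off the trajectory's end: the origin for
  mono-stable clusters, the spontaneous attractor for bi-stable ones.

ε_term was calibrated once against the intact P3 duration (~330 ms) under
the standard protocol and then frozen; every other duration (stages,
blockades, substitutions) is a prediction under the same convention.
First-entry (rather than a sustained-dwell window) is used because the
approach onto the P14 attractor spirals: the activity first touches the
attractor's neighbourhood at the end of the burst proper, then undershoots
and creeps back over ~1 s. The first touch is what a duration read off a
rate trace corresponds to.

`PS_net_amp = ω (A_sum_peak − A_sum_baseline)` with ω = 1; ω only rescales.

## Fixed points and stability

Steady states satisfy the reduced 2-D system in which every STP variable
takes its rate-conditioned steady state u*(A) = U(1 + τ_f A)/(1 + U τ_f A),
x*(A) = 1/(1 + u* τ_r A). The finder polishes roots of that system from a
25 × 25 seed grid on [0, 10]² Hz plus the origin (scipy hybr), merges
duplicates closer than 1e−3 Hz, lifts each root to the full 10-D state and
verifies |rhs| < 1e−8 before classifying. Quasi-nullclines are sampled by
bracketed bisection along both grid directions (near-vertical and
near-horizontal stretches need different scan axes), and the axis branches
created by the rectifier are tagged separately.

Stability is read from the analytic Jacobian of the declared system (10-D
full or 2-D frozen). Eigenvalues with |Re λ| ≤ 1e−10 flag the point
marginal; a fixed point on the rectifier kink (|h − θ| < 1e−9) is flagged
non-smooth, handled with the active-side one-sided derivative, and its
verdict marked provisional.

## Operating regimes and domain maps

Every plane point (E_r, I_r) is treated as a potential operating point with
STP at steady state. Criterion A/B examines the excitatory subsystem —
E_r together with (x_EE, u_EE), inhibition clamped — and criterion C the
full 10-D spectrum. ISN = A ∧ C, Non-ISN = B ∧ C, otherwise unstable;
marginal spectra fall to unstable. Including the recurrent excitatory STP
in the subsystem matters: synaptic depression alone can stabilize the
excitatory side, which is exactly the mechanism that terminates bursts. A
rates-only variant is available behind `include_stp_in_subsystem=False`
for comparison. A behavioural oracle (clamped-inhibition integration from
a 1e−3 Hz offset) cross-checks the spectral criterion A on random points.

On the active side the linearization contains neither thresholds nor
external inputs, so domain maps are exactly θ-invariant. Points with a
zero rate are linearized on the silent side of the rectifier for that
population (a zero-rate steady state generically sits below threshold),
which places the origin and the whole E_r = 0 axis in the Non-ISN domain
and the low-rate part of the I_r = 0 branch in the unstable domain.

Maps default to a 201 × 201 lattice on [0, 10]² Hz (the lower-left corner
is the rest state); areas (AOD) are cell-count × cell-area, and the three
areas partition the box exactly. AOD drift under grid doubling is below 1%
of the box area; analyses that only need orderings (stage comparisons,
substitution rankings) use 101 × 101 for speed.

## Frozen-efficacy analyses

`freeze_at` captures J·u·x per connection at any trajectory time. The
frozen 2-D system exposes the transient unstable fixed point that sits
near the rest state while synapses are recovered, confines the rest
state's attraction domain (the "amplification-threshold", estimated by
bisection along rays from the origin to 1e−3 Hz), and runs away without
bound for threshold-crossing perturbations — integration stops at a 1e6 Hz
guard and flags the trajectory.

## Synthetic inputs

The noise generator emulates sparse, discrete spontaneous events
(retinal-wave / thalamic-like drive): Poisson event times (seeded,
reproducible), brief rectangular pulses of configurable amplitude. It is
*not* a fitted model of any recorded input statistics — event rate,
amplitude and width are illustrative knobs. The statistics helper drives
the network over a long horizon (default study condition: rate 0.25 Hz,
30 Hz × 1 ms events, 150 s — chosen so that inter-event intervals straddle
the seconds-scale recovery time of immature excitatory synapses) and
returns per-event sizes and preceding quiet intervals. What these runs
show is the recovery-limited size variability mechanism; they say nothing
about the spatial statistics of real cluster activity, which a mean-field
model cannot represent.

## Substitution experiments

`run_substitution_experiment` replaces named parameter subsets of a base
stage (default P10) with donor values (default P20), then re-measures the
burst size (standard impulse protocol, so the stimulus convention is
identical for every hybrid network) and the ISN/unstable area ratio.
`ratio_γ = 100 ϖ (γ_res − γ_base)/(γ_donor − γ_base)` with ϖ = −1 for the
size metric and +1 for the area ratio, so the full parameter set maps to
−100% and +100% by construction. θ substitutions change ratio_AOD by
exactly 0 (θ-invariance above). The reverse experiment is the same call
with stages swapped.

## Numerical choices

- Integrator: LSODA, rtol 1e−8 / atol 1e−10, dense output; spans are split
  at input discontinuities so each segment is smooth. Identical calls are
  bit-identical. Cluster sizes shift by < 0.1% under tolerance halving.
- Default protocol horizon 3 s (covers the longest burst with margin);
  metric resampling at 0.05 ms.
- Root-finder trial points are clamped before entering the STP steady-state
  formulas to keep wild intermediate iterates finite.
- Bisection tolerances: 1e−3 Hz for attraction-domain boundaries.

## Known limitations

- Mean-field rates only: no spiking, no temporal-sparseness measures, no
  spatial propagation, no adaptation currents.
- The threshold-linear transfer has a kink; stability verdicts exactly on
  the kink are provisional by construction.
- GABAergic transmission is inhibitory at the network level at all stages;
  a sign-reversed (network-excitatory GABA) variant is not modelled.
- The noise model is illustrative (see above); quantitative comparisons to
  recorded event statistics are out of scope.
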