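# Methods

## The model

`thalcort` integrates a five-population neural mass model of the
cortico-thalamic loop. Each variable is the mean activity of one
population: cortical pyramidal cells (PY), fast inhibitory interneurons
(IN1, GABA_A-like), slow inhibitory interneurons (IN2, GABA_B-like),
thalamocortical relay cells (TC) and the reticular nucleus (RE). The
right-hand side of each equation is an input constant ε plus linear decay
plus sigmoid-coupled inputs, all scaled by a rate factor τ; the thalamic
populations use a linear activation s(x) = αx + β instead of the sigmoid,
a simplification that keeps the thalamic subsystem analytically mild
without changing the cortical phenomenology.

Assumptions worth keeping in mind:

* Populations are homogeneous and space is ignored — one ODE per
  population, no propagation delays.
* The sigmoid steepness ν = 2.5·10⁵ makes f(x) nearly a step; cortical
  populations are effectively on/off with a narrow graded band.
* IN2 is two orders of magnitude slower than IN1 (τ₃ = 0.13 vs
  τ₂ = 32.5). The slow inhibition sculpts the wave component of the
  spike-wave cycle.
* The system is dissipative and all couplings are bounded (sigmoid in
  (0,1)), so trajectories cannot blow up; the integrator still checks
  finiteness each step.

## Parameters that matter

All quantities are dimensionless except time (seconds). The two couplings
studied most are the thalamus→cortex drive k₄ and the cortex→thalamus
drive k₁₀ (defaults 1 and 3: the bistable operating point). The outputs of
IN2 are k₃ (to PY) and k₆ (to IN1); the outputs of IN1 are k₂ (to PY) and
k₈ (to IN2).

When an experiment "strengthens IN2" or "strengthens IN1" it scales both
of that population's output couplings together. The sweep machinery
expresses this with tied axes — `"k3+k6"` or `"k2+k8"` — which set every
named coupling to the common swept value. This tying is load-bearing: the
inhibition-induced SWD onset and the five-regime disinhibition sequence
only occur when a population's outputs move together; varying k₆ or k₈
alone leaves the attractor unchanged over the relevant ranges.

## Stimulation

A stimulus event perturbs the cortical variables PY and IN1 only. The
default mode is a state jump: `direction × magnitude` is added to both
variables at the first grid point at or after the event time, modelling a
brief pulse as an instantaneous displacement in state space. A
rectangular-pulse mode (additive current on the derivatives over a finite
duration, default 0.05 s) is available, but at the magnitudes of interest
it displaces the state by only ~0.015 and cannot switch attractors, which
is why the jump convention is the default. Direction is fixed negative;
scans vary magnitude only.

The two-pulse protocol uses the reference timings: initiation at t = 20 s,
termination at t = 35 s, 50 s total. Termination is phase-sensitive, so
these timings are explicit configuration and are logged with every map.

## Simulation and analysis defaults

* RK4 at dt = 1 ms; default runs 20 s with the first 5 s discarded.
* All analyses operate on the cortical mean (PY + IN1)/2.
* Dominant frequency: plain FFT periodogram of the mean-subtracted,
  untapered window; the peak over (0, Nyquist]. Windows of at least 5 s
  give ≤ 0.2 Hz resolution. Steady windows (variance below 1e−12) report
  0 Hz.
* Extrema: three-point comparison after collapsing plateaus of equal
  consecutive samples.
* Regime boundaries (onset bisections, pulse thresholds) use 50 s runs and
  classify the final 10 s. Near onsets the excitable transients last
  beyond 15 s, and a 20 s run misreads them as sustained oscillation: the
  background/SWD boundary on the cortex→thalamus drive reads 3.21 with
  20 s runs but converges to 3.29 for every run length of 30 s and above.

## The firing-state classifier

A stationary window is labelled by the decision rule:

1. peak-to-peak amplitude < `amp_tol` (1e−3) → SATURATED, split into LOW
   vs HIGH by mean level against `level_threshold` (0.33);
2. otherwise dominant frequency ≥ `tonic_freq_min` (10 Hz) → TONIC;
3. otherwise, inside the 1–5 Hz band: ≥ 2 local maxima per dominant period
   → SWD (spike plus wave), exactly 1 → CLONIC;
4. anything else → UNCLASSIFIED, with diagnostics, never a silent guess.

Maxima per cycle is the count of stable local maxima divided by (window
length × dominant frequency), rounded; maxima-value clusters (5% of
amplitude gap tolerance) are also reported.

`level_threshold` = 0.33 was calibrated once against the model's measured
saturated levels: the background state sits near 0.18 and the
high-saturated states between 0.49 and 0.53, so any cut between ~0.2 and
~0.45 works and 0.33 sits comfortably between the clusters. The 10 Hz
tonic bound exploits the empty band between the ~3 Hz discharges and the
~15 Hz tonic rhythm.

## Sweeps, maps and ramps

1-D scans run either from fixed initial conditions or with inherited
initial conditions (the end state of each run seeds the next, walking the
grid up or down); forward and backward inherited scans differ exactly on
the bistable windows. 2-D maps classify every cell without stimulation
and re-run the background cells with the initiation pulse to separate
stimulus-induced from spontaneous SWD.

Ramps integrate one long run while a parameter follows a linear schedule
(the RK4 stages use the schedule value interpolated within each step, so a
constant schedule is bit-identical to a fixed-parameter run). The default
replica ramps k₄ over 200 s (rate 0.01/s). Sliding 5 s windows stepped by
1 s are classified after removing each window's linear trend — a drifting
equilibrium is still a saturated state — and label runs shorter than 5
windows are treated as transitional and dropped before transition timings
are reported. The slow passage through a subcritical Hopf delays
oscillation onset on downward ramps, which compresses the clonic stretch
to a few windows; transition *timings* on ramps are therefore reported
but only their ordering is treated as meaningful.

## Continuation and bifurcation detection

Equilibria are found by damped Newton iteration on the vector field
(numerical Jacobian, central differences with step 1e−6·(1+|x|); step
halved while the residual would grow; residual max-norm < 1e−10 or
failure after 100 iterations). An analytic Jacobian (f′ = ln ν · f(1−f),
s′ = α) backs the eigenvalue computations and agrees with the finite
differences to ~1e−6.

Branches are continued by seeding each Newton solve with the previous
equilibrium. Hopf points are located by bisecting the sign change of the
leading *complex* eigenpair's real part (a real leading eigenvalue is
reported as non-Hopf); the super/subcritical kind is decided by a probe
simulation just past the crossing on the unstable side — a settled cycle
with amplitude below 0.05 indicates a supercritical branch, a jump to a
large-amplitude attractor a subcritical one.

Folds of limit cycles are located without Floquet machinery, by
simulation: a state on the cycle is carried along the parameter axis and
its persistence (settled amplitude > `amp_tol` after a 30 s run) is
bisected. Two conventions matter:

* The tracked state is never moved more than `max_step` = 0.001 per
  settle run. Near the fold the cycle's basin shrinks, and larger
  parameter jumps drop the inherited state outside it, reporting the fold
  early (by ~0.002 on the second fold of the reference axis).
* The reported value is the bracket endpoint at which the cycle has
  *ceased* to exist, mirroring the smallest-succeeding-magnitude
  convention used by the pulse-threshold bisection.

Bistable intervals combine the equilibrium branch (stability from the
eigenvalues) with bidirectional inherited-state sweeps of the cycle;
cells where a stable equilibrium coexists with an oscillatory attractor
are grouped, and every reported interval is verified by explicit
coexistence of two distinct labels at its midpoint.

## Determinism

No random number generation exists anywhere in the package. Fixed-step
RK4, deterministic protocols and deterministic analyses make every
output — trajectories, scans, maps, thresholds — byte-identical across
reruns; the run writer records checksums so this can be audited.

## Problem sizes

Single runs are 20–50 s of simulated time (2·10⁴–5·10⁴ RK4 steps,
milliseconds of wall time with the compiled kernel). The two-pulse plane
quantities are the heaviest analyses (roughly 10³ fifty-second runs
each); the full reproduction script completes in well under a minute on
one CPU.

## Known limitations

* No noise: stochastic fluctuations, which matter for spontaneous seizure
  onset and termination statistics in real recordings, are out of scope.
* No spatial structure or delays; "cortex" is a single point.
* The classifier's frequency bands leave 5–10 Hz unlabelled by design;
  regimes there (none occur at the shipped presets) surface as
  UNCLASSIFIED.
* Pulse-threshold boundaries depend at the 0.005–0.01 level on the
  stimulus convention and the classification window; the conventions
  above are fixed and logged, and boundary values should be read with
  that granularity in mind.
* Unstable limit cycles are not tracked; subcritical branches are
  characterised indirectly (coexistence plus fold location).
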