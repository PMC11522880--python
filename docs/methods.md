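# Methods

`herdsim` simulates a first-person herding task — a constant-speed herder
agent (HA) corrals autonomous target agents (TAs, "virtual cows") into a
circular containment zone on a fenced plane — and provides the analysis
stack around it: heuristic target-selection policies and their inference
from trajectory logs, trajectory-similarity metrics, and a staged protocol
for fitting the herder model to reference trajectories.

## Task environment

The arena is a 120 m x 90 m fenced field with the containment zone (radius
4 m) at the origin. A herder influences a target when their distance is at
most `d_i = 10 m`. Targets are unit-mass particles obeying

    x_ddot = alpha_r (x - y) / ||x - y||^2 - beta x_dot + wall(x)

with `alpha_r = 20 m^2/s^2` active only inside the influence radius,
drag `beta = 0.2 1/s` acting unconditionally, and the herder-repulsion
magnitude clamped at 30 N. Walls push targets inward with 4 N while in
contact (normals summing at corners). Wall contact is inelastic: the
outward velocity component is absorbed, otherwise a pinned target would
integrate unbounded speed while its position is clamped to the field. The
herder itself is simply projected back onto the field.

## Herder model

The herder moves at fixed speed `v0 = 5 m/s`; only its heading `phi`
(measured from the +y axis, clockwise positive, wrapped to (-180, 180])
is controlled:

    phi_ddot = -b phi_dot + psi_G + psi_T + sum_i psi_Oi

- `psi_G = -kg (phi - theta_G) (exp(-c1 dc) + c2)` attracts the heading to
  the **offset goal** `x_c = x + c x/||x||`, the point `c = 8.5 m` radially
  beyond the target as seen from the zone centre ("behind" the target).
  The `c2` floor keeps the attraction alive at long range.
- `psi_T = zeta * ko (phi - theta_T) exp(-c3 |phi - theta_T|) exp(-c4 d)`
  repels the heading from the targeted TA while the herder is off the
  target-zone line; the gate
  `zeta = 1 - logistic(epsilon - angle(x, y))` (angle subtended at the zone
  centre, `epsilon = 5 deg`) switches the repulsion off smoothly as the
  herder aligns behind the target, producing the approach -> corral phase
  transition.
- `psi_C`-form terms (`ko (phi - theta) exp(-c5 |.|) exp(-c6 d)`) repel the
  heading from point obstacles: the zone centre always, plus every
  non-targeted TA in multi-target trials (1 + (N_TAs - 1) terms).

Angular differences enter the couplings in radians (the gains are
radian-scale; fitted ranges like 25-60 and 150-250 only make sense then).
The `zeta` argument is evaluated in **degrees**: in radians the logistic
would vary by under 3% across the whole relevant range, flattening the
phase transition; on the degree scale `zeta(0deg) ~ 0.007`,
`zeta(5deg) = 0.5`, `zeta(15deg) ~ 1`, which is the sharp gate the model
needs. The scale is exposed as `zeta_gain`.

### Default parameters

`b = 3.5 1/s`, `c = 8.5 m`, `epsilon = 5 deg` and `v0 = 5 m/s` are task
constants. The gains and decay shapes have no published point values; the
shipped defaults are the midpoints of the fitting search ranges
(`kg = 42.5`, `ko = 200`, `c1 = c2 = c3 = c5 = c6 = 0.5`) and are meant to
be replaced by `fitting.staged_fit` output. The exception is
`c4 = 0.15 1/m`, the distance decay of the target-repulsion term, for which
no fitting range exists either: a midpoint-style `c4 = 0.5` makes
`exp(-c4 d)` ~ 0.007 at the 10 m influence radius, so the repulsion that
must hold the herder outside the ring until it is aligned would be inert
exactly where it has to act, and rollouts pierce the ring ~10 deg off-line
and ~16 m from the offset goal. With `c4 = 0.15` the term is comparable to
`psi_G` at `d ~ d_i`, and generic rollouts show the documented behaviour:
median herder-target angle at first influence ~1.5 deg, first influence
~2 m from the offset goal. `ko_obstacle` optionally decouples the obstacle
gain from the target gain (they share `ko` by default).

### Integration

Fixed-step RK4 at `dt = 0.02 s` (the 50 Hz logging rate) on the state
(x, y, phi, phi_dot), holding targets constant within the step; targets
take a semi-implicit Euler step against the herder position at the start of
the step (operator splitting). The RK4 position increment is rescaled to
exactly `v0 dt` — constant forward speed is a model constraint, not a
numerical target. In rollouts the offset goal is clamped into the field:
for a target near a fence the nominal offset lies outside the walls and an
unreachable goal deadlocks the herder.

### Containment latch

In the original game a single-target trial ends when the target is inside
the zone *and* slower than 0.1 m/s, which requires the (human) herder to
stop pushing and let it coast in. The model herder cannot stop: parked at
the 8.5 m offset it influences a resting target forever (8.5 < 10), and a
continuously pushed target always crosses the zone too fast — under the
`rest` latch, model rollouts bat the target back and forth indefinitely
(0/50 generic trials terminate). The simulator therefore latches a target
as corralled when it **enters** the zone, freezing it (`latch_mode="entry"`,
the default); the inside-and-at-rest predicate then holds trivially, and
multi-target trials proceed target by target. `latch_mode="rest"` restores
the literal game rule for studying the non-terminating dynamics.

### Known limitations of the default parameterization

On generic uniform initial conditions: ~6% of single-target rollouts end in
a wall standoff (target resting against a fence; the `zeta ~ 1` repulsion
holds the herder at the influence ring and the clamped offset goal cannot
be reached "behind" the target); transient `zeta` excursions above 0.05
occur after first influence in most trials — near the zone the subtended
angle inflates geometrically (a lateral wobble `delta` at target radius `r`
reads as an angle ~ `delta/r`) — and occasional chaotic trials cross the
containment disc, since `psi_C` vanishes exactly when heading straight at
the centre (odd coupling). These are properties of the model, not of the
integrator; they are measured, not hidden, by the acceptance checks.

## Target-selection policies

Twenty policies combine a timing mode — *initial* (whole order fixed by the
start state), *successive* (re-decide at each engagement, i.e. first entry
into the current target's influence radius), *dynamic* (re-decide when the
current target is corralled) — with a criterion (linear distance from
herder, angular distance from herder subtended at the zone centre, linear
distance from zone; the last only as an initial policy), a direction
(closest/furthest), and an optional collinear-clustering rule: targets
whose pairwise subtended angle is below a threshold (default 18.9 deg,
single-linkage closure) form a cluster, the cluster is ranked by its best
member under the base criterion, and within a cluster the member furthest
from the zone takes precedence (it can be driven through its cluster-mates
"en route"). The headline *successive collinear angle* (SCA) policy is
successive + closest angle + clustering. Ties everywhere break to the
lower target id, deterministically.

"Engagement time" is operationalized as the first sample at which the
herder influences the chosen target — the only selection-related event a
log instruments. `predict_order` replays a log's decision instants: each
next choice is evaluated at the *predicted* current target's engagement
(successive) or containment (dynamic) sample, using the herder position and
the remaining targets' positions recorded there, with clusters recomputed
at every decision instant. The simulator's locked selector uses the same
single-decision function at the same instants, so simulator-generated logs
are exactly recoverable by the scorer. An `online` mode re-evaluates SCA
every 0.25 s without locking, matching how the policy is coupled to the
movement model for behavioural simulation; the locked mode is the one used
for policy-identification round trips.

## Policy scoring

Non-exclusive scoring credits a policy once per trial whose full predicted
permutation equals the observed order (no partial credit). Exclusive
classification ranks policies by non-exclusive accuracy (ties broken by
catalogue order) and assigns each trial to the first matching policy, else
"other"; the resulting proportions partition the trials. The threshold
sweep re-scores SCA over a grid of clustering thresholds, optionally per
participant.

## Trajectory metrics

Paths are resampled to 1000 points uniformly in normalized sample index
(linear interpolation, endpoints preserved). A cohort's mean trajectory is
the pointwise mean of resampled paths; the 90% confidence tube is a single
scalar radius, 1.645 x the sample s.d. (ddof = 1) of point-to-mean
distances pooled over paths and indices. DTW uses the classic symmetric
dynamic program with Euclidean local cost; the normalized variant divides
by the optimal warping-path length (diagonal-preferring backtrack). The
implementation is numba-jitted with a pure-NumPy fallback and is verified
in tests against exhaustive warping-path enumeration. Coverage is the
percentage of path points within the tube radius of the mean *polyline*
(nearest-segment distance, index-free, because simulated and recorded
paths have different time supports). Trace maps square-root-transform the
per-5 m-bin occupancy counts of a cohort; the binary mask keeps bins with
heat > 10 (the threshold applies to the transformed value, so a bin needs
more than 100 points — several trajectories — to survive). A trajectory's
binary trace is the fraction of its distinct visited bins that are
mask-true; its weighted trace is the mean heat over those bins.

## Model parametrization

`staged_fit` minimizes the normalized DTW distance between rollouts and
reference paths with bound-constrained SLSQP, in three stages: the decay
shapes (c1, c2, c3, c4; starts and bounds (0.1, 0.9) — c3 and c4 have no
published ranges and are treated like c1, c2), then the gains (kg, ko;
starts (35, 50) x (150, 220), bounds (25, 60) x (150, 250)), then the
obstacle shapes (c5, c6; (0.1, 1)). Each stage runs 10 uniform random
starts per reference trial, takes the per-trial median over starts and
carries the across-trial median forward; `b`, `c`, `epsilon` and `v0` stay
fixed. Objective rollouts start from the reference's initial positions
with the heading set to the reference path's start tangent, estimated as
the chord between the centroids of resampled points [0, 50) and [50, 150)
— block averaging keeps the estimate usable under temporally correlated
recording noise, which overwhelms a short two-point chord. Reference
rollouts are trimmed of their final 20% before comparison (a simulated
herder ends a trial circling in place). Failures inside the objective
return a large penalty (1e4) instead of aborting a stage. The fitting
landscape is mildly noisy (DTW kinks), so SLSQP runs in range-scaled
coordinates (each stage parameter mapped to [0, 1]) with a 2%-of-range
finite-difference step and `ftol = 1e-4`; scipy's step size is absolute,
and an unscaled step that suits the decay shapes is far too small for the
gains.

Two further points shape recovery experiments (synthetic references
generated from known parameters). First, `make_reference` iterates the
initial heading to a fixed point of the tangent estimator, so the
objective's rollout reproduces the generating rollout exactly and the
objective is zero at the generating parameters. Second,
`reference_smoothness` screens conditions for route bifurcations: near an
ambiguous start (herder almost aligned with the target-zone line) a small
gain change flips which way the herder swings, the objective jumps by
metres, and staged medians land badly — such conditions are excluded, as
ambiguous and outlier trials are excluded by hand in this kind of study.
Even then, recovery of the gains is limited by a structural degeneracy:
the repulsion terms enter as products `ko * exp(-c4 d)` (and
`ko * exp(-c6 d)`), so reference geometries that probe only a narrow band
of herder-target distances can be fit equally well with gains tens of
percent off and decay constants compensating. Across development seeds,
gain recovery within 10% held for most but not all reference sets; the
degeneracy, not optimizer failure, drives the exceptions (trajectory match
stays at DTW ~ 0.3 m).

## Synthetic data

`sample_initial_conditions` places agents uniformly on the field outside
the containment disc with >= 2 m mutual separation; targets additionally
start >= 12 m from the herder so trials begin outside the influence radius,
as in the game's pre-specified starts. `heading="offset"` points the
initial heading at the first target's offset goal (transient-free starts,
used for parametrization references where the path tangent is fed back
into the simulation). `pseudo_human_cohort` emulates between-participant
variability by multiplying the model gains and decays with independent
N(1, 0.05) factors and adding moving-average-filtered (0.5 s window)
Gaussian positional noise, rescaled to the requested pointwise s.d.
(default 1 m) and clipped to the field. What it does *not* emulate:
stop-and-go motion, visual scanning, discrete keyboard kinematics — so
green tests certify the pipeline's arithmetic on plausible cohorts, not
fidelity to real human data. `policy_labelled_logs` samples multi-target
configurations, keeps only trials whose observed chase order equals the
generating policy's prediction (accidental en-route influence can break
this), and accumulates trials until every competing policy mispredicts at
least one kept trial, making the generator uniquely identifiable.
`threshold_probe_trials` places target pairs just below/above a chosen
clustering threshold with the angularly nearer member also nearer the zone,
so the selection order flips exactly at the threshold.

## Problem sizes

Default analysis sizes keep a full run on one core comfortable: 50-trial
behavioural suites, 5-8 trials per policy round-trip, cohorts of 8-24,
3 reference trials with 10 optimizer starts per stage for fitting, and
200-point resampling inside the fitting objective (1000 points elsewhere).

## Known limitations

- The entry latch is a modelling choice, not the game's literal rule; see
  above.
- Policy inference assumes complete logs (every target influenced;
  containment events for dynamic policies).
- The DTW normalization (path-length division) and the trace-map
  normalization (division by distinct visited bins) are documented
  choices among plausible readings.
- The herder never stops; comparisons with stop-and-go recordings should
  use DTW, which is what the fitting objective does.
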