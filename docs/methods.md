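# Methods

`reflexgait` simulates planar, muscle-driven locomotion controlled purely by
spinal-reflex-like feedback, and implements a pipeline that turns that
controller into a continuous speed controller.  This note documents the
models, the numerical choices, and what the shipped fixtures do and do not
demonstrate.

## Reflex controller

The stimulation of muscle *i* is

    u_i(t) = clip( c_i + Σ_{j∈R_i} [ κL_ij · L̃_j(t−Δt_j) + κF_ij · F̃_j(t−Δt_j) ] ),

with `L̃` the contractile-element (CE) length normalized by optimal fiber
length, `F̃` the tendon force normalized by maximum isometric force, and
`Δt_j` a conduction delay assigned by neural path length (hip 5 ms, thigh
10 ms, shank 20 ms; configurable).  `R_i` contains the homonymous pathway
(j = i) and the antagonistic pathways from muscles crossing a shared joint.
For the standard nine-muscle leg (GLU, ILI, RF, HAM, BF, VAS, GAS, TA, SOL)
the network uses 11 mutual antagonist pairs, hence 9 + 22 = 31 connections
and 31 + 31 + 9 = 71 free parameters.  One parameter set drives both legs;
each leg reads its own sensors.  Stimulation is clipped to [0, 1] (a
physical bound; the affine law itself is unbounded).

The canonical encoding — all length gains in connection order, then all
force gains, then the per-muscle offsets — is used everywhere: CSV columns,
optimizer coordinates, PCA loadings.

## Musculotendon units

Each actuator is a Hill-type unit: Gaussian active force–length (width
0.56), hyperbolic force–velocity (curvature 5, eccentric plateau 1.5),
series tendon with quadratic force–strain reaching `f_max` at 4 % strain,
and first-order activation dynamics (τ_act 10 ms, τ_deact 40 ms unless a
muscle overrides them).  The CE velocity is obtained each step by inverting
the force–velocity relation so CE and tendon forces balance.  Two numerical
regularizations matter:

- eccentric lengthening is capped at `v_max`; the raw inversion diverges as
  the force ratio approaches the plateau, which otherwise lets the CE jump
  to its excursion rail in one step and decouples force from activation;
- with a slack tendon the CE tracks the just-taut length (rate-limited by
  `v_max`) instead of shortening at full speed, which both prevents runaway
  shortening at zero load and provides passive re-lengthening.

CE excursion is railed to [0.2, 2.0]·l_opt; a deactivated muscle therefore
yields under load instead of acting as a rigid strut.
`mtu_relax` advances an *unloaded* unit (free-swinging limb): activation
dynamics continue, the CE returns toward optimal length, force is zero.

## Planar plant

The humanoid is a seven-segment planar linkage (torso with lumped head and
arms, femur/tibia/foot per leg) with hinge hips, knees and ankles, built on
a small recursive Newton–Euler engine for planar trees (floating base as a
px–py–rz chain of massless links; mass matrix by unit-acceleration columns;
semi-implicit Euler at dt = 0.5 ms).  Default anthropometry scales standard
segment fractions to 74.5 kg and 1.80 m; all constants live in
`PlantConfig` and can be replaced wholesale.  Muscle paths use constant
moment arms per spanned joint (RF, HAM, GAS are biarticular), so path
length is affine in the joint angles; joint angles are zero at standing
with flexion (ankle: dorsiflexion) positive.  Ground contact acts at a heel
and a toe point per foot: Hunt–Crossley normal force
`k·d^1.5·(1 + b·ḋ)` (clipped non-adhesive) and tanh-regularized Coulomb
friction saturating at μ·normal.

Verified physics: a passive single-pendulum reduction drifts < 0.1 % in
total energy over 10 s at the default step (measured ≈ 0.02 %); the
small-oscillation period matches the analytic value to 0.5 %; trajectories
are bit-deterministic; mirroring state and controls left↔right mirrors the
trajectory to machine precision initially (asserted < 1e-6 over 0.05 s —
beyond that, floating-point summation-order noise is amplified by contact
chaos, which is a property of the dynamics, not an asymmetry).  The package
makes no claim of stable biped *gait*: that requires a large optimization
campaign from a stable seed controller, which is out of desk scale.

## Episodes and gait metrics

An episode integrates plant + controller until `t_max` (default 50 s) or
until the model CoM drops below 0.9 m; an episode is *stable* iff it
reaches `t_max`.  For stable episodes the actual speed `v_act` is the mean
horizontal CoM velocity after a transient (10 s full model, 3 s toy) — the
averaging window is a package choice.  The completed distance selects, at
the episode end, the segment CoM nearest the origin under speed
maximization (trailing segment) and farthest under minimization, and
returns its horizontal displacement.  Gait classification is operational:
running iff periodic flight phases occur, walking iff one foot is always
grounded with alternating single/double support, `none` below four complete
strides.  Stride events come from the vertical contact force with a
20 N / 10 N hysteresis.  The active parameter vector can be swapped at
prescribed times mid-episode; nothing else (joint state, activations,
sensor buffers) is reset — online modulation and gait transitions reuse the
identical loop, so a constant schedule is bit-identical to an offline
episode.

## Speed optimization and harvesting

The cost is `J = 100·J_vel + 100·J_fall` with `J_vel = ±d_sim/t_max`
(+ for minimization, − for maximization) and `J_fall = 1 − t_sim/t_max`.
CMA-ES (in-package implementation of the standard (μ/μ_w, λ) strategy with
cumulative step-size adaptation) performs a local search around a stable
seed controller with initial step size σ₀ = 0.01 by default; termination
when the mean relative improvement of the best cost per iteration over the
trailing 500 iterations falls below 1e-5, with a generation cap as a safety
net.  Each generation's best candidate is re-simulated once,
deterministically; stable re-evaluations are harvested into a speed dataset
of (parameter vector, v_act) records.  Per direction the seed with the
largest harvested speed span is kept; the two harvests are merged, sorted
by speed and deduplicated.

## Key parameters and the speed-modulation function (SMF)

The merged dataset's 71 columns are z-scored (gains and offsets have
heterogeneous scales) and decomposed by PCA; the `n_key` parameters with
the largest absolute first-component loadings are the key parameters (ties
break to the lower canonical index; the largest-magnitude loading of each
component is made positive for determinism).  A restricted optimization
varies only the key entries; every other entry stays bit-equal to the seed
vector.

For each key parameter an ordinary least-squares polynomial of degree
`d_reg ∈ {1,2,3}` in actual speed is fitted (coefficients above the degree
are exactly zero; the regressor is `v_act` because that is what harvested
records carry).  `assemble(model, v_tgt)` evaluates the polynomials at the
target speed and copies the frozen seed values elsewhere; the default
pipeline setting is `n_key = 30`, `d_reg = 3` for the full network.  The
offline sweep runs one deterministic episode per grid point (default grid
0.5–3.5 m/s in 0.025 m/s steps, 121 points), records stability, achieved
speed and gait, and stores the stable target range in the model.

## Online modulation and transitions

Schedules start at the mid-range speed `v_start = v_min + (v_max−v_min)/2`
and hold it for a 20 s settle period.  Steps jump by `j·0.025` m/s
(j ≤ 25, either direction) at the settle time; ramps follow the triangle
wave `v_min + v_a·|((τ−T/4) mod T) − T/2|` with `τ = t − settle`,
`v_a = 0.05` m/s/s and period `T = 2(v_max−v_min)/v_a`, rising first.  The
time shift by the settle period makes the wave start at `v_start`; the
online runner samples-and-holds the target on a 1 s lattice, so ramps are
realized as 0.05 m/s increments.  The slowest and fastest stable sweep
targets are excluded when choosing the online range.  Transition plans swap
whole parameter vectors at fixed 10 s boundaries; the joint re-optimization
over the concatenated sets (142 or 284 dimensions) minimizes the fall
penalty alone, since survival is the objective of that experiment.

## Toy hopper fixture

The toy plant exists to exercise the entire pipeline in minutes with the
*same* muscle and controller code as the biped.  It is a point-mass body on
a massless telescoping leg with an extensor/flexor pair (2 homonymous + 2
antagonistic connections + 2 offsets = 10 parameters through the identical
codec).  Design choices, after exploring and rejecting a full planar SLIP
(whose massless-leg instant-reset idealization produced touchdown-preload,
vaulting and skimming artifacts):

- vertical dynamics are the classic one-dimensional muscle-driven hopper:
  in stance the leg length equals the body height, so contact engages with
  exactly zero force and no placement discontinuities exist;
- the stance force acts along a tilt fixed at touchdown,
  `θ = min(θ₀ + k_tilt·act_ext, θ_max)`, where `act_ext` is the extensor
  activation at landing — "extensor tone pushes the leg backward".  The
  extensor deactivates slowly (τ_deact 0.15 s), so the takeoff activation
  set by the force-feedback gain survives the flight;
- linear drag on the body balances the tilted push, giving a smooth,
  monotone map from the extensor homonymous force gain to forward speed
  over roughly gain ∈ [0.4, 1.9] (measured 1.81 → 2.72 m/s at 50 s
  horizon); the committed baseline (gain 1.0, extensor offset 0.2) hops
  indefinitely at ≈ 2.26 m/s;
- in flight the unloaded muscles relax via `mtu_relax` (without this, force
  feedback latches the tendon loaded against the leg's geometric stop);
- the toy's fall threshold is 0.9 m: active hopping keeps the body above
  ≈ 0.95 m while passive collapse settles near 0.897 m.

The toy uses the telescoping-leg ground interaction rather than the
biped's Hunt–Crossley point contact; muscle, controller, episode, optimizer,
PCA, regression and online machinery are shared unchanged.  The hopper
validates machinery only — its hops classify as "running" (flight phases),
nothing about it emulates human gait, and no toy number is comparable to a
human-scale result.

Synthetic parameter-vs-speed datasets provide exact ground truth for the
analysis stages: true-key columns follow committed cubic polynomials in
speed, all columns receive seeded Gaussian noise.  Noiseless datasets are
recovered by the SMF fit to < 1e-8; with noise at 10 % of the per-key
signal, PCA selection recovers a 5-key set in ≥ 95 % of 100 replicates.
Because the columns are standardized before PCA, a *single* varying column
is not identifiable from the correlation structure — key selection needs at
least two co-varying parameters, which harvested datasets always have.

## Desk-scale budgets

The end-to-end smoke (`pipeline_smoke`, also behind `reflexgait toybench
--smoke`) runs optimization (2 seeds × 2 directions, 12 generations,
population 6, σ₀ = 0.05 — the toy's 10 gains need a larger step than the
full model's 0.01 default to move measurably in so few generations),
harvesting, PCA with 4 keys, restricted optimization, a degree-2 SMF, an
offline sweep at 0.025 m/s resolution over the harvested range, and online
step and ramp runs, in ≈ 100 s on one CPU.  Episodes in the smoke are 10 s
at dt = 1 ms.

## Known limitations

- The biped ships as a validated plant, not a validated gait: no stable
  walking/running parameter set is included.
- Constant moment arms and planar dynamics are first-order simplifications;
  all constants are config-replaceable for users with better tables.
- `v_act` of hopping gaits carries a truncation jitter of order one hop
  length divided by the averaging window; the toy sweep tolerates ≈ 6 %
  local monotonicity violations from this source.
- The gait classifier is operational (flight-phase / support-pattern based)
  and makes no contact with kinematic gait definitions beyond that.
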