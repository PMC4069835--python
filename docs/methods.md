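# Methods

This note records the modeling assumptions, parameter choices and numerical
decisions behind `propriosim`, and what the synthetic-limb tests do and do
not establish about real limbs.

## Problem setting

The input is a uniform-rate stream of 7 joint angles [rad] and 4 joint
torques [N·m] about the elbow-flexion, forearm-pronation, wrist-flexion and
wrist-deviation axes (joints 4–7 in the package's fixed numbering; joints
1–3 are the shoulder). The output, per sample and per muscle, is the muscle
state (normalized fiber length, velocity, force, activation) and three
ensemble-average afferent rates in pulses per second: spindle primary (Ia),
spindle secondary (II) and GTO. Ensemble averages — not single-receptor
spike trains — are the intended stimulation currency; no spike sampling is
performed. Shoulder torques are not resolved: the modeled muscle set spans
too few shoulder actuators, but the shoulder angles still enter the
geometry of the biarticular elbow muscles, which is why they are carried.

## Surrogate geometry

Each muscle's musculotendon length, and each moment arm about a resolved
joint, is a polynomial over the muscle's *spanned joints only*: all
monomials with per-variable exponent ≤ 3 and total degree ≤ 3. Restricting
to spanned joints keeps the basis small (4 terms for a uniarticular muscle,
20 for a three-joint muscle) where a full 7-variable tensor basis would be
both ill-conditioned and pointless. Fitting is ordinary least squares via
numpy's SVD-based `lstsq`; rank deficiency falls back to the minimum-norm
solution with a warning, and a table with fewer rows than basis terms is an
error. The default sweep is an 11-point full-factorial grid per spanned
joint with held-out validation on the 10-point midpoint grid.

Sign convention: `R_mj = −∂L^MT/∂q_j`, so a muscle that shortens as a joint
angle grows has a positive moment arm and contributes positive torque about
that axis. This makes the torque-balance rows of the optimization
self-consistent without per-muscle sign tables.

Angles are radians everywhere inside the package; the trajectory reader
accepts degrees behind an explicit flag and converts by π/180 on read.

## Muscle mechanics

The Hill model is dimensionless and shared by all muscles; a muscle is four
numbers (F^M_o, L^M_o, L^T_s, v^M_max = 7·L^M_o/s) plus curve constants.
Curve forms and defaults (conventional values from the muscle-modeling
literature, all configurable):

* active force-length: Gaussian `exp(−(L̄−1)²/γ)`, γ = 0.45;
* passive: `(exp(k_PE(L̄−1)/ε₀)−1)/(exp(k_PE)−1)` above L̄ = 1, zero below,
  k_PE = 5, ε₀ = 0.6;
* force-velocity: Hill hyperbola `(1+v̄)/(1−v̄/a_f)` on shortening
  (a_f = 0.25, clamped to 0 below v̄ = −1) and a saturating exponential
  eccentric branch reaching F_len = 1.4, C¹-continuous at v̄ = 0.

The tendon is in series elastically but never integrated: its loaded length
is the equilibrium cubic of normalized force, and the fiber length is the
path length minus the loaded tendon length. The cubic's four coefficients
are fixed model constants, not fitting parameters.

**Fiber-velocity estimate.** The per-step state update feeds the *previous*
sample's force into the tendon cubic (the only way to break the
force/length circularity in a single-pass loop). Differencing the resulting
tendon-corrected fiber length to get velocity closes a feedback loop
through the force-velocity curve whose gain scales like
`a·f_v′(0)·(L^T_s/L^M_o)·L̄^T′/(v̄_max·dt)`; for short-fibered,
long-tendoned muscles (wrist flexors: L^T_s/L^M_o ≈ 4) at 120 Hz this
exceeds 1 and the recursion oscillates violently. The package therefore
uses the backward difference of the musculotendon *path* length scaled by
1/v_max — a rigid-tendon velocity estimate, standard practice in
computed-muscle-control-style pipelines — which depends only on kinematics
and is unconditionally stable. The first sample's velocity is zero, and the
initial force is the passive-force/tendon-length fixed point at the initial
pose with zero activation.

## Static optimization

Per sample, with gains `g_mj = f_l·f_v·R_mj·F^M_o` and passive torques
removed from the target, the LP is

    min  β + w·Σ a_m          (w = 0.01)
    s.t. a_m − β ≤ 0,  Σ_m g_mj a_m = T*_j − passive_j,
         max(0, a_min) ≤ a_m ≤ min(1, a_max),  0 ≤ β ≤ 1,

solved with scipy's HiGHS backend. The summed-activation term removes the
criterion's indifference below the maximum; its weight is exposed as
`sum_weight`. The per-step bounds come from the first-order activation ODE
with excitation pinned at 0 or 1 over one timestep, clamped into [0, 1].

Infeasibility (torque beyond capacity, or a degenerate joint whose gains
are all zero against a nonzero target) triggers a re-solve with per-joint
slack variables penalized at 10³: the stream degrades gracefully with a
reported residual instead of halting, which is the right failure mode for a
prosthesis. Muscles with no moment about any resolved joint are excluded
from the programme and held at their lower bound.

LP degeneracy can make the activation split among identical parallel
branches arbitrary; the branch-sharing postprocess replaces activations
within configured anatomical groups (default: the three triceps heads) by
their gain-weighted mean, which preserves the group torque exactly when the
branches act about the same joints, and reverts with a warning otherwise.

## Spindle model

Each of bag1, bag2 and chain is a polar region (spring K^pr, nonlinear
damping `β·C·(L−R−L^sr_o)·|L̇|^0.3·sign(L̇)`) in series with a much stiffer
sensory region (K^sr). Because K^sr ≫ K^pr, imposed stretch is taken up by
the polar region, and the fiber tension has the closed form

    T = M·L̈ + β·C·(L−R−L^sr_o)·|L̇|^0.3·sign(L̇) + K^pr·(L−L^pr_o−L^sr_o) + Γ,

clamped at zero below slack. Sensory stretch is `T/K^sr + L^sr_o`; each
fiber fires `G·max(0, stretch − threshold)`; Ia combines bag1 against
bag2+chain by partial occlusion (`larger + S·smaller`, S = 0.156); II sums
bag2/chain terms mixing sensory stretch (weight X = 0.7) with a
polar-stretch term. Fusimotor drive maps to steady intrafusal tension
through a saturating γ²/(γ²+γ_c²) curve and raises the damping coefficient;
dynamic drive routes to bag1, static drive to bag2 and chain (standard
spindle physiology). First-order fusimotor kinetics are out of scope; the
pipeline default is zero fusimotor drive (passive-motion signals).

The fiber constants shipped as defaults are transcribed from the cited
intrafusal-fiber modeling literature and are labeled as such in the config;
every test invariant holds for any physically valid set (K^sr ≫ K^pr > 0,
C_L ≥ C_S > 0, G ≥ 0), so the package's correctness claims do not rest on
the transcription. Gains are divided by 15 (`gain_scale` config) to move
the fusimotor-induced rate ceiling from the ~150 pps feline range to the
< 30 pps observed in humans; a guard flag prevents double application. For
muscles physiologically confined away from optimal length, rest/threshold
recalibration translates the polar rest length, the damping slack length
and the polar secondary threshold by a common offset so the spindle is
silent at a chosen neutral pose, leaving the response to stretch relative
to neutral unchanged.

Standalone trajectory analysis differentiates the length series by central
differences (one-sided at the ends); the streaming pipeline uses strictly
causal backward differences so that truncating the input reproduces a
prefix of the output exactly.

**Reference ODE.** The oracle integrates the un-approximated second-order
tension dynamics — the system the equilibrium expression is the fixed point
of — by explicit Euler: `(M/K^sr)·T̈ = T_eq(L, L̇ − Ṫ/K^sr, L̈) − T`, where
the sensory end's own motion feeds back into the polar velocity. Its
natural frequency is √(K^sr/M) ≈ 230 rad/s, so explicit Euler needs steps
of order 0.1–1 ms and provably diverges at the 120 Hz limb rate; divergence
is detected and raised. Two consequences shape the oracle tests: on holds
the ODE tracks the equilibrium exactly when started from rest (the
fixed-point property), but after movement its final approach is algebraic,
not exponential — the |L̇|^0.3 damping gives `error ~ t^(−3/7)` — so
post-ramp agreement is asserted as a time-averaged discrepancy relative to
peak Ia (≤ 10%) rather than a tight absolute tolerance. This slow
adaptation tail is a property of the fiber model, not a solver artifact.

## GTO model

The static stage uses normalized force so one parameter set serves all
muscles: `k₃ = F^M_o,soleus/k₂ = 25.8 N / 4 N = 6.45`, and `k₁ = 25 pps`
rescales the feline rate ceiling to human microneurographic observations
(the feline parameterization, k₁ = 60 pps on absolute force, remains
available). The dynamic stage is the classic phasic transfer function with
unit DC gain and high-frequency gain 1.7, discretized by the bilinear
transform `s = k(z−1)/(z+1)` with `k = ω₀/tan(ω₀/2f_s)` so the discrete
response matches the continuous one exactly at 6 Hz. At 1 kHz this
reproduces the canonical published coefficients to 5 decimal places. When
the trajectory rate differs from 1 kHz the filter is *redesigned* at the
actual rate (the design is a few lines; resampling the signal would add
latency and state). Each muscle owns one biquad, initialized at the steady
response to the initial force so there is no artificial startup transient.
The non-negativity clamp sits outside the filter state, which evolves
unclamped to preserve the linearity of the dynamic stage.

## Synthetic limb

The fixture generator defines muscles whose length is base length plus
per-joint terms: constant-pulley (`−r·q`, constant moment arm) or
sinusoidal wrap (`A·sin(q+φ)`, moment arm `−A·cos(q+φ)`). Sinusoids are
deliberately outside the cubic polynomial class so the surrogate fit is a
genuine approximation test (held-out R² ≈ 0.9998 at the default 11-point
grids, not exactly 1). Wrap phases for resolved joints keep `q+φ` inside
(−π/2, π/2) over the joint range so every muscle's moment arm keeps one
sign — flexors stay flexors — which real elbow/wrist muscles satisfy over
ordinary workspaces and which branch averaging relies on. The default
roster names 17 elbow/wrist muscles (biceps long/short, brachialis,
brachioradialis, three triceps heads, anconeus, two pronators, supinator,
FCR, FCU, ECRL, ECRB, ECU, EDCI), with the biceps heads and long triceps
also spanning a shoulder angle so shoulder pose modulates elbow muscle
lengths. Tendon slack lengths are set so fibers sit at optimal length at
the neutral pose; maximum forces and optimal fiber lengths are typical
upper-limb magnitudes (elbow ≈ 600 N / 10 cm, wrist ≈ 250 N / 6 cm).

What the synthetic limb does *not* emulate: true 3D wrapping geometry and
its moment-arm zero crossings at extreme poses, inertial/gravitational
torque generation (torques are inputs by design), muscle-specific curve
constants, and measured human afferent data. Passing the recovery and
oracle tests therefore establishes internal consistency and approximation
quality of the pipeline, not fidelity to any individual's limb.

## Problem sizes and tolerances

Default test/validation sizes: 11-point fitting grids with midpoint
held-out validation; LP oracle on 25 random instances of ≤ 3 muscles and
≤ 2 joints, with exhaustive grid search at 10⁻³ step over the free
activation dimensions (the equality-constrained remainder is solved
linearly); spindle oracle runs of a few seconds at 120 Hz with 0.05–0.1 ms
inner Euler steps; end-to-end recovery on a 30 s, 120 Hz multi-tone
trajectory (3601 samples) with four prescribed activation envelopes
(≤ 0.4). Solver tolerance for torque equalities is HiGHS's default;
residuals are reported per joint and asserted below 10⁻⁶ N·m on optimal
samples. Determinism: all randomness flows through explicit
`numpy.random.default_rng(seed)` generators; identical inputs and config
give bit-identical outputs.

## Known limitations

* The equilibrium spindle lacks the initial firing burst seen in human
  recordings of rapid stretch; the underlying fiber model shows bursts only
  at much higher stretch velocities.
* Linear min-max optimization shares load poorly among many parallel
  branches (hence the branch-averaging postprocess) and is expected to
  degrade as joints and muscles are added.
* Activation-rate bounds approximate the nonlinear activation ODE by a
  one-step reachable interval; fast torque reversals at low sample rates
  can make a sample transiently infeasible, which surfaces as a relaxed
  sample with reported residual rather than an error.
* The spindle/GTO human rescalings (÷15, k₁ = 25) are ceiling-matching
  heuristics, not fits to human data.
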