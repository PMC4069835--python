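# propriosim

Real-time simulation of upper-limb proprioceptive afferent signals.

A proprioceptive neural prosthesis needs to convert what a prosthetic limb is
doing — its joint angles and joint torques — into the neural firing patterns
that an intact limb's mechanoreceptors would produce, fast enough to stream on
portable hardware. `propriosim` implements that processing chain for a
7-degree-of-freedom, 17-muscle model of the human arm (3 shoulder angles,
elbow flexion, forearm pronation, wrist flexion and deviation): it estimates
muscle lengths, moment arms, activations and forces from the joint stream, and
from those the ensemble-average firing rates of muscle-spindle primary (Ia)
and secondary (II) afferents and Golgi tendon organs (GTOs), in pulses per
second.

The package is aimed at neural-engineering and motor-control researchers who
need afferent-rate estimates from kinematic/kinetic recordings without running
a full 3D musculoskeletal simulation in the loop.

## The model

Every stage replaces an expensive standard computation with a cheap surrogate
whose error is quantified against an independent oracle:

* **Geometry.** Musculotendon length and moment arms are sparse cubic
  polynomial surfaces over the joint angles the muscle spans,
  `L^MT(q) = Σᵢ cᵢ Πⱼ qⱼ^eᵢⱼ` with exponents in 0–3, fitted by least squares
  to a sweep of the workspace. Moment arms obey the tendon-excursion relation
  `R_mj = −∂L^MT/∂q_j`.
* **Muscle.** A dimensionless Hill-type model (zero pennation): force
  `F = [a·f_l(L̄^M)·f_v(v̄^M) + f_p(L̄^M)]·F^M_o`, with the series-elastic
  tendon handled in equilibrium through a cubic fit to the tendon strain
  curve, `L̄^T = 0.04879 F̄³ − 0.1009 F̄² + 0.1003 F̄ + 1`, so no tendon ODE is
  integrated. `v^M_max = 7 L^M_o /s`.
* **Static optimization.** Muscle redundancy is resolved each sample by the
  min-max linear programme: minimize `β + 0.01 Σ a_m` subject to `a_m ≤ β`,
  torque balance about the elbow/wrist joints, and per-step activation bounds
  derived from first-order activation dynamics (τ_act = 15 ms,
  τ_deact = 50 ms). Infeasible samples are relaxed with penalized slack so a
  streaming application never halts.
* **Spindle.** Three intrafusal fiber types (bag1, bag2, chain) with the
  second-order tension dynamics replaced by their closed-form equilibrium
  (all stretch taken up by the compliant polar region), making the output
  step-size independent; Ia combines bag1 and bag2+chain through partial
  occlusion. Feline-fitted gains are divided by 15 to match human
  microneurographic rates. A full-ODE Euler reference implementation ships as
  the oracle.
* **GTO.** `R_NL = k₁ ln(k₃ F̄ + 1)` (k₁ = 25 pps human, k₃ = 25.8/4 = 6.45)
  followed by the phasic dynamics `H(s) = (1.7s² + 2.58s + 0.4)/(s² + 2.2s + 0.4)`
  discretized by the bilinear transform with 6 Hz prewarping.

A synthetic analytic limb (pulley and sinusoidal-wrap muscles with closed-form
lengths, moment arms and inverse-consistent torques) stands in for a 3D
musculoskeletal model, so the whole pipeline is testable end to end without
external data.

## Worked example

`python examples/full_pipeline_demo.py` generates a 5 s multi-tone motion on
the synthetic limb, computes the torques that four prescribed muscle
activations would produce, then feeds only angles and torques to the full
pipeline:

```
samples processed:        601 at 120 Hz
solver status:            {'optimal': 601}
max torque residual:      1.21e-12 N m
max min-max criterion:    0.149 (largest prescribed activation 0.357)
Ia range over all muscles: 0.0 .. 11.4 pps
GTO range over all muscles: 0.0 .. 26.4 pps
```

Every sample is solved to optimality: the measured torques are reproduced to
machine precision, and the largest activation the solver needs (β = 0.149) is
well below the largest activation that generated the data — the min-max
criterion spreads load across the redundant muscles. The Ia and GTO rows are
the afferent rates a stimulator would encode. The other examples print the
surrogate-fit quality per muscle (`fit_length_surfaces.py`), the
ramp-hold-release spindle protocol against the Euler reference
(`spindle_stretch_protocol.py`), and the GTO step response with its 1.7×
phasic overshoot (`gto_step_response.py`).

A thin CLI wraps the same machinery: `propriosim make-fixtures`,
`propriosim fit-surfaces`, `propriosim simulate`, `propriosim validate`.

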