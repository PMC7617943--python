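# forcematch

Generative modelling and hierarchical Bayesian analysis of **sensory
attenuation** in the force-matching task.

When you press on your own finger, the touch feels weaker than an
identical externally applied force. The force-matching task measures
this: a torque motor presses a target force *F*<sub>T</sub> onto a
passive finger, and the participant reproduces the sensation either by
pressing directly with the other hand (*direct* condition) or by driving
the motor with a slider or joystick (*indirect* condition). Healthy
participants overshoot substantially in the direct condition only — the
self-generated force is attenuated, so they press harder to match the
remembered sensation.

`forcematch` implements a complete computational treatment of this
paradigm for researchers in sensorimotor neuroscience and computational
psychiatry: closed-form trial-level models of the matching force,
synthetic cohort generation with known ground truth, hierarchical
Bayesian estimation with model comparison, posterior predictive checks,
and the descriptive regression/Bayes-factor analyses.

## The model

Both conditions share the same perceptual, memory (contraction bias
toward the session mean) and comparison noise, summarized per target
level by the indirect matching force
*F*<sub>I</sub> ~ N(*F̄*<sub>I</sub>, σ<sub>FI</sub>). Attenuation acts
only in the direct condition through a trial-to-trial attenuation factor
*K* ~ N(*K̄*, σ<sub>K</sub>):

* **subtractive** (fixed offset):  *F*<sub>D</sub> = *K* + *F*<sub>I</sub>, so
  *F̄*<sub>D</sub> = *K̄* + *F̄*<sub>I</sub>,
  σ<sub>FD</sub> = √(σ<sub>K</sub>² + σ<sub>FI</sub>²), skewness ≡ 0.
* **divisive** (attenuation proportional to intensity):
  *F*<sub>D</sub> = *K* · *F*<sub>I</sub>, a product of normals with
  *F̄*<sub>D</sub> = *K̄* *F̄*<sub>I</sub>,
  σ<sub>FD</sub> = √(*F̄*<sub>I</sub>²σ<sub>K</sub>² + (*K̄*² + σ<sub>K</sub>²)σ<sub>FI</sub>²)
  and skewness 6δ<sub>K</sub>δ<sub>FI</sub>/(1 + δ<sub>K</sub>² + δ<sub>FI</sub>²)<sup>3/2</sup>
  where δ = mean/SD. The product density has no closed form and is
  approximated by a skew-normal matched for mean, SD and skewness.

Two signatures separate the models: the divisive direct force grows
multiplicatively with the target and is positively skewed, and both
models predict **excess trial-to-trial variability** in the direct
condition because prediction noise (σ<sub>K</sub>) enters only there.
A divisive factor *K̄* maps to an attenuation fraction 1 − 1/*K̄* of the
self-generated sensation.

Per-participant parameters are tied by population-level hyperpriors and
estimated with an adaptive Metropolis-within-Gibbs sampler; models are
compared with DIC and summarized by posterior medians, highest-density
intervals and the 95%-HDI group-difference rule.

## Worked example

```python
import forcematch as fm

att = fm.AttenuationParams(mean_K=1.61, sd_K=0.152)
ind = fm.IndirectLevelParams(target_force=2.0, mean_FI=2.0, sd_FI=0.3)
print(fm.divisive_moments(att, ind))
print(f"attenuation: {fm.attenuation_fraction(1.61):.2f} "
      f"+/- {fm.attenuation_fraction_sd(1.61, 0.152):.2f}")
```

```
MomentTriple(mean=3.22, sd=0.5725245496919761, skew=0.21406933793583097)
attenuation: 0.38 +/- 0.06
```

A 2 N force reproduced directly comes out at 3.22 N on average — skewed
toward larger forces — and a mean factor of 1.61 means the self-generated
force is attenuated by 38% ± 6%.

The `examples/` directory holds one narrative script per capability
(closed-form moments, simulate + describe, hierarchical fit + DIC,
gain-manipulation study, posterior predictive check). For instance
`python examples/fit_hierarchical.py` prints:

```
divisive     pop mean_K median 1.547 (90% HDI [1.459, 1.632]), DIC 296.5, max pop R-hat 1.089
subtractive  pop mean_K median 1.167 (90% HDI [0.987, 1.331]), DIC 560.1, max pop R-hat 1.030
Delta DIC (subtractive - divisive) = 263.6  (> 0 favors divisive)
implied attenuation: 1 - 1/1.55 = 0.35 of the self-generated force
```

i.e. on a 10-participant cohort generated divisively with mean factor
1.6, the divisive fit recovers the factor and DIC identifies the
generating model decisively.

A thin CLI wraps the same pipeline
(`forcematch simulate | fit | describe | ppc | compare | report`):

```sh
forcematch simulate --preset study1 --n-participants 20 --seed 1 --out sim/
forcematch fit --data sim/trials.csv --model both --out fits/
```

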