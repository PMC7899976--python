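# msisim

Why does a repetitive, predictable ride make people less motion sick than
the same ride with randomised direction or timing, even when the physical
motion intensity is identical? Classical computational models of motion
sickness — which map head acceleration to motion sickness incidence (MSI)
through subjective-vertical-conflict (SVC) dynamics — cannot tell these
conditions apart, because they see only the acceleration signal.

`msisim` implements an SVC observer model coupled to an *online learner of
the exogenous motion dynamics*, for researchers in vestibular modelling,
vehicle comfort and VR sickness who want to simulate how motion
predictability shapes sickness. The next horizontal acceleration sample is
modelled as a nonlinear autoregressive function of the window of the last
`T_w = 10 s` of noisy samples, `y_t = f(x_t) + w`, and `f` is learned by
**recursive Gaussian process regression**: a squared-exponential GP prior is
tracked at `m` fixed location vectors `X`, each step producing a one-step
predictive mean μₜᵖ and variance Cₜᵖ via the gain row
`J_t = k(x_t, X) K(X,X)⁻¹`, followed by a Kalman-style posterior update from
the observed sample. The prediction enters the observer's internal model
weighted by its confidence,

    α̃_t = k_pr · μₜᵖ,   k_pr = c₁ · exp(−c₂ · Cₜᵖ),

reducing the conflict Δv between sensed and expected vertical — but only
when the motion is learnable. The conflict drives MSI through a Hill
saturation `(|Δv|/b)²/(1+(|Δv|/b)²)` and a slow second-order lag
`P/(τ_I s + 1)²`.

## Worked example

Simulate 60 s of the predictable condition with the learner:

```python
import numpy as np
from msisim import SessionSpec, generate_session, simulate

profile = generate_session(SessionSpec(condition="M_P", total_duration=60.0, seed=1))
result = simulate(profile, mode="C_GPR", seed=1)
steady = result.times >= 20.0
print(f"median predicted variance: {np.median(result.C_p[steady]):.3f}")
print(f"median prediction weight k_pr: {np.median(result.k_pr[steady]):.3f}")
print(f"MSI at 60 s: {result.final_msi:.4f} %")
```

prints

```
median predicted variance: 0.095
median prediction weight k_pr: 0.602
MSI at 60 s: 0.0210 %
```

After one movement cycle the learner predicts the periodic profile well:
the predictive variance settles below 0.3 (m/s²)² (median 0.095), so the
confidence weight sits near 0.6 and most of the upcoming acceleration is
cancelled inside the internal model, keeping the conflict — and the
accumulating MSI — small.

The full 3 × 2 experiment (motion conditions M_P / M_dU / M_tU crossed with
calculation conditions C_Control / C_GPR, 900 s sessions, 5 seeds per cell)
runs from the command line in about ten minutes:

```
msisim experiment --out runs/
```

```
condition      mode  n  msi_mean   msi_sd  msi_min  msi_max
      M_P C_Control  5  1.053723 0.000000 1.053723 1.053723
      M_P     C_GPR  5  1.065307 0.001001 1.063845 1.066451
     M_dU C_Control  5  1.058139 0.000470 1.057713 1.058882
     M_dU     C_GPR  5  1.902051 0.079508 1.823939 2.025221
     M_tU C_Control  5  1.033228 0.018466 1.005129 1.049814
     M_tU     C_GPR  5  2.311708 0.060813 2.210589 2.368356
```

Without learning (C_Control) the three motion conditions are
indistinguishable (the profiles are RMS-matched by construction). With
learning (C_GPR) the predictable condition yields roughly half the final
MSI of the direction- or timing-randomised conditions, which remain mutually
similar — the model reproduces the predictability effect reported in human
cart experiments.

`msisim generate-profile`, `msisim simulate` and `msisim summarize` expose
the individual stages; profiles and per-step traces
(`t, mu_p, C_p, error, k_pr, conflict_norm, msi`) are exchanged as CSV, run
settings as a YAML config (see `msisim experiment --help`).

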