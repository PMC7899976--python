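# Methods

`msisim` simulates the motion sickness accrued by a passively moved observer
and how that sickness depends on whether the motion pattern can be learned.
Two coupled components are involved: a vestibular observer model built on
subjective-vertical-conflict (SVC) theory, and an online learner that acquires
the dynamics of the exogenous motion and feeds its predictions into the
observer's internal model. This note records the model equations as
implemented, the parameters and their defaults, the synthetic motion
conditions, and the numerical and design choices that were genuinely open.

## Observer model of the sickness pathway

The sensory input is the gravito-inertial acceleration (GIA)

    alpha = a + g,

the sum of inertial acceleration and gravity, which the otoliths transduce
(modelled as an identity map: only low-frequency translational motion is
considered). The sensed vertical `v` is a first-order low-pass of the GIA
with time constant `tau`:

    dv/dt = (alpha - v) / tau.

A CNS internal model mirrors this pathway. Its state `alpha_bar` is the
internal estimate of the GIA, corrected by integrating the conflict through a
feedback gain:

    d(alpha_bar)/dt = K_fb * (v - v_hat),

and the expected vertical `v_hat` is produced by an internal low-pass
identical to the sensory one, driven by the internal GIA estimate plus the
predicted exogenous motion `alpha_tilde`:

    d(v_hat)/dt = (alpha_bar + alpha_tilde - v_hat) / tau.

The conflict `Delta v = v - v_hat` drives sickness through a saturating Hill
function of its Euclidean norm,

    h = (|Delta v|/b)^2 / (1 + (|Delta v|/b)^2),

followed by a critically damped second-order lag with DC gain `P` and a long
time constant,

    tau_I^2 m'' + 2 tau_I m' + m = P h,

whose output `m` is the motion sickness incidence (MSI), the percentage of a
population expected to vomit under the exposure. The full state is the
11-vector `xi = [v, v_hat, alpha_bar, m_dot, m]`; the model output is the
last component.

The internal wiring deserves a comment because only the block structure of
such observer models is standardised, not the ODEs. We chose the minimal
realisation consistent with an 11-dimensional state: the conflict is
integrated (gain `K_fb`) directly into the internal GIA estimate, the
internal low-pass equals the sensory one, and both otolith blocks are
identity. Initialisation is the zero-conflict rest state
`v = v_hat = alpha_bar = g`, `m = m_dot = 0`, which is an exact fixed point
of the dynamics in the absence of motion — simulated sickness is therefore
attributable entirely to the motion input.

### Observer parameters

| parameter | meaning | default | unit |
|---|---|---|---|
| `tau` | vertical-perception low-pass time constant | 2.0 | s |
| `tau_I` | MSI accumulation time constant | 720 | s |
| `K_fb` | conflict feedback gain | 5.0 | 1/s per (m/s²) |
| `b` | Hill half-saturation conflict | 0.5 | m/s² |
| `P` | MSI saturation (lag DC gain) | 85.0 | % |
| `c1` | maximum prediction weight | 0.8 | – |
| `c2` | prediction-weight decay per unit variance | 3.0 | (m/s²)⁻² |
| `k_pr_control` | fixed weight in the control condition | 0.5 | – |
| `g` | gravity, z-up head frame | (0, 0, 9.81) | m/s² |

These are the standard values for this model family; `c1`, `c2` follow the
source tradition of trial-and-error tuning of the confidence-weight law.

## Online learning of the exogenous motion

The horizontal exogenous acceleration is treated as a nonlinear
autoregressive (NAR) process: with `alpha_hat_t = alpha_t + n_t`
(`n_t ~ N(0, 1e-4)` sensor noise), the window
`x_t = [alpha_hat_{t-1}, ..., alpha_hat_{t-d}]` (newest first) of the
`d = T_w/dt = 1000` most recent samples (`T_w = 10 s`, `dt = 0.01 s`)
predicts the next sample through an unknown function `f`, learned under a GP
prior with squared-exponential kernel

    k(x_i, x_j) = sigma_f^2 exp(-1/2 (x_i-x_j)^T Lambda^{-1} (x_i-x_j)),
    Lambda = diag[lambda_i].

Rather than batch regression, the posterior over `f` at `m = 100` fixed
location vectors `X` is tracked recursively: at each step the gain row
`J_t = k(x_t, X) K(X,X)^{-1}` (computed through a cached Cholesky
factorisation) yields the predictive mean `J_t mu_f` and variance
`k(x_t,x_t) - J_t (k(X,x_t) - C_f J_t^T)`; the observed sample then updates
`(mu_f, C_f)` by the Kalman-style correction with innovation variance
`C_p + sigma_w^2`. When observed inputs lie in `X` the recursion is exact
(it reproduces the batch GP posterior; asserted to 1e-6 in the tests against
a dense reference implementation, itself cross-checked against
scikit-learn's batch GP).

The prediction enters the internal model weighted by its confidence,

    alpha_tilde = k_pr * mu_p,   k_pr = c1 exp(-c2 * C_p),

so an uncertain learner contributes nothing and a confident one contributes
up to `c1` of its predicted mean — an analogy with reliability-weighted
multisensory integration.

### Location vectors

The `m` location vectors are selected once by greedy max-min
(farthest-point) coverage of windows harvested from a noise-free predictable
session (64 s, every 4th window). The same `X` serves every simulated
condition, so between-condition differences arise from how well each
condition's windows are predicted, never from a per-condition basis. The
greedy sweep is deterministic (first pick: farthest from the candidate
centroid).

### Kernel hyperparameters and their calibration

The hyperparameters of the learner are not dictated by the model structure;
they were fixed once, as follows, and are exposed in the configuration:

- `sigma_f = 2.5 m/s²`: prior amplitude at the scale of the peak
  acceleration, so the prior predictive variance (6.25) makes the untrained
  learner maximally uncertain and `k_pr ~ 0`.
- `sigma_w = 0.01 m/s²`: matches the sensor-noise SD actually injected.
- `lambda = 270` (isotropic): calibrated once against the steady-state
  behaviour the coupled model is meant to exhibit on the predictable
  condition — predictive variance settling below 0.3 (m/s²)² within one
  pause of prediction onset and a steady prediction weight near 0.6. The
  lengthscale controls how far the posterior generalises between location
  vectors: squared distances between neighbouring 1000-dimensional windows
  of these pulse trains are O(10–100), so values below ~100 collapse the
  kernel off the basis (variance pinned at the prior) while values above
  ~1000 interpolate so aggressively that the steady weight saturates at
  `c1`. Within the usable band the steady weight varies smoothly
  (0.50 at lambda=200, 0.63 at 300) and 270 centres it at 0.60. The
  calibration used a 60 s predictable run and was frozen before the
  condition-contrast experiment was evaluated.

`jitter = 1e-8 * sigma_f^2` is added to the Gram diagonal; `C_f` is
re-symmetrised after each update; the predictive variance is clamped at zero
and clamping events are counted (none occur at the defaults — the jitter and
the max-min spacing of `X` keep the system well conditioned).

## Synthetic motion conditions

The generator emulates a cart moved back and forth on a horizontal track for
900 s with external vision blocked, repeating a single 8 s movement of
amplitude 9.0 m and peak acceleration 2.5 m/s², in three conditions:

- `M_P` (predictable): direction alternates, pauses fixed at 8 s;
- `M_dU` (unpredictable direction): timing as `M_P`, each direction drawn
  uniformly (same or opposite to the alternating schedule);
- `M_tU` (unpredictable timing): directions as `M_P`, pauses drawn uniformly
  from 4–12 s.

The movement waveform is a symmetric half-sine accelerate / coast /
decelerate pulse; the half-sine width `t_a` solves
`(2 A t_a / pi)(T - t_a) = amplitude` in closed form (`t_a = 0.784 s` at the
defaults), which satisfies the duration, peak and amplitude constraints
simultaneously and starts and ends at rest. Only the three printed
constraints pin the waveform; any smooth rest-to-rest pulse satisfying them
would serve.

Two choices make the conditions energy-matched, so the observer alone (no
learning) cannot distinguish them: all conditions use the identical pulse
samples (onsets snapped to the 0.01 s grid), and the `M_tU` pauses are
rescaled after drawing — clipping to [4, 12] s and redistributing the
residual — so each session's total pause budget equals the fixed-pause
schedule's. The RMS acceleration is then identical across conditions by
construction (the direction sign never affects squares). Sessions are
truncated/padded with zeros to exactly 900 s. Direction draws in `M_dU`
ignore cumulative cart position: the model consumes acceleration only, so a
track-length constraint would add bookkeeping without affecting any model
input.

What the generator does *not* emulate: vertical or rotational motion,
visual-scene input, vibration or actuator imperfections of a physical cart,
and any within-movement variability — every movement is an exact copy.
Passing tests therefore show that the *model* separates predictable from
unpredictable schedules under idealised kinematics; they do not show how
strong that separation would be with the richer variability of real vehicle
motion.

## The simulation experiment

The experiment grid crosses the three motion conditions with two calculation
conditions: `C_GPR` (the coupled learner, as above) and `C_Control`
(no learning; the true horizontal acceleration scaled by a fixed
`k_pr = 0.5` feeds the internal model). Five replicate seeds per cell;
per-cell seeds derive deterministically from a base seed, and a given
(condition, replicate) pair shares its seed across the two modes so both see
identical profiles and sensor noise. The expected contrasts, asserted as
orderings of seed-averaged final MSIs (no formal hypothesis test is claimed,
since replicate structure is a simulation choice, not an estimate of any
population variability):

- under `C_GPR`: mean MSI(M_P) below both unpredictable conditions, with
  non-overlapping min–max ranges, and the two unpredictable conditions
  mutually closer than either is to `M_P`;
- under `C_Control`: the three conditions agree within a 5 % relative spread.

The mechanism is visible in the traces: on `M_P` the prediction error
collapses after the first movement cycle and the variance stays low, so
`k_pr ~ 0.6` of the upcoming acceleration is cancelled inside the internal
model; on `M_dU`/`M_tU` the learner confidently mispredicts at each
randomised onset (the preceding window looks identical to the predictable
case), the variance spikes, and the average cancellation is weaker.

### Problem sizes

Full-scale sessions are 900 s at 0.01 s steps with `m = 100` and an update
every step. The packaged test suite exercises the contrast at a scaled-down
profile — 300 s sessions, `m = 50`, posterior update every 5th sample
(inference still runs every sample) — which preserves all four qualitative
contrasts; the full grid is reproduced offline via
`msisim experiment --out ...` (about ten minutes on one CPU). Learner
steady-state quantities (variance, `k_pr`) are measured on 60 s predictable
runs at full learner settings, since they converge within the first two
cycles.

## Numerical choices

- **Integration**: one Heun (explicit trapezoid) step per 0.01 s sample for
  the coupled observer, inputs held constant across the step. Plain forward
  Euler was rejected: the conflict-feedback loop is lightly damped
  (eigenfrequency ~ sqrt(K_fb/tau) ~ 1.6 rad/s) and first-order integration
  changed the 900 s MSI by ~2 % under step halving; with Heun the change is
  far below the 1 % sanity bound asserted in the tests.
- **Linear algebra**: `K(X,X)^{-1}` is never formed; the Cholesky factor is
  cached at initialisation and reused every step. The covariance update
  subtracts a rank-one outer product, preserving symmetry up to roundoff.
- **Degenerate inputs**: infeasible movement kinematics raise an error
  naming the achievable amplitude range; empty profiles, negative noise
  variance, non-finite observations and malformed CSVs raise informative
  errors rather than propagating NaNs; a non-finite observer state is
  reported with the offending component's name.
- **Warm-up**: until `d` samples exist the learner emits the prior
  (mean 0, variance `sigma_f^2`) and performs no update; with `c2 = 3` the
  prior variance drives `k_pr` to ~5e-9, so the warm-up contributes no
  phantom prediction.

## Known limitations

- Translational motion only, head upright and fixed: no canal dynamics,
  no rotation, no visual pathway, no efference copy (passive motion only).
- The learner's input is the one-dimensional horizontal acceleration; the
  multi-axis generalisation of the NAR window is untested.
- Hyperparameter calibration anchors to steady-state behaviour on the
  predictable condition; no marginal-likelihood optimisation is provided.
- MSI is a population-level incidence; the model says nothing about
  individual susceptibility or habituation across sessions.
- The between-condition contrast is asserted as an ordering across five
  seeded replicates, not as a statistical test.
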