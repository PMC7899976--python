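"""Subjective-vertical-conflict (SVC) observer model of motion sickness.

The model receives the gravito-inertial acceleration (GIA) alpha = a + g
sensed by the otoliths (modelled as identity) and low-pass filters it with
time constant tau into the sensed vertical v.  A CNS internal model mirrors
this pathway: its own GIA estimate alpha_bar (corrected by integrating the
conflict through gain K_fb) plus the predicted exogenous motion alpha_tilde
is filtered by an identical low-pass into the expected vertical v_hat.  The
conflict Delta v = v - v_hat drives motion sickness through a saturating Hill
function of its norm and a second-order lag P/(tau_I s + 1)^2 with a long
time constant, whose output m is the predicted motion sickness incidence
(MSI, % of a population expected to vomit).

State vector (11-dimensional): xi = [v, v_hat, alpha_bar, m_dot, m].
Integration is one Heun (explicit trapezoid) step per sample (default
0.01 s); second-order accuracy keeps the end-of-session MSI insensitive to
halving the step.

The predicted exogenous motion comes either from the online GP learner
(condition ``C_GPR``: alpha_tilde = k_pr * predicted mean, with confidence
weight k_pr = c1 exp(-c2 * predicted variance)) or, in the control condition
``C_Control``, from the true acceleration scaled by a fixed k_pr = 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .motion import MotionProfile, MovementSpec, SessionSpec, add_sensor_noise, generate_session
from .rgpr import (
    OnlineMotionPredictor,
    RecursiveGPRegressor,
    RGPRConfig,
    harvest_windows,
    select_location_vectors,
)

__all__ = [
    "SVCParams",
    "SVCState",
    "PredictedMotion",
    "SimulationResult",
    "gia",
    "hill",
    "prediction_gain",
    "predicted_motion",
    "step",
    "integrate_msi_lag",
    "build_location_vectors",
    "simulate",
]

MODES = ("C_Control", "C_GPR")


@dataclass(frozen=True)
class SVCParams:
    """Observer-model parameters.

    tau: low-pass time constant of vertical perception (s).
    tau_I: time constant of the MSI accumulation lag (s).
    K_fb: conflict feedback gain into the internal GIA estimate.
    b: half-saturation conflict magnitude of the Hill function (m/s^2).
    P: MSI saturation level (%), the lag's DC gain.
    c1, c2: prediction-weight law k_pr = c1 * exp(-c2 * variance).
    k_pr_control: fixed weight used in the control condition.
    g: gravity vector in the upright head frame (m/s^2).
    """

    tau: float = 2.0
    tau_I: float = 720.0
    K_fb: float = 5.0
    b: float = 0.5
    P: float = 85.0
    c1: float = 0.8
    c2: float = 3.0
    k_pr_control: float = 0.5
    g: tuple[float, float, float] = (0.0, 0.0, 9.81)

    def __post_init__(self) -> None:
        if min(self.tau, self.tau_I, self.b) <= 0:
            raise ValueError("tau, tau_I and b must be positive")
        if not 0.0 < self.P <= 100.0:
            raise ValueError("P must be in (0, 100]")
        if not 0.0 < self.c1 <= 1.0:
            raise ValueError("c1 must be in (0, 1]")
        if self.c2 < 0:
            raise ValueError("c2 must be non-negative")

    @property
    def g_vec(self) -> np.ndarray:
        return np.asarray(self.g, dtype=float)


@dataclass
class SVCState:
    """Observer state: sensed vertical, expected vertical, internal GIA
    estimate (3-vectors, m/s^2), MSI rate (%/s) and MSI (%)."""

    v: np.ndarray
    v_hat: np.ndarray
    alpha_bar: np.ndarray
    m_dot: float = 0.0
    m: float = 0.0

    @classmethod
    def rest(cls, params: SVCParams) -> "SVCState":
        """Zero-conflict rest state: all verticals aligned with gravity."""
        g = params.g_vec
        return cls(v=g.copy(), v_hat=g.copy(), alpha_bar=g.copy())

    def as_vector(self) -> np.ndarray:
        """The 11-dimensional state xi = [v, v_hat, alpha_bar, m_dot, m]."""
        return np.concatenate([self.v, self.v_hat, self.alpha_bar, [self.m_dot, self.m]])


@dataclass(frozen=True)
class PredictedMotion:
    """Predicted exogenous GIA contribution fed to the internal model."""

    alpha_tilde: np.ndarray  # 3-vector, m/s^2
    k_pr: float


def gia(a: np.ndarray, g: np.ndarray) -> np.ndarray:
    """Gravito-inertial acceleration alpha = a + g."""
    return np.asarray(a, dtype=float) + np.asarray(g, dtype=float)


def hill(conflict_norm: float, b: float) -> float:
    """Saturating map of conflict magnitude to lag drive: (x/b)^2 / (1+(x/b)^2)."""
    if conflict_norm < 0:
        raise ValueError("conflict norm must be non-negative")
    r = (conflict_norm / b) ** 2
    return r / (1.0 + r)


def prediction_gain(variance: float, params: SVCParams) -> float:
    """Confidence weight k_pr = c1 * exp(-c2 * variance); decays as the
    learner's predictive variance grows."""
    if variance < 0:
        raise ValueError("variance must be non-negative")
    return params.c1 * math.exp(-params.c2 * variance)


def predicted_motion(
    mean: float,
    variance: float,
    params: SVCParams,
    mode: str = "C_GPR",
    alpha_true_horizontal: float = 0.0,
) -> PredictedMotion:
    """Build the horizontal predicted-motion input for either condition.

    ``C_GPR`` weights the learner's predicted mean by the confidence gain;
    ``C_Control`` bypasses the learner and feeds the true horizontal
    acceleration scaled by the fixed control weight.
    """
    if mode == "C_GPR":
        k_pr = prediction_gain(variance, params)
        at = k_pr * mean
    elif mode == "C_Control":
        k_pr = params.k_pr_control
        at = k_pr * alpha_true_horizontal
    else:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    return PredictedMotion(alpha_tilde=np.array([at, 0.0, 0.0]), k_pr=k_pr)


def _msi_lag_derivs(m: float, m_dot: float, h: float, params: SVCParams) -> tuple[float, float]:
    """Derivatives of the two-state realisation of P/(tau_I s + 1)^2 driven by h:
    tau_I^2 m'' + 2 tau_I m' + m = P h."""
    m_ddot = (params.P * h - m - 2.0 * params.tau_I * m_dot) / params.tau_I**2
    return m_dot, m_ddot


def _derivs(
    v: np.ndarray,
    v_hat: np.ndarray,
    alpha_bar: np.ndarray,
    m: float,
    m_dot: float,
    alpha: np.ndarray,
    alpha_tilde: np.ndarray,
    params: SVCParams,
):
    """Time derivatives of the observer state.

    dv/dt         = (alpha - v) / tau                     (sensory low-pass)
    dv_hat/dt     = (alpha_bar + alpha_tilde - v_hat)/tau (internal low-pass)
    dalpha_bar/dt = K_fb * (v - v_hat)                    (conflict feedback)
    and the MSI lag driven by the Hill function of |v - v_hat|.
    """
    dv = (alpha - v) / params.tau
    dv_hat = (alpha_bar + alpha_tilde - v_hat) / params.tau
    conflict = v - v_hat
    dalpha_bar = params.K_fb * conflict
    h = hill(float(np.linalg.norm(conflict)), params.b)
    dm, dm_dot = _msi_lag_derivs(m, m_dot, h, params)
    return dv, dv_hat, dalpha_bar, dm, dm_dot


def step(
    state: SVCState,
    alpha: np.ndarray,
    predicted: PredictedMotion,
    params: SVCParams,
    dt: float,
) -> SVCState:
    """Advance the observer by one Heun (explicit trapezoid) step of length dt.

    The GIA and predicted-motion inputs are held constant over the step (they
    arrive sampled anyway); the state derivatives of :func:`_derivs` are
    averaged between the step endpoints for second-order accuracy.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    for name, val in (("v", state.v), ("v_hat", state.v_hat), ("alpha_bar", state.alpha_bar)):
        if not np.all(np.isfinite(val)):
            raise ValueError(f"non-finite state component {name}")
    at = predicted.alpha_tilde
    k1 = _derivs(state.v, state.v_hat, state.alpha_bar, state.m, state.m_dot, alpha, at, params)
    k2 = _derivs(
        state.v + dt * k1[0],
        state.v_hat + dt * k1[1],
        state.alpha_bar + dt * k1[2],
        state.m + dt * k1[3],
        state.m_dot + dt * k1[4],
        alpha,
        at,
        params,
    )
    half = 0.5 * dt
    return SVCState(
        v=state.v + half * (k1[0] + k2[0]),
        v_hat=state.v_hat + half * (k1[1] + k2[1]),
        alpha_bar=state.alpha_bar + half * (k1[2] + k2[2]),
        m=state.m + half * (k1[3] + k2[3]),
        m_dot=state.m_dot + half * (k1[4] + k2[4]),
    )


def integrate_msi_lag(
    h: float, t_end: float, dt: float, params: SVCParams
) -> np.ndarray:
    """Integrate the isolated MSI lag under a constant Hill drive h.

    Returns the MSI trace sampled every dt; useful for checking the pathway's
    step response against the closed form P*h*(1 - exp(-t/tau_I)(1+t/tau_I)).
    """
    n = round(t_end / dt)
    m, m_dot = 0.0, 0.0
    out = np.empty(n)
    for i in range(n):
        dm1, dm_dot1 = _msi_lag_derivs(m, m_dot, h, params)
        dm2, dm_dot2 = _msi_lag_derivs(m + dt * dm1, m_dot + dt * dm_dot1, h, params)
        m += 0.5 * dt * (dm1 + dm2)
        m_dot += 0.5 * dt * (dm_dot1 + dm_dot2)
        out[i] = m
    return out


@dataclass
class SimulationResult:
    """Per-step traces of one simulated session."""

    dt: float
    mu_p: np.ndarray  # predicted mean (m/s^2)
    C_p: np.ndarray  # predicted variance ((m/s^2)^2)
    error: np.ndarray  # mu_p - true horizontal acceleration
    k_pr: np.ndarray
    conflict_norm: np.ndarray  # |v - v_hat| (m/s^2)
    msi: np.ndarray  # %
    meta: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return (np.arange(len(self.msi)) + 1) * self.dt

    @property
    def final_msi(self) -> float:
        return float(self.msi[-1])

    def to_csv(self, path: str | Path) -> None:
        data = np.column_stack(
            [self.times, self.mu_p, self.C_p, self.error, self.k_pr, self.conflict_norm, self.msi]
        )
        np.savetxt(
            path,
            data,
            fmt="%.10g",
            delimiter=",",
            header="t,mu_p,C_p,error,k_pr,conflict_norm,msi",
            comments="",
        )


def build_location_vectors(
    config: RGPRConfig,
    movement: MovementSpec,
    dt: float,
    pause_fixed: float = 8.0,
) -> np.ndarray:
    """Location vectors for the learner: greedy farthest-point selection of m
    windows harvested from one noise-free predictable (M_P) session.

    The same X is used for every simulated condition, so differences between
    conditions come only from how well their windows are predicted, not from
    a per-condition basis.
    """
    d = config.window_size(dt)
    spec = SessionSpec(
        condition="M_P",
        total_duration=config.harvest_duration,
        pause_fixed=pause_fixed,
        dt=dt,
        seed=0,
        movement=movement,
    )
    session = generate_session(spec)
    candidates = harvest_windows(session.accel, d, config.candidate_stride)
    return select_location_vectors(candidates, config.m)


def simulate(
    profile: MotionProfile,
    mode: str = "C_GPR",
    params: SVCParams | None = None,
    rgpr_config: RGPRConfig | None = None,
    seed: int = 0,
    location_vectors: np.ndarray | None = None,
) -> SimulationResult:
    """Run the coupled learner/observer loop over one motion profile.

    Per step: the learner observes the previous noisy accelerations, emits a
    one-step prediction, the prediction (weighted by its confidence) enters
    the internal model, the observer advances one Euler step, and the learner
    is updated with the new noisy sample.  Deterministic given the seed.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    params = params or SVCParams()
    rgpr_config = rgpr_config or RGPRConfig()
    dt = profile.dt
    n = len(profile.accel)
    a_true = profile.accel
    g = params.g_vec

    predictor: OnlineMotionPredictor | None = None
    noisy: np.ndarray | None = None
    if mode == "C_GPR":
        if location_vectors is None:
            movement = MovementSpec(
                duration=profile.meta.get("movement_duration", 8.0),
                peak_accel=profile.meta.get("peak_accel", 2.5),
                amplitude=profile.meta.get("amplitude", 9.0),
            )
            location_vectors = build_location_vectors(rgpr_config, movement, dt)
        reg = RecursiveGPRegressor(
            location_vectors, rgpr_config.hyper, rgpr_config.jitter_rel
        )
        predictor = OnlineMotionPredictor(
            reg, learn_stride=rgpr_config.learn_stride, capacity=n + 1
        )
        noisy = add_sensor_noise(profile, rgpr_config.sensor_noise_variance, seed)

    state = SVCState.rest(params)
    mu_p = np.zeros(n)
    C_p = np.zeros(n)
    error = np.zeros(n)
    k_pr = np.zeros(n)
    conflict_norm = np.zeros(n)
    msi = np.zeros(n)

    alpha = g.copy()  # GIA; only the horizontal component varies below
    for t in range(n):
        if mode == "C_GPR":
            pred = predictor.step(noisy[t])
            pm = predicted_motion(pred.mean, pred.variance, params, mode)
            mu_p[t], C_p[t] = pred.mean, pred.variance
            error[t] = pred.mean - a_true[t]
        else:
            pm = predicted_motion(0.0, 0.0, params, mode, alpha_true_horizontal=a_true[t])
            mu_p[t] = a_true[t]
        k_pr[t] = pm.k_pr
        alpha[0] = g[0] + a_true[t]
        state = step(state, alpha, pm, params, dt)
        conflict_norm[t] = float(np.linalg.norm(state.v - state.v_hat))
        msi[t] = state.m

    meta = {
        "mode": mode,
        "seed": seed,
        "condition": profile.meta.get("condition"),
        "clamp_count": predictor.regressor.clamp_count if predictor else 0,
        "n_infer": predictor.regressor.n_infer if predictor else 0,
    }
    return SimulationResult(
        dt=dt,
        mu_p=mu_p,
        C_p=C_p,
        error=error,
        k_pr=k_pr,
        conflict_norm=conflict_norm,
        msi=msi,
        meta=meta,
    )
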