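"""Generation of horizontal motion-profile sessions and sensor observations.

A session is a long (default 900 s) sequence of repetitive single back-and-forth
cart movements separated by pauses.  Three conditions differ only in what is
predictable about the repetition:

``M_P``
    fully predictable: direction alternates, pauses are fixed at 8 s;
``M_dU``
    direction of each movement is drawn at random (same or opposite to the
    predictable schedule), timing unchanged;
``M_tU``
    directions follow the predictable schedule, but each pause is drawn
    uniformly from 4–12 s.

All three conditions use the identical acceleration pulse, so their
root-mean-square accelerations match; for ``M_tU`` the drawn pauses are
rescaled so the total moving/paused time matches the predictable schedule
exactly (see :func:`generate_session`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MovementSpec",
    "SessionSpec",
    "MotionEvent",
    "MotionProfile",
    "InfeasibleMovementError",
    "ProfileParseError",
    "build_single_movement",
    "generate_session",
    "rms_acceleration",
    "add_sensor_noise",
    "write_profile",
    "read_profile",
]

CONDITIONS = ("M_P", "M_dU", "M_tU")


class InfeasibleMovementError(ValueError):
    """Raised when no rest-to-rest pulse can realise the requested amplitude."""


class ProfileParseError(ValueError):
    """Raised when a profile CSV cannot be parsed."""


@dataclass(frozen=True)
class MovementSpec:
    """Kinematics of one rest-to-rest movement.

    The acceleration waveform is a half-sine pulse of width ``pulse_width``
    reaching ``peak_accel``, a zero-acceleration coast, and a mirrored
    deceleration half-sine, so the cart starts and ends at rest and covers
    ``amplitude`` metres in ``duration`` seconds.
    """

    duration: float = 8.0  # s
    peak_accel: float = 2.5  # m/s^2
    amplitude: float = 9.0  # m

    def __post_init__(self) -> None:
        if self.duration <= 0 or self.peak_accel <= 0 or self.amplitude <= 0:
            raise ValueError("duration, peak_accel and amplitude must be positive")
        self.pulse_width  # validate feasibility eagerly

    @property
    def max_amplitude(self) -> float:
        """Largest displacement reachable with this duration and peak (t_a = T/2)."""
        return self.peak_accel * self.duration**2 / (2.0 * math.pi)

    @property
    def pulse_width(self) -> float:
        """Half-sine width t_a solving (2 A t_a / pi)(T - t_a) = amplitude.

        The smaller root of t_a^2 - T t_a + pi*amplitude/(2A) = 0 is taken;
        it always lies in (0, T/2] when real.
        """
        T, A, D = self.duration, self.peak_accel, self.amplitude
        disc = T * T - 2.0 * math.pi * D / A
        if disc < 0:
            raise InfeasibleMovementError(
                f"amplitude {D} m unreachable in {T} s at peak {A} m/s^2; "
                f"achievable range is (0, {self.max_amplitude:.4g}] m"
            )
        return 0.5 * (T - math.sqrt(disc))


@dataclass(frozen=True)
class SessionSpec:
    """A full session: condition, length, timing parameters and seed."""

    condition: str = "M_P"
    total_duration: float = 900.0  # s
    pause_fixed: float = 8.0  # s, M_P / M_dU pause
    pause_range: tuple[float, float] = (4.0, 12.0)  # s, M_tU pause bounds
    dt: float = 0.01  # s
    seed: int = 0
    movement: MovementSpec = field(default_factory=MovementSpec)

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}; expected one of {CONDITIONS}")
        if self.total_duration <= 0:
            raise ValueError("total_duration must be positive")
        if not self.pause_range[0] < self.pause_range[1]:
            raise ValueError("pause_range lower bound must be below upper bound")
        if self.dt <= 0:
            raise ValueError("dt must be positive")


@dataclass(frozen=True)
class MotionEvent:
    """One movement: onset time (s), direction (+1/-1), pause following it (s)."""

    onset: float
    direction: int
    pause_after: float


@dataclass
class MotionProfile:
    """Time-gridded signed horizontal acceleration plus movement metadata."""

    dt: float
    accel: np.ndarray  # m/s^2, shape (n,)
    events: list[MotionEvent] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    @property
    def duration(self) -> float:
        return len(self.accel) * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(len(self.accel)) * self.dt


def build_single_movement(spec: MovementSpec, dt: float) -> np.ndarray:
    """Sample one movement's acceleration pulse on a grid of step ``dt``.

    Returns ``round(duration/dt)`` samples at t = 0, dt, 2*dt, ...; the pulse
    is A*sin(pi*t/t_a) on [0, t_a), zero on the coast, and the mirrored
    negative half-sine on [T - t_a, T).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = round(spec.duration / dt)
    if n < 2 or abs(n - spec.duration / dt) > 1e-6:
        raise ValueError(f"dt={dt} does not divide movement duration {spec.duration}")
    t_a = spec.pulse_width
    t = np.arange(n) * dt
    a = np.zeros(n)
    rise = t < t_a
    a[rise] = spec.peak_accel * np.sin(np.pi * t[rise] / t_a)
    fall = t >= spec.duration - t_a
    a[fall] = -spec.peak_accel * np.sin(np.pi * (t[fall] - (spec.duration - t_a)) / t_a)
    return a


def _equalized_pauses(
    rng: np.random.Generator, n: int, lo: float, hi: float, target_sum: float
) -> np.ndarray:
    """Draw n pauses ~ U(lo, hi) and rescale them so they sum to target_sum.

    Values are kept inside [lo, hi]; the rescaling residual is redistributed
    over unpinned pauses until it vanishes.  target_sum must lie in
    [n*lo, n*hi].
    """
    if not n * lo <= target_sum <= n * hi:
        raise ValueError("pause budget outside feasible range")
    p = rng.uniform(lo, hi, size=n)
    p *= target_sum / p.sum()
    for _ in range(100):
        p = np.clip(p, lo, hi)
        resid = target_sum - p.sum()
        if abs(resid) < 1e-9:
            return p
        adjustable = (p < hi) if resid > 0 else (p > lo)
        p[adjustable] += resid / adjustable.sum()
    raise RuntimeError("pause equalization did not converge")  # pragma: no cover


def generate_session(spec: SessionSpec) -> MotionProfile:
    """Generate a full session for one of the three motion conditions.

    The movement count and the total time spent moving are identical across
    conditions (for ``M_tU`` the random pauses are rescaled to the fixed-pause
    budget), so the session RMS acceleration is condition-independent.
    Reproducible: the same ``SessionSpec`` always yields the same profile.
    """
    rng = np.random.default_rng(spec.seed)
    move = spec.movement
    dt = spec.dt
    n_total = round(spec.total_duration / dt)
    pulse = build_single_movement(move, dt)

    cycle = move.duration + spec.pause_fixed
    n_moves = int(math.floor((spec.total_duration - move.duration) / cycle)) + 1
    if n_moves < 1:
        raise ValueError("total_duration shorter than a single movement")

    alternating = np.array([1 if k % 2 == 0 else -1 for k in range(n_moves)])
    if spec.condition == "M_P":
        directions = alternating
        pauses = np.full(n_moves - 1, spec.pause_fixed)
    elif spec.condition == "M_dU":
        # keep the predictable timing; flip each direction with probability 1/2
        flips = rng.integers(0, 2, size=n_moves)
        directions = alternating * np.where(flips == 1, -1, 1)
        pauses = np.full(n_moves - 1, spec.pause_fixed)
    elif spec.condition == "M_tU":
        directions = alternating
        lo, hi = spec.pause_range
        pauses = _equalized_pauses(
            rng, n_moves - 1, lo, hi, target_sum=(n_moves - 1) * spec.pause_fixed
        )
    else:  # pragma: no cover - guarded by SessionSpec
        raise ValueError(f"unknown condition {spec.condition!r}")

    onsets = np.concatenate([[0.0], np.cumsum(pauses + move.duration)])
    # snap onsets to the sample grid so every movement reuses identical samples
    onset_idx = np.rint(onsets / dt).astype(int)
    accel = np.zeros(n_total)
    events: list[MotionEvent] = []
    for k in range(n_moves):
        i0 = onset_idx[k]
        if i0 + len(pulse) > n_total:
            raise RuntimeError("movement extends past session end")  # pragma: no cover
        accel[i0 : i0 + len(pulse)] = directions[k] * pulse
        if k < n_moves - 1:
            pause_after = (onset_idx[k + 1] - i0) * dt - move.duration
        else:
            pause_after = spec.total_duration - (i0 * dt + move.duration)
        events.append(MotionEvent(i0 * dt, int(directions[k]), pause_after))

    meta = {
        "condition": spec.condition,
        "total_duration": spec.total_duration,
        "seed": spec.seed,
        "peak_accel": move.peak_accel,
        "movement_duration": move.duration,
        "amplitude": move.amplitude,
    }
    return MotionProfile(dt=dt, accel=accel, events=events, meta=meta)


def rms_acceleration(profile: MotionProfile) -> float:
    """Root-mean-square of the acceleration samples over the whole session."""
    if len(profile.accel) == 0:
        raise ValueError("empty profile")
    return float(np.sqrt(np.mean(profile.accel**2)))


def add_sensor_noise(
    profile: MotionProfile, variance: float = 1e-4, seed: int = 0
) -> np.ndarray:
    """Noisy observations of the profile: each sample plus i.i.d. N(0, variance).

    Models the sensory channel feeding the motion learner; reproducible from
    the seed.
    """
    if variance < 0:
        raise ValueError("noise variance must be non-negative")
    if variance == 0:
        return profile.accel.copy()
    rng = np.random.default_rng(seed)
    return profile.accel + rng.normal(0.0, math.sqrt(variance), size=len(profile.accel))


_CSV_HEADER = "t,accel_x"


def write_profile(profile: MotionProfile, path: str | Path) -> None:
    """Write a profile as CSV (columns ``t, accel_x``) plus a JSON event sidecar."""
    path = Path(path)
    data = np.column_stack([profile.times, profile.accel])
    np.savetxt(path, data, fmt="%.17g", delimiter=",", header=_CSV_HEADER, comments="")
    sidecar = {
        "dt": profile.dt,
        "meta": profile.meta,
        "events": [
            {"onset": e.onset, "direction": e.direction, "pause_after": e.pause_after}
            for e in profile.events
        ],
    }
    path.with_suffix(path.suffix + ".events.json").write_text(json.dumps(sidecar, indent=1))


def read_profile(path: str | Path) -> MotionProfile:
    """Read a profile written by :func:`write_profile`; lossless round-trip."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ProfileParseError(f"{path}: empty file")
    if lines[0].strip() != _CSV_HEADER:
        raise ProfileParseError(
            f"{path}:1: expected header '{_CSV_HEADER}', got '{lines[0].strip()}'"
        )
    t = np.empty(len(lines) - 1)
    accel = np.empty(len(lines) - 1)
    for i, line in enumerate(lines[1:], start=2):
        parts = line.split(",")
        if len(parts) != 2:
            raise ProfileParseError(f"{path}:{i}: expected 2 columns, got {len(parts)}")
        try:
            t[i - 2], accel[i - 2] = float(parts[0]), float(parts[1])
        except ValueError as exc:
            raise ProfileParseError(f"{path}:{i}: {exc}") from exc
    if len(t) < 2:
        raise ProfileParseError(f"{path}: need at least two samples to infer dt")
    dt = float(t[1] - t[0])

    events: list[MotionEvent] = []
    meta: dict = {}
    sidecar_path = path.with_suffix(path.suffix + ".events.json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        dt = float(sidecar.get("dt", dt))
        meta = sidecar.get("meta", {})
        events = [
            MotionEvent(e["onset"], int(e["direction"]), e["pause_after"])
            for e in sidecar.get("events", [])
        ]
    return MotionProfile(dt=dt, accel=accel, events=events, meta=meta)
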