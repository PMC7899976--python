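"""The 3 x 2 simulation experiment: motion conditions x calculation conditions.

Runs every (condition, mode, seed) cell of the grid, collects the predicted
MSI at the end of each session, and summarises per-cell statistics.  The whole
experiment is a pure function of its configuration: per-cell seeds derive
deterministically from the base seed, and the same seed is used for a given
(condition, replicate) under both calculation conditions so the two modes see
identical motion profiles and sensor noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .motion import CONDITIONS, MovementSpec, SessionSpec, generate_session
from .rgpr import KernelHyperparams, RGPRConfig
from .svc import MODES, SVCParams, SimulationResult, build_location_vectors, simulate

__all__ = [
    "ExperimentConfig",
    "ExperimentResult",
    "FAST_PROFILE",
    "run_experiment",
    "summarize",
    "ordering_flags",
]

logger = logging.getLogger(__name__)

#: Scaled-down profile for quick runs: shorter sessions, decimated learning,
#: fewer location vectors.  Preserves the qualitative contrasts between cells.
FAST_PROFILE = {"total_duration": 300.0, "learn_stride": 5, "m": 50}


@dataclass(frozen=True)
class ExperimentConfig:
    conditions: tuple[str, ...] = CONDITIONS
    modes: tuple[str, ...] = MODES
    n_seeds: int = 5
    base_seed: int = 0
    total_duration: float = 900.0
    dt: float = 0.01
    pause_fixed: float = 8.0
    pause_range: tuple[float, float] = (4.0, 12.0)
    movement: MovementSpec = field(default_factory=MovementSpec)
    svc: SVCParams = field(default_factory=SVCParams)
    rgpr: RGPRConfig = field(default_factory=RGPRConfig)

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if not self.conditions or not self.modes:
            raise ValueError("conditions and modes must be non-empty")
        for c in self.conditions:
            if c not in CONDITIONS:
                raise ValueError(f"unknown condition {c!r}")
        for m in self.modes:
            if m not in MODES:
                raise ValueError(f"unknown mode {m!r}")

    def with_fast_profile(self) -> "ExperimentConfig":
        """Return a copy using the scaled-down :data:`FAST_PROFILE`."""
        return replace(
            self,
            total_duration=FAST_PROFILE["total_duration"],
            rgpr=replace(
                self.rgpr,
                learn_stride=FAST_PROFILE["learn_stride"],
                m=FAST_PROFILE["m"],
            ),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        """Load a configuration from a YAML key-value file.

        Recognised keys mirror the dataclass fields; movement/svc/rgpr blocks
        are nested mappings (``rgpr`` additionally accepts the flat hyper keys
        ``sigma_f``, ``lengthscale``, ``noise_sd``).  ``fast: true`` applies
        the fast profile after everything else.
        """
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs: dict = {}
        for key in ("n_seeds", "base_seed", "total_duration", "dt", "pause_fixed"):
            if key in raw:
                kwargs[key] = raw[key]
        if "conditions" in raw:
            kwargs["conditions"] = tuple(raw["conditions"])
        if "modes" in raw:
            kwargs["modes"] = tuple(raw["modes"])
        if "pause_range" in raw:
            kwargs["pause_range"] = tuple(raw["pause_range"])
        move_raw = raw.get("movement", {})
        movement_keys = {"duration", "peak_accel", "amplitude"}
        # flat aliases from the profile-level schema
        if "movement_duration" in raw:
            move_raw.setdefault("duration", raw["movement_duration"])
        for k in ("peak_accel", "amplitude"):
            if k in raw:
                move_raw.setdefault(k, raw[k])
        if move_raw:
            kwargs["movement"] = MovementSpec(**{k: move_raw[k] for k in move_raw if k in movement_keys})
        if "svc" in raw:
            kwargs["svc"] = SVCParams(**raw["svc"])
        rgpr_raw = dict(raw.get("rgpr", {}))
        if "noise_variance" in raw:
            rgpr_raw.setdefault("sensor_noise_variance", raw["noise_variance"])
        if rgpr_raw:
            hyper_keys = {"sigma_f", "lengthscale", "noise_sd"}
            hyper_kwargs = {k: rgpr_raw.pop(k) for k in list(rgpr_raw) if k in hyper_keys}
            if hyper_kwargs:
                rgpr_raw["hyper"] = KernelHyperparams(**hyper_kwargs)
            kwargs["rgpr"] = RGPRConfig(**rgpr_raw)
        config = cls(**kwargs)
        if raw.get("fast"):
            config = config.with_fast_profile()
        return config


@dataclass
class ExperimentResult:
    records: pd.DataFrame  # condition, mode, seed, final_msi, run_path
    config: ExperimentConfig


def derive_seed(base_seed: int, condition: str, replicate: int) -> int:
    """Deterministic per-cell seed, shared across modes; < 2**31."""
    ss = np.random.SeedSequence([base_seed, CONDITIONS.index(condition), replicate])
    return int(ss.generate_state(1)[0] % (2**31))


def run_experiment(
    config: ExperimentConfig, out_dir: str | Path | None = None
) -> ExperimentResult:
    """Execute all (condition, mode, seed) cells of the configured grid.

    If ``out_dir`` is given, the per-run trace CSVs and a summary CSV are
    written there.  Location vectors for the learner are built once and
    shared by all runs.
    """
    out_path = Path(out_dir) if out_dir is not None else None
    if out_path is not None:
        out_path.mkdir(parents=True, exist_ok=True)

    X = None
    if "C_GPR" in config.modes:
        X = build_location_vectors(
            config.rgpr, config.movement, config.dt, config.pause_fixed
        )

    rows = []
    for condition in config.conditions:
        for rep in range(config.n_seeds):
            seed = derive_seed(config.base_seed, condition, rep)
            session = generate_session(
                SessionSpec(
                    condition=condition,
                    total_duration=config.total_duration,
                    pause_fixed=config.pause_fixed,
                    pause_range=config.pause_range,
                    dt=config.dt,
                    seed=seed,
                    movement=config.movement,
                )
            )
            for mode in config.modes:
                try:
                    result = simulate(
                        session,
                        mode=mode,
                        params=config.svc,
                        rgpr_config=config.rgpr,
                        seed=seed,
                        location_vectors=X,
                    )
                except Exception as exc:
                    raise RuntimeError(
                        f"cell ({condition}, {mode}, seed {seed}) failed: {exc}"
                    ) from exc
                _log_run(condition, mode, seed, result)
                run_path = ""
                if out_path is not None:
                    run_path = str(out_path / f"run_{condition}_{mode}_{rep}.csv")
                    result.to_csv(run_path)
                rows.append(
                    {
                        "condition": condition,
                        "mode": mode,
                        "seed": seed,
                        "replicate": rep,
                        "final_msi": result.final_msi,
                        "run_path": run_path,
                    }
                )
    records = pd.DataFrame(rows)
    if out_path is not None:
        summarize(records).to_csv(out_path / "summary.csv", index=False)
    return ExperimentResult(records=records, config=config)


def _log_run(condition: str, mode: str, seed: int, result: SimulationResult) -> None:
    """Log per-cycle prediction-error RMS and variance-clamp events."""
    if mode == "C_GPR":
        n_cycle = max(1, round(16.0 / result.dt))
        n_cycles = len(result.error) // n_cycle
        rms = [
            float(np.sqrt(np.mean(result.error[i * n_cycle : (i + 1) * n_cycle] ** 2)))
            for i in range(min(n_cycles, 8))
        ]
        logger.info(
            "%s/%s seed=%d final_msi=%.4f clamps=%d/%d error_rms_per_cycle=%s",
            condition,
            mode,
            seed,
            result.final_msi,
            result.meta.get("clamp_count", 0),
            result.meta.get("n_infer", 0),
            np.round(rms, 4).tolist(),
        )
    else:
        logger.info("%s/%s seed=%d final_msi=%.4f", condition, mode, seed, result.final_msi)


def summarize(records: pd.DataFrame | ExperimentResult) -> pd.DataFrame:
    """Per-cell summary: n, mean, SD, min and max of the final MSI."""
    if isinstance(records, ExperimentResult):
        records = records.records
    if len(records) == 0:
        raise ValueError("empty experiment result")
    out = (
        records.groupby(["condition", "mode"], sort=True)["final_msi"]
        .agg(n="count", msi_mean="mean", msi_sd="std", msi_min="min", msi_max="max")
        .reset_index()
    )
    out["msi_sd"] = out["msi_sd"].fillna(0.0)
    return out


def ordering_flags(summary: pd.DataFrame) -> dict[str, bool]:
    """Qualitative contrasts expected from the experiment.

    Under the learning condition the predictable profile should yield the
    lowest MSI, with the two unpredictable profiles mutually similar; under
    the control condition the three profiles should be nearly equivalent.
    Flags are only computed for contrasts whose cells are present.
    """
    flags: dict[str, bool] = {}
    gpr = summary[summary["mode"] == "C_GPR"].set_index("condition")
    if {"M_P", "M_dU", "M_tU"}.issubset(gpr.index):
        mp, du, tu = gpr.loc["M_P"], gpr.loc["M_dU"], gpr.loc["M_tU"]
        flags["gpr_mp_lowest_mean"] = bool(
            mp["msi_mean"] < du["msi_mean"] and mp["msi_mean"] < tu["msi_mean"]
        )
        flags["gpr_mp_range_below_others"] = bool(
            mp["msi_max"] < du["msi_min"] and mp["msi_max"] < tu["msi_min"]
        )
        gap = min(du["msi_mean"] - mp["msi_mean"], tu["msi_mean"] - mp["msi_mean"])
        flags["gpr_du_tu_similar"] = bool(abs(du["msi_mean"] - tu["msi_mean"]) < gap)
    ctrl = summary[summary["mode"] == "C_Control"].set_index("condition")
    if len(ctrl) >= 2:
        means = ctrl["msi_mean"].to_numpy()
        flags["control_spread_small"] = bool(
            (means.max() - means.min()) / means.mean() < 0.05
        )
    return flags
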