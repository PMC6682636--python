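"""Run configuration: parsing, validation, serialization and seed fan-out.

A RunConfig mirrors the model/grid/noise/analysis parameters field-for-field
in YAML (or JSON, a YAML subset).  Unknown keys are rejected so that typos
fail loudly; an empty document yields the reference defaults (tau = 10 ms,
kappa = 1, p = 0.42, 601 x 601 cells at 0.1 mm, dt = 0.1 ms).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import numpy as np
import yaml

from .kernel import KernelParams
from .simulator import NoiseSpec, SimConfig
from .solutions import ModelParams

__all__ = ["RunConfig", "TrackingConfig", "StatsConfig", "SpectrumConfig",
           "ConfigError", "parse_config", "serialize_config", "stage_seed"]

#: fixed stage indices for the seed-splitting rule, so each pipeline stage
#: can be rerun independently with the same derived seed
_STAGE_INDEX = {
    "simulate": 1, "fit-wave": 2, "sweep-ei": 3, "analyze": 4,
    "st-spectrum": 5, "sample-kernels": 6,
}


class ConfigError(ValueError):
    """Raised for schema violations; message lists the offending keys."""


@dataclass(frozen=True)
class TrackingConfig:
    threshold_frac: float = 0.5
    transient: float = 5.0  # rescaled time (50 ms at tau = 10 ms)
    v_eps: float | None = None  # defaults derived from grid spacing
    a_eps: float | None = None
    window: float = 2.0  # 20 ms classification windows

    def __post_init__(self):
        if not 0 < self.threshold_frac < 1:
            raise ConfigError("threshold_frac must lie in (0, 1)")


@dataclass(frozen=True)
class StatsConfig:
    apen_m: int = 2
    apen_r_frac: float = 0.2
    dfa_n_boxes: int = 20


@dataclass(frozen=True)
class SpectrumConfig:
    n_velocities: int = 100


@dataclass(frozen=True)
class RunConfig:
    kernel: KernelParams = field(
        default_factory=lambda: KernelParams(144.4, 73.7, 1.87, 3.24)
    )
    model: ModelParams = field(default_factory=ModelParams)
    sim: SimConfig = field(default_factory=SimConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    spectrum: SpectrumConfig = field(default_factory=SpectrumConfig)
    seed: int = 0
    n_waves: int = 7

    def __post_init__(self):
        # keep the simulator's kernel/model in sync with the top level
        object.__setattr__(
            self, "sim",
            SimConfig(
                grid_n=self.sim.grid_n, spacing=self.sim.spacing,
                dt=self.sim.dt, duration=self.sim.duration,
                snapshot_stride=self.sim.snapshot_stride,
                kernel=self.kernel, model=self.model, noise=self.sim.noise,
            ),
        )


_SECTIONS = {
    "kernel": KernelParams,
    "model": ModelParams,
    "tracking": TrackingConfig,
    "stats": StatsConfig,
    "spectrum": SpectrumConfig,
}


def _build(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigError(f"unknown keys under '{path}': {sorted(unknown)}")
    return cls(**data)


def parse_config(text: str) -> RunConfig:
    """Parse a YAML/JSON document into a validated RunConfig."""
    raw = yaml.safe_load(text) or {}
    if not isinstance(raw, dict):
        raise ConfigError("configuration document must be a mapping")
    top_allowed = set(_SECTIONS) | {"sim", "seed", "n_waves"}
    unknown = set(raw) - top_allowed
    if unknown:
        raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")

    kwargs = {}
    for name, cls in _SECTIONS.items():
        if name in raw:
            try:
                kwargs[name] = _build(cls, dict(raw[name]), name)
            except (TypeError, ValueError) as exc:
                raise ConfigError(f"invalid '{name}' section: {exc}") from exc
    if "sim" in raw:
        simdata = dict(raw["sim"])
        noise = simdata.pop("noise", None)
        allowed = {"grid_n", "spacing", "dt", "duration", "snapshot_stride"}
        unknown = set(simdata) - allowed
        if unknown:
            raise ConfigError(f"unknown keys under 'sim': {sorted(unknown)}")
        try:
            noise_spec = _build(NoiseSpec, dict(noise), "sim.noise") if noise else NoiseSpec()
            kwargs["sim"] = SimConfig(noise=noise_spec, **simdata)
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid 'sim' section: {exc}") from exc
    for scalar in ("seed", "n_waves"):
        if scalar in raw:
            kwargs[scalar] = int(raw[scalar])
    return RunConfig(**kwargs)


def serialize_config(config: RunConfig) -> str:
    """YAML document that parse_config maps back to an equal RunConfig."""
    doc = {
        "kernel": asdict(config.kernel),
        "model": asdict(config.model),
        "sim": {
            "grid_n": config.sim.grid_n,
            "spacing": config.sim.spacing,
            "dt": config.sim.dt,
            "duration": config.sim.duration,
            "snapshot_stride": config.sim.snapshot_stride,
            "noise": asdict(config.sim.noise),
        },
        "tracking": asdict(config.tracking),
        "stats": asdict(config.stats),
        "spectrum": asdict(config.spectrum),
        "seed": config.seed,
        "n_waves": config.n_waves,
    }
    return yaml.safe_dump(doc, sort_keys=False)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministically derive a per-stage seed from the global one."""
    if stage not in _STAGE_INDEX:
        raise ValueError(f"unknown stage {stage!r}")
    ss = np.random.SeedSequence((int(seed), _STAGE_INDEX[stage]))
    return int(ss.generate_state(1)[0] % (2 ** 31))
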