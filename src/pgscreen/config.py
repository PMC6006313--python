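"""Declarative run configuration (YAML) for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields

import yaml

from .caller import CallerParams
from .errors import ConfigError
from .reference import DEFAULT_BIN_SIZE
from .simulate import CohortParams, GCBias

__all__ = ["RunConfig", "load_config", "save_config"]


def _from_mapping(cls, mapping: dict, context: str):
    """Build a dataclass from a mapping, rejecting unknown keys."""
    known = {f.name for f in fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(f"{context}: unknown keys {sorted(unknown)}")
    try:
        return cls(**mapping)
    except (ValueError, TypeError) as exc:
        raise ConfigError(f"{context}: {exc}") from exc


@dataclass
class RunConfig:
    """All knobs for one reproducible run.

    ``simulator`` holds the cohort generation conditions, ``caller`` the
    calling thresholds; ``seed`` drives every source of randomness.
    """

    n_embryos: int = 40
    seed: int = 0
    bin_size: int = DEFAULT_BIN_SIZE
    out_dir: str = "pgs_run"
    bins_path: str | None = None
    simulator: CohortParams = field(default_factory=CohortParams)
    caller: CallerParams = field(default_factory=CallerParams)

    def __post_init__(self) -> None:
        if self.n_embryos <= 0:
            raise ConfigError("n_embryos must be positive")
        if self.bin_size <= 0:
            raise ConfigError("bin_size must be positive")

    def to_dict(self) -> dict:
        d = asdict(self)
        sim = d["simulator"]
        if self.simulator.gc_bias is not None:
            sim["gc_bias"] = {
                "coeffs": list(self.simulator.gc_bias.coeffs),
                "floor": self.simulator.gc_bias.floor,
            }
        sim["mosaic_fraction_range"] = list(sim["mosaic_fraction_range"])
        sim["te_cells_range"] = list(sim["te_cells_range"])
        return d

    @classmethod
    def from_dict(cls, mapping: dict) -> "RunConfig":
        mapping = dict(mapping)
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ConfigError(f"config: unknown keys {sorted(unknown)}")
        sim_map = dict(mapping.pop("simulator", {}) or {})
        if "gc_bias" in sim_map and sim_map["gc_bias"] is not None:
            gb = sim_map["gc_bias"]
            sim_map["gc_bias"] = GCBias(
                coeffs=tuple(gb.get("coeffs", GCBias().coeffs)),
                floor=float(gb.get("floor", GCBias().floor)),
            )
        for key in ("mosaic_fraction_range", "te_cells_range"):
            if key in sim_map:
                sim_map[key] = tuple(sim_map[key])
        caller_map = dict(mapping.pop("caller", {}) or {})
        cfg = _from_mapping(cls, mapping, "config")
        cfg.simulator = _from_mapping(CohortParams, sim_map, "config.simulator")
        cfg.caller = _from_mapping(CallerParams, caller_map, "config.caller")
        return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return RunConfig.from_dict(data)


def save_config(config: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
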