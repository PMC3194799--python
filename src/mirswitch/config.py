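"""Run configuration: one YAML dialect tying model, protocol and analysis.

A config has exactly one model block (``dimensionless`` or ``dimensional``),
an optional ``protocol`` block, an ``analysis`` selector, numeric settings,
a seed and an output directory.  Unknown keys anywhere are an error — silent
misspellings in a parameter file are how irreproducible figures happen.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import yaml

from .model_core import DimensionalParams, DimensionlessParams
from .stimulus import StimulusProtocol

__all__ = ["RunConfig", "load_config", "dump_config"]

ANALYSES = ("steady", "sweep", "phase", "simulate", "ensemble", "sweep-ensemble")

_NUMERIC_DEFAULTS = {
    "dt": 0.01,
    "sde_dt": 0.002,
    "t_end": 200.0,
    "grid_points": 201,
    "phase_grid": 40,
    "settle_tol": 1e-5,
    "return_tol": 1e-3,
}

_ENSEMBLE_DEFAULTS = {"cells": 200, "transition_rule": "separatrix"}


def _check_keys(block: dict, allowed: set[str], where: str) -> None:
    unknown = set(block) - allowed
    if unknown:
        raise ValueError(f"unknown key(s) {sorted(unknown)} in {where}")


@dataclass
class RunConfig:
    model: DimensionlessParams | DimensionalParams
    analysis: str = "steady"
    protocol: StimulusProtocol | None = None
    numerics: dict = field(default_factory=dict)
    ensemble: dict = field(default_factory=dict)
    sweep: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "out"

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSES:
            raise ValueError(f"analysis must be one of {ANALYSES}")
        merged = dict(_NUMERIC_DEFAULTS)
        merged.update(self.numerics)
        _check_keys(merged, set(_NUMERIC_DEFAULTS), "numerics")
        for key, value in merged.items():
            if key.endswith("_tol") or key in ("dt", "sde_dt", "t_end"):
                if not value > 0:
                    raise ValueError(f"numerics.{key} must be > 0")
        self.numerics = merged
        ens = dict(_ENSEMBLE_DEFAULTS)
        ens.update(self.ensemble)
        _check_keys(ens, set(_ENSEMBLE_DEFAULTS), "ensemble")
        self.ensemble = ens

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {
            "analysis": self.analysis,
            "numerics": dict(self.numerics),
            "ensemble": dict(self.ensemble),
            "seed": self.seed,
            "output_dir": self.output_dir,
        }
        if self.sweep:
            d["sweep"] = dict(self.sweep)
        if isinstance(self.model, DimensionlessParams):
            m = asdict(self.model)
            m["alpha_range"] = list(m["alpha_range"])
            d["model"] = {"dimensionless": m}
        else:
            m = asdict(self.model)
            m["saturation_consts"] = list(m["saturation_consts"])
            d["model"] = {"dimensional": m}
        if self.protocol is not None:
            d["protocol"] = self.protocol.to_dict()
        return d


def _parse_model(block: dict) -> DimensionlessParams | DimensionalParams:
    _check_keys(block, {"dimensionless", "dimensional"}, "model")
    if ("dimensionless" in block) == ("dimensional" in block):
        raise ValueError(
            "model must contain exactly one of 'dimensionless' or 'dimensional'"
        )
    if "dimensionless" in block:
        sub = dict(block["dimensionless"])
        _check_keys(
            sub,
            {"alpha", "beta", "kappa", "gamma", "epsilon", "alpha_range"},
            "model.dimensionless",
        )
        if "alpha_range" in sub:
            sub["alpha_range"] = tuple(float(v) for v in sub["alpha_range"])
        return DimensionlessParams(**sub)
    sub = dict(block["dimensional"])
    _check_keys(sub, set(DimensionalParams.__dataclass_fields__), "model.dimensional")
    sub["saturation_consts"] = tuple(float(v) for v in sub["saturation_consts"])
    return DimensionalParams(**sub)


def parse_config(data: dict) -> RunConfig:
    _check_keys(
        data,
        {"model", "analysis", "protocol", "numerics", "ensemble", "sweep",
         "seed", "output_dir"},
        "config",
    )
    if "model" not in data:
        raise ValueError("config is missing the required 'model' block")
    model = _parse_model(data["model"])
    protocol = (
        StimulusProtocol.from_dict(data["protocol"]) if "protocol" in data else None
    )
    return RunConfig(
        model=model,
        analysis=data.get("analysis", "steady"),
        protocol=protocol,
        numerics=data.get("numerics", {}),
        ensemble=data.get("ensemble", {}),
        sweep=data.get("sweep", {}),
        seed=int(data.get("seed", 0)),
        output_dir=data.get("output_dir", "out"),
    )


def load_config(path) -> RunConfig:
    """Parse and fully validate a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ValueError(f"{path} does not contain a YAML mapping")
    return parse_config(data)


def dump_config(cfg: RunConfig, path) -> None:
    """Write a config back out; load(dump(load(x))) is the identity."""
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
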