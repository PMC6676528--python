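"""Structured run configuration: YAML loading, validation, model building.

One config file describes a whole run.  The ``model`` section defines the
event schedule (or speciation scenario), the optional ``similarity``
section the decay and sd laws of the synthetic generator, and the
optional ``fit`` section the mode-search parameters.  A JSON Schema
describing the format ships with the package (``data/config.schema.json``)
and the same rules are enforced here with path-qualified error messages.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Any, Dict, Optional, Tuple, Union

import yaml

from .mixture_inference import ModeSearchConfig
from .schedule import (
    Branch,
    Event,
    EventSchedule,
    SpeciationScenario,
    SurvivalDistribution,
    ValidationError,
    doubling,
    tripling,
)
from .similarity import DecayModel, SdModel

__all__ = [
    "load_config",
    "build_model",
    "build_decay",
    "build_sd_model",
    "build_mode_config",
    "config_schema",
]


def config_schema() -> Dict[str, Any]:
    """The shipped JSON Schema for run configuration files."""
    text = resources.files("wgdfrac").joinpath("data/config.schema.json").read_text()
    return json.loads(text)


def load_config(path: Union[str, Path]) -> Dict[str, Any]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    if "model" not in cfg:
        raise ValidationError(f"{path}: config requires a 'model' section")
    return cfg


def _require(d: Dict[str, Any], key: str, where: str) -> Any:
    if key not in d:
        raise ValidationError(f"{where}: missing required key {key!r}")
    return d[key]


def _survival_from_spec(spec: Dict[str, Any], where: str, *, default_r: int = 2) -> SurvivalDistribution:
    if "u" in spec:
        u = spec["u"]
        return SurvivalDistribution(len(u) - 1, tuple(float(x) for x in u))
    r = int(spec.get("ploidy", default_r))
    u2 = float(_require(spec, "u2", where))
    u0 = float(spec.get("u0", 0.0))
    if r == 2:
        return doubling(u2, u0)
    if r == 3:
        u3 = spec.get("u3")
        return tripling(u2, None if u3 is None else float(u3), u0)
    raise ValidationError(f"{where}: give the full u vector for ploidy {r}")


def _event_from_spec(spec: Dict[str, Any], where: str) -> Event:
    kind = _require(spec, "kind", where)
    time = float(_require(spec, "time", where))
    if kind == "observation":
        return Event("observation", time)
    if kind == "wgd":
        return Event("wgd", time, _survival_from_spec(spec, where))
    if kind == "speciation":
        if "u" in spec or "u2" in spec:
            return Event("speciation", time, _survival_from_spec(spec, where, default_r=2))
        return Event("speciation", time)
    raise ValidationError(f"{where}: unknown event kind {kind!r}")


def _branch_from_spec(spec: Dict[str, Any], label: str) -> Branch:
    where = f"model.branch_{label.lower()}"
    events = tuple(
        _event_from_spec(e, f"{where}.events[{i}]") for i, e in enumerate(_require(spec, "events", where))
    )
    cs = spec.get("copy_survival")
    return Branch(events, None if cs is None else float(cs), label)


def build_model(cfg: Dict[str, Any]) -> Union[EventSchedule, SpeciationScenario]:
    """Build the schedule or scenario described by the 'model' section."""
    m = cfg["model"] if "model" in cfg else cfg
    mtype = m.get("type", "schedule")
    m1 = int(_require(m, "M1", "model"))
    events = [_event_from_spec(e, f"model.events[{i}]") for i, e in enumerate(_require(m, "events", "model"))]
    if mtype == "schedule":
        return EventSchedule(m1, tuple(events))
    if mtype == "scenario":
        if not events or events[-1].kind != "speciation":
            raise ValidationError("model.events of a scenario must end with the speciation event")
        return SpeciationScenario(
            m1,
            tuple(events[:-1]),
            events[-1],
            _branch_from_spec(_require(m, "branch_a", "model"), "A"),
            _branch_from_spec(_require(m, "branch_b", "model"), "B"),
        )
    raise ValidationError(f"model.type must be 'schedule' or 'scenario', got {mtype!r}")


def build_decay(cfg: Dict[str, Any]) -> DecayModel:
    spec = (cfg.get("similarity") or {}).get("decay") or {}
    return DecayModel(
        amplitude=float(spec.get("amplitude", 1.0)),
        rate=float(spec.get("rate_per_my", 0.009)),
    )


def build_sd_model(cfg: Dict[str, Any]) -> SdModel:
    spec = (cfg.get("similarity") or {}).get("sd") or {}
    return SdModel(
        intercept=float(spec.get("intercept", 0.075)),
        slope=float(spec.get("slope", -0.06)),
    )


def build_mode_config(cfg: Dict[str, Any]) -> ModeSearchConfig:
    spec = cfg.get("fit") or {}
    nc = spec.get("n_components")
    if nc is not None:
        nc = (int(nc), int(nc)) if isinstance(nc, (int, float)) else (int(nc[0]), int(nc[1]))
    return ModeSearchConfig(
        bin_width=float(spec.get("bin_width", 0.01)),
        window=int(spec.get("window", 5)),
        min_prominence=float(spec.get("min_prominence", 0.05)),
        n_components=nc,
    )
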