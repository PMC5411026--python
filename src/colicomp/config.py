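"""YAML run configuration: [model], [inoculum], [scenario], [sweep], [output] sections."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml

from .params import ModelParams, ScenarioMode, ScenarioSpec
from .synthetic import InoculumSpec

__all__ = ["load_config", "run_metadata"]


def load_config(path: str | Path) -> dict:
    """Parse a YAML config into typed objects.

    Returns a dict with keys ``model`` (ModelParams), ``inoculum``
    (InoculumSpec), ``scenario`` (ScenarioSpec), and the raw ``sweep`` and
    ``output`` sections (dicts) if present.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    out: dict = {}
    out["model"] = ModelParams(**raw.get("model", {}))
    out["inoculum"] = InoculumSpec(**raw.get("inoculum", {}))
    scen = raw.get("scenario", {})
    if isinstance(scen, str):
        scen = {"mode": scen}
    mode = ScenarioMode(scen.get("mode", "stochastic"))
    kwargs = {k: v for k, v in scen.items() if k != "mode"}
    out["scenario"] = ScenarioSpec(mode=mode, **kwargs)
    out["sweep"] = raw.get("sweep", {})
    out["output"] = raw.get("output", {})
    return out


def run_metadata(params: ModelParams, scenario: ScenarioSpec | None,
                 inoculum: InoculumSpec | None = None, **extra) -> str:
    """JSON metadata record for one run (parameters, seed, version)."""
    from . import __version__

    payload = {
        "version": __version__,
        "params": dataclasses.asdict(params),
        "scenario": dataclasses.asdict(scenario) if scenario else {"mode": "stochastic"},
    }
    if inoculum is not None:
        payload["inoculum"] = dataclasses.asdict(inoculum)
    payload.update(extra)
    return json.dumps(payload, indent=2, default=str)
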