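"""Configuration loading and structured outputs.

Patients, parameter overrides and dosing regimens are described in YAML or
JSON files; every run writes a JSON manifest (inputs, seed, package
version, wall time) sufficient to reproduce its outputs exactly.
"""

from __future__ import annotations

import json
import platform
import time
from pathlib import Path
from typing import Any, Dict, Mapping

import yaml

from .model_core import ModelState, ParameterSet, PatientParameters, STATE_NAMES
from .pkpd import REGIMEN_TEMPLATES, Regimen, resolve_regimen

__all__ = [
    "load_config",
    "dump_config",
    "load_patient",
    "load_parameters",
    "save_parameters",
    "load_regimen",
    "export_model_description",
    "RunManifest",
]


def load_config(path: str | Path) -> Dict[str, Any]:
    """Load a YAML or JSON mapping (decided by suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ValueError(f"{path}: top level must be a mapping")
    return dict(data)


def dump_config(data: Mapping[str, Any], path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(dict(data), sort_keys=True))


def load_patient(path: str | Path) -> PatientParameters:
    return PatientParameters.from_dict(load_config(path))


def load_parameters(path: str | Path | None = None,
                    overrides: Mapping[str, float] | None = None) -> ParameterSet:
    """Parameter set from an optional file plus inline overrides.

    The file may either map names to numbers or carry a ``parameters`` list
    of ``{name, value, ...}`` records (the format written by
    :func:`save_parameters`). Unknown names raise.
    """
    params = ParameterSet()
    if path is not None:
        data = load_config(path)
        if "parameters" in data:
            params.update({rec["name"]: rec["value"]
                           for rec in data["parameters"]})
        else:
            params.update(data)
    if overrides:
        params.update(overrides)
    return params


def save_parameters(params: ParameterSet, path: str | Path) -> None:
    """Write the full registry (name, value, unit, range, doc) for editing."""
    dump_config({"parameters": params.to_records()}, path)


def load_regimen(name_or_path: str | Path, body_weight: float = 75.0,
                 horizon: float = 456.0) -> Regimen:
    """Regimen from a template name or a YAML/JSON regimen file."""
    if isinstance(name_or_path, str) and name_or_path in REGIMEN_TEMPLATES:
        return resolve_regimen(name_or_path, body_weight, horizon)
    spec = load_config(name_or_path)
    horizon = float(spec.get("horizon", horizon))
    return resolve_regimen(spec, body_weight, horizon)


def export_model_description(model, regimen: Regimen | None = None) -> Dict[str, Any]:
    """Structured JSON description of an assembled model.

    Lists the named state vector, the patient, every parameter with value,
    unit, range and description, the compartment geometry, and the resolved
    dose events — a machine-readable account of the exact system simulated.
    """
    desc: Dict[str, Any] = {
        "model": "checkpoint-blockade QSP, reduced breast-cancer configuration",
        "state_names": list(STATE_NAMES),
        "patient": model.patient.to_dict(),
        "parameters": model.params.to_records(),
        "geometry": {k: getattr(model.geometry, k)
                     for k in ("V_blood", "V_peripheral", "V_tumour_pk", "V_tdln",
                               "n_tdln", "Vv", "Q", "SA_BP", "SA_BT",
                               "K_B", "K_P", "K_T", "K_LN", "k_Lt")},
    }
    if regimen is not None:
        desc["regimen"] = {
            "horizon_day": regimen.horizon,
            "events": [{"drug": e.drug, "time_day": e.time,
                        "amount_mg": e.amount_mg, "route": e.route}
                       for e in regimen.events],
        }
    return desc


class RunManifest:
    """Reproducibility record written next to every CLI output."""

    def __init__(self, command: str, inputs: Mapping[str, Any], seed: int) -> None:
        from . import __version__

        self._t0 = time.monotonic()
        self.data: Dict[str, Any] = {
            "command": command,
            "inputs": dict(inputs),
            "seed": seed,
            "package_version": __version__,
            "python_version": platform.python_version(),
        }

    def write(self, path: str | Path, outputs: Mapping[str, str]) -> None:
        self.data["outputs"] = dict(outputs)
        self.data["wall_time_s"] = round(time.monotonic() - self._t0, 3)
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(json.dumps(self.data, indent=2, sort_keys=True) + "\n")
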