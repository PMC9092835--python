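"""Config loading with unit normalization, tidy CSV writers, run manifests.

The shipped ``model1.yaml`` / ``model2.yaml`` mirror the published parameter
tables row for row (name, value, unit) so the unit conversion performed here
is auditable.  Canonical internal units are milliliter, nanogram and hour;
the mixed liters/milliliters and minutes/hours of the source tables are a
proven hazard, so every conversion is logged.
"""

from __future__ import annotations

import hashlib
import importlib.resources
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ConfigurationError, ModelSpec, SimulationResult

#: unit string (lowercased) -> factor into the canonical system (ml, ng, h)
UNIT_FACTORS = {
    "milliliter": 1.0,
    "liter": 1000.0,
    "nanogram/milliliter": 1.0,
    "milliliter/hour": 1.0,
    "milliliter/minute": 60.0,
    "1/hour": 1.0,
    "1/minute": 60.0,
    "dimensionless": 1.0,
}


@dataclass
class ConfigBundle:
    model: str
    path: str
    rows: list[dict]
    quantities: dict[str, float]       # canonical units
    log: list[str] = field(default_factory=list)
    spec: ModelSpec | None = None
    sha256: str = ""


def _packaged(name: str) -> Path:
    return Path(importlib.resources.files("s100b_pbpk") / "configs" / f"{name}.yaml")


def normalize_rows(rows: list[dict], log: list[str]) -> dict[str, float]:
    """Flatten table rows to canonical-unit quantities keyed by row name.

    A row with an ``of`` field is a per-compartment concentration and is
    keyed ``"<of>.<name>"``.
    """
    out: dict[str, float] = {}
    for i, row in enumerate(rows):
        for req in ("name", "value", "unit"):
            if req not in row:
                raise ConfigurationError(
                    f"row {i} ({row.get('name', '?')!r}): missing field {req!r}")
        unit = str(row["unit"]).strip().lower()
        if unit not in UNIT_FACTORS:
            raise ConfigurationError(
                f"row {i} ({row['name']!r}): unknown unit {row['unit']!r}")
        try:
            value = float(row["value"])
        except (TypeError, ValueError) as exc:
            raise ConfigurationError(
                f"row {i} ({row['name']!r}): non-numeric value") from exc
        key = f"{row['of']}.{row['name']}" if "of" in row else str(row["name"])
        if key in out:
            raise ConfigurationError(f"duplicate quantity {key!r}")
        factor = UNIT_FACTORS[unit]
        out[key] = value * factor
        if factor != 1.0:
            log.append(f"{key}: {value} {row['unit']} -> {value * factor:g} "
                       "(canonical ml/ng/h)")
    return out


def load_config(path_or_model: str | Path) -> ConfigBundle:
    """Load and validate a model config; returns bundle with the wired spec.

    Accepts a file path or one of the packaged names ``model1``/``model2``.
    """
    from .model1 import build_model1
    from .model2 import build_model2

    path = Path(path_or_model)
    if str(path_or_model) in ("model1", "model2"):
        path = _packaged(str(path_or_model))
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = path.read_bytes()
    doc = yaml.safe_load(raw)
    if not isinstance(doc, dict) or "model" not in doc or "quantities" not in doc:
        raise ConfigurationError(
            f"{path}: config must carry 'model' and 'quantities' keys")
    model = doc["model"]
    log: list[str] = []
    quantities = normalize_rows(doc["quantities"], log)
    builders = {"model1": build_model1, "model2": build_model2}
    if model not in builders:
        raise ConfigurationError(f"{path}: unknown model id {model!r}")
    spec = builders[model](quantities, log=log)
    return ConfigBundle(model=model, path=str(path), rows=doc["quantities"],
                        quantities=quantities, log=log, spec=spec,
                        sha256=hashlib.sha256(raw).hexdigest())


def spec_to_rows(bundle: ConfigBundle) -> list[dict]:
    """Round-trip view: the rows as loaded (values and units preserved)."""
    return [dict(r) for r in bundle.rows]


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_timeseries(result: SimulationResult, path: str | Path) -> Path:
    """Tidy CSV: time_h, compartment, concentration_ng_per_ml, amount_ng.

    Compartments in lexicographic order; full float precision so the bundled
    reader round-trips losslessly.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(path, index=False, float_format="%.17g")
    return path


def read_timeseries(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, float_precision="round_trip")
    expected = ["time_h", "compartment", "concentration_ng_per_ml", "amount_ng"]
    if list(frame.columns) != expected:
        raise ConfigurationError(f"{path}: unexpected columns {list(frame.columns)}")
    return frame


def write_manifest(path: str | Path, *, bundle: ConfigBundle | None = None,
                   seed: int | None = None, solver: dict | None = None,
                   events: list | None = None, extra: dict | None = None) -> Path:
    """JSON run manifest sufficient to reproduce the run byte-for-byte."""
    from . import __version__
    manifest = {
        "package_version": __version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "seed": seed,
        "solver": solver or {"method": "BDF", "rtol": 1e-8, "atol": 1e-11},
        "events": [
            {"time_h": e.time, "parameter": e.parameter, "value": e.value}
            for e in (events or [])
        ],
    }
    if bundle is not None:
        manifest["config"] = {"model": bundle.model, "path": bundle.path,
                              "sha256": bundle.sha256,
                              "unit_conversions": bundle.log}
    if extra:
        manifest.update(extra)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
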