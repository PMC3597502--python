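"""Configuration round-tripping and table serialization.

Scenario configs are YAML or JSON documents (auto-detected on load) whose
sections mirror :class:`phagedyn.scenarios.Scenario`.  Unknown keys are
rejected field by field; omitted keys fall back to the dataclass defaults
and the applied defaults are logged.  Trajectories serialize to delimited
text with a fixed column contract: ``time_h, r_ug_ml, B0.., P0.., Mij..,
LY, BP0, BP1``, floats printed with 10 significant digits; the event log
goes to a sibling ``*.events.tsv``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .core import DomainError, ModelParams
from .engine import (
    Simulation,
    SimulationControl,
    TimeSeries,
    TransferSchedule,
)
from .extended import ExtendedParams
from .scenarios import Scenario

__all__ = [
    "ConfigError",
    "scenario_to_dict",
    "scenario_from_dict",
    "load_config",
    "save_config",
    "write_timeseries",
    "read_timeseries",
    "read_table",
]

logger = logging.getLogger("phagedyn")

FLOAT_FORMAT = "%.10g"


class ConfigError(ValueError):
    """A config document failed validation; message lists every problem."""


def _section_to_dict(obj) -> dict:
    return {f.name: getattr(obj, f.name) for f in dataclasses.fields(obj)}


def scenario_to_dict(scenario: Scenario) -> dict:
    doc = {
        "name": scenario.name,
        "note": scenario.note,
        "params": _section_to_dict(scenario.params),
        "initial": {
            "r": scenario.init_r,
            "B": list(scenario.init_B),
            "P": list(scenario.init_P),
        },
        "control": _section_to_dict(scenario.control),
    }
    if scenario.ext_params is not None:
        doc["extended"] = _section_to_dict(scenario.ext_params)
        doc["initial"]["LY"] = scenario.init_LY
        if scenario.init_BP is not None:
            doc["initial"]["BP"] = list(scenario.init_BP)
    if scenario.schedule is not None:
        doc["transfers"] = _section_to_dict(scenario.schedule)
    return doc


def _coerce(value, annotation, section: str, key: str):
    # YAML 1.1 parses exponent floats without a dot ("5e-7") as strings;
    # coerce scalars toward the declared field type.
    if value is None or isinstance(value, (list, tuple, dict, bool)):
        return value
    ann = str(annotation)
    try:
        if "float" in ann and not isinstance(value, float):
            return float(value)
        if ann.startswith("int") and not isinstance(value, int):
            return int(value)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"{section}.{key}: cannot interpret {value!r} ({exc})")
    return value


def _build_section(cls, data: dict, section: str, errors: list[str]):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    for key in sorted(unknown):
        errors.append(f"{section}: unknown key {key!r} (valid: {sorted(fields)})")
    if unknown:
        return None
    try:
        data = {
            k: _coerce(v, fields[k].type, section, k) for k, v in data.items()
        }
    except ConfigError as exc:
        errors.append(str(exc))
        return None
    for name, f in fields.items():
        if name not in data and f.default is not dataclasses.MISSING:
            logger.info("config: %s.%s defaulted to %r", section, name, f.default)
    try:
        return cls(**data)
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return None


def scenario_from_dict(doc: dict) -> Scenario:
    """Validate a config document and build the Scenario it describes."""
    if not isinstance(doc, dict):
        raise ConfigError("config root must be a mapping")
    errors: list[str] = []
    known_top = {"name", "note", "params", "extended", "initial", "control", "transfers"}
    for key in sorted(set(doc) - known_top):
        errors.append(f"unknown top-level key {key!r} (valid: {sorted(known_top)})")

    params = _build_section(ModelParams, doc.get("params", {}), "params", errors)
    control = _build_section(
        SimulationControl, doc.get("control", {}), "control", errors
    )
    ext = None
    if "extended" in doc:
        ext = _build_section(ExtendedParams, doc["extended"], "extended", errors)
    schedule = None
    if "transfers" in doc:
        schedule = _build_section(
            TransferSchedule, doc["transfers"], "transfers", errors
        )

    initial = doc.get("initial", {})
    known_init = {"r", "B", "P", "LY", "BP"}
    for key in sorted(set(initial) - known_init):
        errors.append(f"initial: unknown key {key!r} (valid: {sorted(known_init)})")

    if params is not None and control is not None:
        ratio = params.lam / control.dt
        if abs(ratio - round(ratio)) > 1e-9 * max(1.0, ratio):
            errors.append(
                f"control: latent period lam={params.lam} is not an integer "
                f"multiple of dt={control.dt}"
            )
    if errors:
        raise ConfigError("invalid config:\n  " + "\n  ".join(errors))

    try:
        return Scenario(
            name=str(doc.get("name", "unnamed")),
            params=params,
            control=control,
            init_r=float(initial.get("r", 350.0)),
            init_B=tuple(float(x) for x in initial.get("B", (0.0,) * params.n_orders)),
            init_P=tuple(float(x) for x in initial.get("P", (0.0,) * params.n_phage)),
            ext_params=ext,
            init_LY=float(initial.get("LY", 0.0)),
            init_BP=(
                tuple(float(x) for x in initial["BP"]) if "BP" in initial else None
            ),
            schedule=schedule,
            note=str(doc.get("note", "")),
        )
    except (DomainError, ValueError) as exc:
        raise ConfigError(f"invalid config: {exc}") from exc


def load_config(path: str | Path) -> Scenario:
    """Parse a YAML or JSON scenario config into a validated Scenario."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() == ".json":
            doc = json.loads(text)
        else:
            doc = yaml.safe_load(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    scenario = scenario_from_dict(doc)
    logger.info("loaded scenario %r from %s", scenario.name, path)
    return scenario


def save_config(scenario: Scenario, path: str | Path) -> Path:
    """Serialize a Scenario to YAML (or JSON if the suffix is .json)."""
    path = Path(path)
    doc = scenario_to_dict(scenario)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def write_timeseries(ts: TimeSeries, path: str | Path, fmt: str | None = None) -> Path:
    """Write a trajectory (and its event log) to delimited text."""
    path = Path(path)
    if fmt is None:
        fmt = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise DomainError("format must be 'tsv' or 'csv'")
    sep = "\t" if fmt == "tsv" else ","
    frame = ts.to_frame()
    frame.to_csv(path, sep=sep, index=False, float_format=FLOAT_FORMAT)
    events_path = path.with_suffix(".events.tsv")
    ts.events_frame().to_csv(
        events_path, sep="\t", index=False, float_format=FLOAT_FORMAT
    )
    return path


def read_timeseries(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep)


def read_table(path: str | Path) -> pd.DataFrame:
    """Read a small delimited table, sniffing the separator."""
    return pd.read_csv(path, sep=None, engine="python")


def simulate_to_file(
    scenario: Scenario, out: str | Path, fmt: str | None = None
) -> TimeSeries:
    """Run a scenario and persist the trajectory; logs full provenance."""
    logger.info(
        "simulate: name=%s seed=%d params=%s extended=%s schedule=%s control=%s",
        scenario.name,
        scenario.control.seed,
        _section_to_dict(scenario.params),
        None if scenario.ext_params is None else _section_to_dict(scenario.ext_params),
        None if scenario.schedule is None else _section_to_dict(scenario.schedule),
        _section_to_dict(scenario.control),
    )
    ts = Simulation(scenario).run()
    write_timeseries(ts, out, fmt)
    logger.info(
        "simulate: wrote %d samples, %d events, %d clips to %s",
        len(ts), len(ts.events), ts.meta["clips"], out,
    )
    return ts
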