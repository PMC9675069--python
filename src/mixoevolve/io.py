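"""Scenario configuration, canonical fixtures, and table writers.

A scenario bundles the model constants with analysis settings (temperature
grid, trait-grid size, reference temperature for static runs).  Configs are
YAML or JSON mappings whose keys use the ASCII parameter names
(``rho_max``, ``alpha_max``, ``b``, ``K_B``, ``r``, ``h``, ``I_in``, ``k``,
``l``, ``m_rho``, ``m_alpha``, ``T0_rho``, ``T0_alpha``, ``z``) plus an
optional ``analysis`` block.  Every parameter except the trade-off shape
``z`` may be omitted and defaults to the standard values; ``z`` must always
be stated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .model import ModelParams

__all__ = ["AnalysisSettings", "Scenario", "load_scenario",
           "canonical_scenarios", "write_fixture_files", "write_table"]

_PARAM_KEYS = {f.name for f in fields(ModelParams)}
_FLOAT_FORMAT = "%.12g"


@dataclass(frozen=True)
class AnalysisSettings:
    """Analysis-level settings, all overridable from the config file."""

    T_min: float = 13.0
    T_max: float = 33.0
    T_step: float = 1.0
    trait_grid_n: int = 201
    reference_T: float = 13.0

    def __post_init__(self) -> None:
        if self.T_step <= 0:
            raise ValueError(f"T_step must be positive, got {self.T_step!r}")
        if self.T_max < self.T_min:
            raise ValueError("T_max must not be below T_min")
        if self.trait_grid_n < 3:
            raise ValueError(f"trait_grid_n must be >= 3, got {self.trait_grid_n!r}")

    def temperature_grid(self) -> list[float]:
        grid = []
        T = self.T_min
        while T <= self.T_max + 1e-9:
            grid.append(round(T, 10))
            T += self.T_step
        return grid


@dataclass(frozen=True)
class Scenario:
    params: ModelParams
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)


def _build_scenario(data: dict, source: str) -> Scenario:
    if not isinstance(data, dict):
        raise ValueError(f"{source}: config must be a mapping, got {type(data).__name__}")
    analysis_data = data.pop("analysis", {}) or {}
    unknown = sorted(set(data) - _PARAM_KEYS)
    if unknown:
        raise ValueError(
            f"{source}: unknown parameter keys {unknown}; valid keys are "
            f"{sorted(_PARAM_KEYS)} plus an optional 'analysis' block")
    if "z" not in data:
        raise ValueError(f"{source}: the trade-off shape 'z' must be given "
                         "explicitly (no default curvature is assumed)")
    unknown_a = sorted(set(analysis_data)
                       - {f.name for f in fields(AnalysisSettings)})
    if unknown_a:
        raise ValueError(f"{source}: unknown analysis keys {unknown_a}")
    params = ModelParams(**data)
    analysis = AnalysisSettings(**analysis_data)
    return Scenario(params=params, analysis=analysis)


def load_scenario(path) -> Scenario:
    """Load and validate a YAML/JSON scenario file."""
    path = Path(path)
    text = path.read_text()
    data = yaml.safe_load(text) if path.suffix.lower() not in (".json",) \
        else json.loads(text)
    if data is None:
        data = {}
    return _build_scenario(dict(data), str(path))


def canonical_scenarios() -> dict:
    """The three canonical trade-off scenarios (z = −1, 0, 1) at the default
    resource landscape (K_B = 1e8 cells/cm², I_in = 100)."""
    return {name: Scenario(params=ModelParams(z=z))
            for name, z in (("specialist", -1.0), ("linear", 0.0),
                            ("generalist", 1.0))}


def write_fixture_files(directory) -> list:
    """Write the canonical scenarios as YAML files; returns the paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, scenario in canonical_scenarios().items():
        payload = dataclasses.asdict(scenario.params)
        payload["analysis"] = dataclasses.asdict(scenario.analysis)
        out = directory / f"{name}.yaml"
        out.write_text(yaml.safe_dump(payload, sort_keys=False))
        paths.append(out)
    return paths


def _to_dict(record) -> dict:
    if dataclasses.is_dataclass(record):
        return dataclasses.asdict(record)
    return dict(record)


def _serialize(value):
    if isinstance(value, bool):
        return str(value).lower()
    if isinstance(value, float):
        return _FLOAT_FORMAT % value
    return str(value)


def write_table(records, path, format: str = "csv",
                metadata: dict | None = None, columns=None) -> None:
    """Write homogeneous records as CSV (RFC 4180) or JSON lines.

    Column order follows the first record (or ``columns``, which also allows
    a header-only file for an empty record list); floats are serialized with
    12 significant digits so repeated runs diff clean.  ``metadata`` key/value
    pairs, if given, are prepended as ``#``-prefixed comment lines (CSV) or a
    single header object line (JSON lines).
    """
    records = [_to_dict(r) for r in records]
    path = Path(path)
    if format not in ("csv", "jsonl"):
        raise ValueError(f"format must be 'csv' or 'jsonl', got {format!r}")
    if columns is None and records:
        columns = list(records[0])
    lines = []
    if format == "csv":
        if metadata:
            lines += [f"# {k}: {v}" for k, v in metadata.items()]
        if columns:
            lines.append(",".join(columns))
            for rec in records:
                lines.append(",".join(_serialize(rec[c]) for c in columns))
    else:
        if metadata:
            lines.append(json.dumps({"_metadata": metadata}))
        for rec in records:
            lines.append(json.dumps(
                {k: (float(_FLOAT_FORMAT % v) if isinstance(v, float) else v)
                 for k, v in rec.items()}))
    path.write_text("\n".join(lines) + "\n")
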