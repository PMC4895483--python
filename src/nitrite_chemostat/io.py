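"""Configuration and table IO.

Parameter sets are stored as structured TOML (JSON accepted as an
alternative, chosen by file extension).  Sections mirror the parameter
dataclasses: ``[chemostat]``, ``[catalytic]``, ``[assembly]``, ``[turnover]``
(with a ``[turnover.k_d]`` subtable), ``[nrf_expression]``,
``[nir_expression]``, ``[potential]``, ``[translocation]`` and an optional
``[expression_overrides]`` with ``nrf``/``nir`` constants.  Loading is
strict: unknown keys are rejected and missing keys are reported with their
section.

CSV dialect everywhere: comma separator, "." decimal, UTF-8, mandatory
header row.
"""

from __future__ import annotations

import json
import tomllib
from dataclasses import fields
from pathlib import Path

import pandas as pd

from . import kinetics as kin
from .kinetics import (
    AssemblyParams,
    CatalyticParams,
    ChemostatParams,
    ModelParameters,
    TurnoverParams,
)
from .regulatory import (
    NirExpressionParams,
    NrfExpressionParams,
    PotentialParams,
    TranslocationParams,
)

__all__ = ["load_params", "save_params", "params_to_dict", "params_from_dict",
           "write_scan_csv", "SCAN_COLUMNS"]

_SECTIONS = {
    "chemostat": (ChemostatParams, "chemostat"),
    "catalytic": (CatalyticParams, "catalytic"),
    "assembly": (AssemblyParams, "assembly"),
    "turnover": (TurnoverParams, "turnover"),
    "nrf_expression": (NrfExpressionParams, "nrf_expr"),
    "nir_expression": (NirExpressionParams, "nir_expr"),
    "potential": (PotentialParams, "potential"),
    "translocation": (TranslocationParams, "transloc"),
}

SCAN_COLUMNS = ["s_mM", "u_mM", "w_uM", "J_nrfA", "J_import", "J_export",
                "J_nirB", "J_total", "J_population", "residual", "converged"]


def params_to_dict(params: ModelParameters) -> dict:
    out: dict = {"name": params.name}
    for section, (cls, attr) in _SECTIONS.items():
        block = getattr(params, attr)
        out[section] = {f.name: getattr(block, f.name) for f in fields(cls)}
    overrides = {}
    if params.nrf_expr_const is not None:
        overrides["nrf"] = params.nrf_expr_const
    if params.nir_expr_const is not None:
        overrides["nir"] = params.nir_expr_const
    if overrides:
        out["expression_overrides"] = overrides
    return out


def _build_section(section: str, cls, data: dict):
    if not isinstance(data, dict):
        raise ValueError(f"section [{section}] must be a table")
    expected = {f.name for f in fields(cls)}
    unknown = set(data) - expected
    if unknown:
        raise ValueError(f"unknown key {sorted(unknown)[0]!r} in section [{section}]")
    missing = expected - set(data)
    if missing:
        raise ValueError(f"missing required key {sorted(missing)[0]!r} in section [{section}]")
    vals = {}
    for k, v in data.items():
        if k == "k_d":
            if not isinstance(v, dict):
                raise ValueError("turnover.k_d must be a table of species -> rate")
            vals[k] = {sp: float(r) for sp, r in v.items()}
        else:
            vals[k] = float(v)
    return cls(**vals)


def params_from_dict(data: dict) -> ModelParameters:
    data = dict(data)
    name = data.pop("name", "unnamed")
    overrides = data.pop("expression_overrides", {})
    if set(overrides) - {"nrf", "nir"}:
        raise ValueError("expression_overrides accepts only 'nrf' and 'nir' keys")
    blocks = {}
    for section, (cls, attr) in _SECTIONS.items():
        if section not in data:
            raise ValueError(f"missing required section [{section}]")
        blocks[attr] = _build_section(section, cls, data.pop(section))
    if data:
        raise ValueError(f"unknown section [{sorted(data)[0]}]")
    params = ModelParameters(
        name=str(name),
        nrf_expr_const=float(overrides["nrf"]) if "nrf" in overrides else None,
        nir_expr_const=float(overrides["nir"]) if "nir" in overrides else None,
        **blocks,
    )
    report = kin.validate_params(params)
    if report:
        raise ValueError("invalid parameter file: " + "; ".join(report))
    return params


def load_params(path: str | Path) -> ModelParameters:
    """Load a parameter file (TOML, or JSON for ``.json`` paths)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text())
    else:
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
    return params_from_dict(data)


def _toml_value(v) -> str:
    if isinstance(v, str):
        return json.dumps(v)
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _dump_toml(data: dict) -> str:
    lines = []
    for k, v in data.items():
        if not isinstance(v, dict):
            lines.append(f"{k} = {_toml_value(v)}")
    for k, v in data.items():
        if isinstance(v, dict):
            lines.append(f"\n[{k}]")
            for k2, v2 in v.items():
                if isinstance(v2, dict):
                    continue
                lines.append(f"{k2} = {_toml_value(v2)}")
            for k2, v2 in v.items():
                if isinstance(v2, dict):
                    lines.append(f"\n[{k}.{k2}]")
                    for k3, v3 in v2.items():
                        lines.append(f"{k3} = {_toml_value(v3)}")
    return "\n".join(lines) + "\n"


def save_params(params: ModelParameters, path: str | Path) -> None:
    """Serialize ``params`` losslessly (floats via repr round-trip)."""
    report = kin.validate_params(params)
    if report:
        raise ValueError("refusing to save invalid parameters: " + "; ".join(report))
    path = Path(path)
    data = params_to_dict(params)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(_dump_toml(data))


def write_scan_csv(scan_result, path: str | Path) -> None:
    """Write a ScanResult with the documented column list."""
    df = scan_result.to_frame()
    df = df[SCAN_COLUMNS]
    df.to_csv(path, index=False)


def read_expression_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"u_mM", "activity", "operon"}
    if not required <= set(df.columns):
        raise ValueError(f"expression CSV must have columns {sorted(required)}")
    return df


def read_accumulation_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"s_mM", "u_star_mM"}
    if not required <= set(df.columns):
        raise ValueError(f"accumulation CSV must have columns {sorted(required)}")
    return df
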