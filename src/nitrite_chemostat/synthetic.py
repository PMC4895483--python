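"""Synthetic datasets with the statistical structure the analysis assumes.

The study's chemostat and expression measurements are not numerically
tabulated, so the pipeline is exercised on generated stand-ins: a unimodal
*nrf* activity curve peaking at sub-millimolar nitrite, a monotone
saturating *nir* curve rising in the millimolar range, and an accumulation
curve u*(s) <= s produced by the package's own steady-state scan.  Noise is
multiplicative lognormal (activities and concentrations are positive);
every generator is a pure function of (parameters, grid, sigma, seed).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .calibration import AccumulationDataset, ExpressionDataset
from .kinetics import ModelParameters
from .regulatory import NirExpressionParams, NrfExpressionParams, eval_m_nir, eval_m_nrf
from .steady_state import scan

__all__ = [
    "gen_expression_dataset",
    "gen_accumulation_dataset",
    "default_fixture_bundle",
    "DEFAULT_U_GRID",
    "DEFAULT_S_DATA_GRID",
    "NOISE_SD_DEFAULT",
]

#: 20 nitrite levels spanning the activation and repression ranges (mM).
DEFAULT_U_GRID = np.round(np.concatenate([[0.0], np.geomspace(0.02, 5.0, 19)]), 6)
#: 15 added-nitrite levels for accumulation fixtures (mM).
DEFAULT_S_DATA_GRID = np.round(np.geomspace(0.05, 7.0, 15), 6)
NOISE_SD_DEFAULT = 0.05

GENERATOR_VERSION = "1"


def gen_expression_dataset(
    true_nrf: NrfExpressionParams,
    true_nir: NirExpressionParams,
    u_grid: np.ndarray = DEFAULT_U_GRID,
    noise_sd: float = NOISE_SD_DEFAULT,
    seed: int = 0,
) -> ExpressionDataset:
    """Activities = Hill value x exp(N(0, sigma)) on ``u_grid``, both operons."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    u_grid = np.asarray(u_grid, dtype=float)
    if u_grid.size == 0:
        raise ValueError("u_grid must not be empty")
    rng = np.random.default_rng(seed)
    a_nrf = np.asarray(eval_m_nrf(u_grid, true_nrf)) * np.exp(
        rng.normal(0.0, noise_sd, size=u_grid.shape))
    a_nir = np.asarray(eval_m_nir(u_grid, true_nir)) * np.exp(
        rng.normal(0.0, noise_sd, size=u_grid.shape))
    return ExpressionDataset(
        u=np.concatenate([u_grid, u_grid]),
        activity=np.concatenate([a_nrf, a_nir]),
        operon=np.array(["nrf"] * len(u_grid) + ["nir"] * len(u_grid), dtype=object),
    )


def gen_accumulation_dataset(
    true_params: ModelParameters,
    s_grid: np.ndarray = DEFAULT_S_DATA_GRID,
    noise_sd: float = NOISE_SD_DEFAULT,
    seed: int = 0,
) -> AccumulationDataset:
    """u* from a steady-state scan of ``true_params`` with multiplicative
    lognormal noise, clipped rowwise to [0, s]."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    s_grid = np.asarray(s_grid, dtype=float)
    sc = scan(true_params, s_grid)
    rng = np.random.default_rng(seed)
    u_star = sc.u * np.exp(rng.normal(0.0, noise_sd, size=s_grid.shape))
    u_star = np.clip(u_star, 0.0, s_grid)
    return AccumulationDataset(
        s_added=s_grid,
        u_star=u_star,
        meta={"noise_model": "multiplicative-lognormal", "noise_sd": noise_sd, "seed": seed},
    )


def default_fixture_bundle(seed: int, out_dir: str | Path) -> dict:
    """Write the canonical CSV fixture set and its manifest.

    Uses the committed default parameters as generating truth.  Returns the
    manifest dict.  Regeneration with the same seed is byte-identical.
    """
    from .defaults import default_params
    from .io import params_to_dict

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = default_params()

    expr = gen_expression_dataset(
        params.nrf_expr, params.nir_expr, DEFAULT_U_GRID, NOISE_SD_DEFAULT, seed)
    acc = gen_accumulation_dataset(params, DEFAULT_S_DATA_GRID, NOISE_SD_DEFAULT, seed + 1)

    expr.to_frame().to_csv(out / "expression.csv", index=False)
    acc.to_frame().to_csv(out / "accumulation.csv", index=False)

    manifest = {
        "generator_version": GENERATOR_VERSION,
        "seed": int(seed),
        "noise_model": "multiplicative-lognormal",
        "noise_sd": NOISE_SD_DEFAULT,
        "u_grid_mM": [float(x) for x in DEFAULT_U_GRID],
        "s_grid_mM": [float(x) for x in DEFAULT_S_DATA_GRID],
        "generating_parameters": params_to_dict(params),
        "files": ["expression.csv", "accumulation.csv"],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
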