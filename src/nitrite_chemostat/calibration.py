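"""Fitting the regulatory inputs and calibrating kinetic parameters.

Two fitting problems:

* ``fit_expression_params`` -- least-squares fit of the generalized-Hill
  expression efficiencies to (nitrite, relative activity) data, one operon
  at a time.  The objective is non-convex (products/sums of Hill terms), so
  a multi-start gradient descent is used: positive parameters are
  log-transformed and each restart runs a trust-region reflective
  least-squares solve from a log-uniform random start within bounds.
* ``calibrate_kinetics`` -- adapts free kinetic parameters of the full model
  to a steady-state accumulation curve u*(s); every objective evaluation
  runs a continuation scan of positive stationary points over the data's
  ``s`` values.

Both are deterministic given a seed.  Objectives are unweighted sums of
squared residuals on the natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .kinetics import ModelParameters
from .regulatory import NirExpressionParams, NrfExpressionParams, eval_m_nir, eval_m_nrf
from .steady_state import ScanError, scan

__all__ = [
    "ExpressionDataset",
    "AccumulationDataset",
    "FitResult",
    "fit_expression_params",
    "calibrate_kinetics",
    "get_param",
    "set_params",
]

MIN_POINTS_PER_OPERON = 6

_NRF_FIELDS = [f.name for f in fields(NrfExpressionParams)]
_NIR_FIELDS = [f.name for f in fields(NirExpressionParams)]

#: Default search bounds for Hill parameters: fold-changes, half-effect
#: constants (mM) and exponents.
DEFAULT_EXPR_BOUNDS = {"delta": (1e-3, 1e3), "K": (1e-3, 50.0), "h": (0.3, 20.0)}


@dataclass
class ExpressionDataset:
    """Rows of (u, relative activity) tagged by operon ('nrf' or 'nir')."""

    u: np.ndarray
    activity: np.ndarray
    operon: np.ndarray

    def __post_init__(self):
        self.u = np.asarray(self.u, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.operon = np.asarray(self.operon, dtype=object)
        if not (len(self.u) == len(self.activity) == len(self.operon)):
            raise ValueError("u, activity and operon must have equal length")
        if np.any(self.u < 0):
            raise ValueError("nitrite concentrations u must be >= 0")
        if np.any(self.activity < 0):
            raise ValueError("activities must be >= 0")
        bad = set(self.operon) - {"nrf", "nir"}
        if bad:
            raise ValueError(f"unknown operon tag(s): {sorted(bad)}")

    def subset(self, operon: str) -> tuple[np.ndarray, np.ndarray]:
        mask = self.operon == operon
        return self.u[mask], self.activity[mask]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"u_mM": self.u, "activity": self.activity, "operon": self.operon})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionDataset":
        return cls(df["u_mM"].to_numpy(), df["activity"].to_numpy(), df["operon"].to_numpy())

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExpressionDataset":
        from .io import read_expression_csv

        return cls.from_frame(read_expression_csv(path))


@dataclass
class AccumulationDataset:
    """Steady-state chemostat nitrite u* versus added nitrite s."""

    s_added: np.ndarray
    u_star: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.s_added = np.asarray(self.s_added, dtype=float)
        self.u_star = np.asarray(self.u_star, dtype=float)
        if len(self.s_added) != len(self.u_star):
            raise ValueError("s_added and u_star must have equal length")
        if np.any(self.u_star < 0) or np.any(self.u_star > self.s_added + 1e-12):
            raise ValueError("accumulation data must satisfy 0 <= u* <= s rowwise")

    def sorted(self) -> "AccumulationDataset":
        order = np.argsort(self.s_added)
        return AccumulationDataset(self.s_added[order], self.u_star[order], dict(self.meta))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"s_mM": self.s_added, "u_star_mM": self.u_star})

    @classmethod
    def from_csv(cls, path: str | Path) -> "AccumulationDataset":
        from .io import read_accumulation_csv

        df = read_accumulation_csv(path)
        return cls(df["s_mM"].to_numpy(), df["u_star_mM"].to_numpy())


@dataclass
class FitResult:
    """Outcome of a multi-start fit."""

    params: object
    objective: float
    n_restarts: int
    restart_objectives: list[float]
    converged: list[bool]
    names: list[str] = field(default_factory=list)
    log: list[str] = field(default_factory=list)

    def __post_init__(self):
        finite = [o for o in self.restart_objectives if np.isfinite(o)]
        if finite and self.objective > min(finite) + 1e-12:
            raise ValueError("best objective must be the minimum over restarts")


def _bounds_for(field_names: list[str], bounds: dict) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = [], []
    for n in field_names:
        kind = "delta" if n.startswith("delta") else ("K" if n.startswith("K") else "h")
        b = bounds[kind]
        lo.append(b[0])
        hi.append(b[1])
    return np.array(lo), np.array(hi)


def fit_expression_params(
    data: ExpressionDataset,
    operon: str,
    n_restarts: int = 32,
    seed: int = 0,
    bounds: dict | None = None,
) -> FitResult:
    """Fit the Hill expression efficiency of one operon by multi-start
    log-parameterized least squares.

    Requires at least six data points for the operon and a non-degenerate
    design (not all ``u`` identical).  Returns the best-of-restarts fit.
    """
    if operon not in ("nrf", "nir"):
        raise ValueError("operon must be 'nrf' or 'nir'")
    u, y = data.subset(operon)
    if len(u) < MIN_POINTS_PER_OPERON:
        raise ValueError(
            f"insufficient data: {len(u)} points for operon {operon!r}, "
            f"need >= {MIN_POINTS_PER_OPERON}"
        )
    if np.ptp(u) == 0:
        raise ValueError("degenerate design: all u values identical")

    names = _NRF_FIELDS if operon == "nrf" else _NIR_FIELDS
    cls = NrfExpressionParams if operon == "nrf" else NirExpressionParams
    fn = eval_m_nrf if operon == "nrf" else eval_m_nir
    lo, hi = _bounds_for(names, bounds or DEFAULT_EXPR_BOUNDS)
    log_lo, log_hi = np.log(lo), np.log(hi)

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = cls(**dict(zip(names, np.exp(theta))))
        return np.asarray(fn(u, p)) - y

    rng = np.random.default_rng(seed)
    best = None
    objectives: list[float] = []
    converged: list[bool] = []
    for _ in range(n_restarts):
        theta0 = rng.uniform(log_lo, log_hi)
        try:
            sol = least_squares(
                residuals, theta0, bounds=(log_lo, log_hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
            obj = float(np.sum(sol.fun ** 2))
            objectives.append(obj)
            converged.append(bool(sol.success))
            if best is None or obj < best[0]:
                best = (obj, sol.x)
        except Exception:  # a pathological start: record and move on
            objectives.append(np.inf)
            converged.append(False)
    assert best is not None
    obj, theta = best
    vals = dict(zip(names, np.exp(theta)))
    # both expression forms are symmetric under exchange of their two Hill
    # terms; canonicalize to ascending half-effect constants
    pre = "nrf" if operon == "nrf" else "nir"
    if vals[f"K_{pre}_1"] > vals[f"K_{pre}_2"]:
        for stem in ("delta", "K", "h"):
            a, b = f"{stem}_{pre}_1", f"{stem}_{pre}_2"
            vals[a], vals[b] = vals[b], vals[a]
    fitted = cls(**vals)
    return FitResult(
        params=fitted, objective=obj, n_restarts=n_restarts,
        restart_objectives=objectives, converged=converged, names=list(names),
    )


# -- dotted-path access to nested parameter blocks ---------------------------

def get_param(params: ModelParameters, path: str) -> float:
    block_name, _, leaf = path.partition(".")
    if not leaf:
        raise KeyError(f"parameter path {path!r} must be 'block.field'")
    block = getattr(params, block_name)
    return getattr(block, leaf)


def set_params(params: ModelParameters, updates: dict[str, float]) -> ModelParameters:
    by_block: dict[str, dict[str, float]] = {}
    for path, value in updates.items():
        block_name, _, leaf = path.partition(".")
        if not leaf:
            raise KeyError(f"parameter path {path!r} must be 'block.field'")
        getattr(getattr(params, block_name), leaf)  # raises for unknown names
        by_block.setdefault(block_name, {})[leaf] = float(value)
    for block_name, kv in by_block.items():
        params = replace(params, **{block_name: replace(getattr(params, block_name), **kv)})
    return params


def calibrate_kinetics(
    data: AccumulationDataset,
    base: ModelParameters,
    free: list[str],
    bounds: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    n_restarts: int = 1,
    bound_factor: float = 30.0,
) -> FitResult:
    """Adapt the free kinetic parameters to an accumulation curve.

    ``free`` lists dotted parameter paths (e.g. ``"catalytic.k_cat_nrf"``);
    ``bounds`` maps each to a positive (lo, hi) interval, defaulting to the
    base value divided/multiplied by ``bound_factor``.  The objective is
    sum_i (u*_model(s_i) - u*_data(s_i))^2 with u*_model from a continuation
    scan of positive stationary points; a solver failure at a trial point is
    penalized and logged, never fatal.  Restart 1 starts from the base
    values; further restarts are log-uniform within bounds (seeded).
    """
    if not free:
        raise ValueError("free parameter list must not be empty")
    data = data.sorted()
    s_grid = data.s_added
    if len(s_grid) < 2:
        raise ValueError("need at least two accumulation points")
    if np.any(np.diff(s_grid) <= 0):
        raise ValueError("duplicate s values in accumulation data")

    base_vals = np.array([get_param(base, p) for p in free], dtype=float)
    bounds = dict(bounds or {})
    lo = np.empty(len(free))
    hi = np.empty(len(free))
    for i, p in enumerate(free):
        b = bounds.get(p, (base_vals[i] / bound_factor, base_vals[i] * bound_factor))
        if not (0 < b[0] < b[1]):
            raise ValueError(f"bounds for {p!r} must be positive and ordered, got {b}")
        lo[i], hi[i] = b
        if not (b[0] <= base_vals[i] <= b[1]):
            raise ValueError(
                f"initial value of {p!r} ({base_vals[i]!r}) violates its bounds {b}"
            )
    log_lo, log_hi = np.log(lo), np.log(hi)
    log_entries: list[str] = []

    def residuals(theta: np.ndarray) -> np.ndarray:
        trial = set_params(base, dict(zip(free, np.exp(theta))))
        try:
            sc = scan(trial, s_grid)
        except (ScanError, RuntimeError) as exc:
            log_entries.append(f"penalized trial {np.exp(theta)}: {exc}")
            return np.full(len(s_grid), 1e3)
        return sc.u - data.u_star

    rng = np.random.default_rng(seed)
    starts = [np.log(base_vals)]
    for _ in range(n_restarts - 1):
        starts.append(rng.uniform(log_lo, log_hi))

    best = None
    objectives: list[float] = []
    converged: list[bool] = []
    for theta0 in starts:
        sol = least_squares(
            residuals, theta0, bounds=(log_lo, log_hi), method="trf",
            xtol=1e-12, ftol=1e-12, gtol=1e-12, max_nfev=200,
            diff_step=1e-6,
        )
        obj = float(np.sum(sol.fun ** 2))
        objectives.append(obj)
        converged.append(bool(sol.success))
        if best is None or obj < best[0]:
            best = (obj, sol.x)
    assert best is not None
    obj, theta = best
    calibrated = set_params(base, dict(zip(free, np.exp(theta))))
    calibrated = replace(calibrated, name=f"{base.name}+calibrated")
    return FitResult(
        params=calibrated, objective=obj, n_restarts=len(starts),
        restart_objectives=objectives, converged=converged, names=list(free),
        log=log_entries,
    )
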