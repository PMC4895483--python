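"""Model/Results interface tying the pipeline together.

``NitriteChemostatModel`` holds the observation tables (expression
activities and/or an accumulation curve) together with a base parameter
set; ``fit()`` first fits the Hill expression efficiencies per operon, then
calibrates the requested free kinetic parameters against the accumulation
curve, and returns a ``NitriteChemostatResults`` carrying the calibrated
parameters, the fit diagnostics, steady-state prediction and a ``summary()``
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .calibration import (
    AccumulationDataset,
    ExpressionDataset,
    FitResult,
    calibrate_kinetics,
    fit_expression_params,
    get_param,
)
from .kinetics import ModelParameters, validate_params
from .steady_state import DEFAULT_S_GRID, ScanResult, scan

__all__ = ["NitriteChemostatModel", "NitriteChemostatResults"]

#: Kinetic parameters calibrated by default: the ones the study adjusted to
#: the accumulation data rather than took from direct measurements.
DEFAULT_FREE = ("turnover.ks_nrf", "turnover.ks_nir_C", "catalytic.k_cat_nirC_in")


class NitriteChemostatModel:
    """Nitrite-utilization model bound to observation data.

    Parameters
    ----------
    accumulation : AccumulationDataset, optional
        Steady-state chemostat nitrite u* vs added nitrite s.
    expression : ExpressionDataset, optional
        Relative operon activities vs nitrite.
    params : ModelParameters, optional
        Base parameter set; defaults to the committed calibrated set.
    """

    def __init__(
        self,
        accumulation: AccumulationDataset | None = None,
        expression: ExpressionDataset | None = None,
        params: ModelParameters | None = None,
    ):
        if params is None:
            from .defaults import default_params

            params = default_params()
        report = validate_params(params)
        if report:
            raise ValueError("invalid base parameters: " + "; ".join(report))
        if accumulation is None and expression is None:
            raise ValueError("provide at least one of accumulation/expression data")
        self.accumulation = accumulation
        self.expression = expression
        self.params = params

    @classmethod
    def from_csv(
        cls,
        accumulation_csv: str | Path | None = None,
        expression_csv: str | Path | None = None,
        params: ModelParameters | None = None,
    ) -> "NitriteChemostatModel":
        acc = AccumulationDataset.from_csv(accumulation_csv) if accumulation_csv else None
        expr = ExpressionDataset.from_csv(expression_csv) if expression_csv else None
        return cls(accumulation=acc, expression=expr, params=params)

    def fit(
        self,
        free: tuple[str, ...] = DEFAULT_FREE,
        seed: int = 0,
        n_restarts_expression: int = 32,
        bounds: dict | None = None,
    ) -> "NitriteChemostatResults":
        """Fit expression functions (if expression data is bound) and then
        calibrate ``free`` kinetic parameters (if accumulation data is bound)."""
        from dataclasses import replace

        params = self.params
        expr_fits: dict[str, FitResult] = {}
        if self.expression is not None:
            for operon, attr in (("nrf", "nrf_expr"), ("nir", "nir_expr")):
                fr = fit_expression_params(
                    self.expression, operon, n_restarts=n_restarts_expression, seed=seed)
                expr_fits[operon] = fr
                params = replace(params, **{attr: fr.params})
        kin_fit: FitResult | None = None
        if self.accumulation is not None and free:
            kin_fit = calibrate_kinetics(
                self.accumulation, params, list(free), bounds=bounds, seed=seed)
            params = kin_fit.params
        return NitriteChemostatResults(
            model=self, params=params, expression_fits=expr_fits, kinetic_fit=kin_fit)


@dataclass
class NitriteChemostatResults:
    """Calibrated parameters plus diagnostics and derived analyses."""

    model: NitriteChemostatModel
    params: ModelParameters
    expression_fits: dict[str, FitResult] = field(default_factory=dict)
    kinetic_fit: FitResult | None = None

    def scan(self, s_grid=DEFAULT_S_GRID) -> ScanResult:
        """Steady-state scan under the calibrated parameters."""
        return scan(self.params, s_grid)

    def predict(self, s_grid) -> np.ndarray:
        """Predicted steady-state chemostat nitrite u*(s) (mM)."""
        return self.scan(np.asarray(s_grid, dtype=float)).u

    def resid(self) -> np.ndarray:
        """Residuals u*_model - u*_data on the accumulation grid."""
        if self.model.accumulation is None:
            raise ValueError("no accumulation data bound to the model")
        data = self.model.accumulation.sorted()
        return self.predict(data.s_added) - data.u_star

    def summary(self) -> str:
        lines = []
        w = 68
        lines.append("Nitrite chemostat model calibration".center(w))
        lines.append("=" * w)
        lines.append(f"{'Parameter set:':<28}{self.params.name}")
        if self.model.accumulation is not None:
            lines.append(f"{'Accumulation points:':<28}{len(self.model.accumulation.s_added)}")
        if self.model.expression is not None:
            lines.append(f"{'Expression points:':<28}{len(self.model.expression.u)}")
        for operon, fr in self.expression_fits.items():
            lines.append("-" * w)
            lines.append(f"{operon} expression fit   SSR = {fr.objective:.4g}   "
                         f"restarts = {fr.n_restarts}")
            for n in fr.names:
                lines.append(f"    {n:<22}{getattr(fr.params, n):>14.6g}")
        if self.kinetic_fit is not None:
            fr = self.kinetic_fit
            lines.append("-" * w)
            lines.append(f"kinetic calibration   SSR = {fr.objective:.4g} mM^2   "
                         f"restarts = {fr.n_restarts}")
            for n in fr.names:
                lines.append(f"    {n:<26}{get_param(self.params, n):>14.6g}")
        lines.append("=" * w)
        return "\n".join(lines)

    def plot_accumulation(self, ax=None, s_grid=DEFAULT_S_GRID):
        """Accumulation data (dots) with the model curve; needs matplotlib."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sc = self.scan(s_grid)
        ax.plot(sc.s, sc.u, label="model u*(s)")
        if self.model.accumulation is not None:
            d = self.model.accumulation
            ax.plot(d.s_added, d.u_star, "o", label="data")
        ax.set_xlabel("added nitrite s (mM)")
        ax.set_ylabel("chemostat nitrite u* (mM)")
        ax.legend()
        return ax
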