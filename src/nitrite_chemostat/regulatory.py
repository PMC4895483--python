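"""Phenomenological regulatory inputs of the nitrite-utilization model.

Three generalized-Hill functions drive the kinetic core:

* ``eval_m_nrf`` -- relative expression efficiency of the *nrf* operon as a
  function of chemostat nitrite ``u``.  A product of an activating and a
  repressing Hill factor, so the curve rises at sub-millimolar nitrite and
  falls again in the millimolar range (unimodal).
* ``eval_m_nir`` -- relative expression efficiency of the *nir* operon; a
  two-term rational Hill form that is monotone increasing in the millimolar
  range.
* ``eval_U`` -- the "nominal membrane potential", a bounded unimodal function
  of the *added* nitrite ``s`` standing in for the proton-motive force.  It
  modulates the cytoplasm->periplasm translocation rate of the Nrf subunits
  through ``eval_kt_cp``: kt(s) = kt_cp * (1 + d_U * U(s)).

All functions accept scalars or numpy arrays and are dimensionless except
``eval_kt_cp`` (s^-1).  Concentrations are in mM.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NrfExpressionParams",
    "NirExpressionParams",
    "PotentialParams",
    "TranslocationParams",
    "eval_m_nrf",
    "eval_m_nir",
    "eval_U",
    "eval_kt_cp",
]


def _check_positive(obj, names):
    for n in names:
        v = getattr(obj, n)
        if not np.isfinite(v) or v <= 0:
            raise ValueError(f"{type(obj).__name__}.{n} must be finite and > 0, got {v!r}")


def _check_nonnegative(obj, names):
    for n in names:
        v = getattr(obj, n)
        if not np.isfinite(v) or v < 0:
            raise ValueError(f"{type(obj).__name__}.{n} must be finite and >= 0, got {v!r}")


@dataclass(frozen=True)
class NrfExpressionParams:
    """Parameters of the *nrf* expression efficiency m_Nrf(u).

    ``delta_nrf_1 > 1`` makes the first factor activating, ``delta_nrf_2 < 1``
    makes the second repressing; ``K`` are half-effect constants (mM) and
    ``h`` Hill exponents.
    """

    delta_nrf_1: float
    delta_nrf_2: float
    K_nrf_1: float
    K_nrf_2: float
    h_nrf_1: float
    h_nrf_2: float

    def __post_init__(self):
        _check_positive(self, ["K_nrf_1", "K_nrf_2", "h_nrf_1", "h_nrf_2"])
        _check_nonnegative(self, ["delta_nrf_1", "delta_nrf_2"])


@dataclass(frozen=True)
class NirExpressionParams:
    """Parameters of the *nir* expression efficiency m_Nir(u)."""

    delta_nir_1: float
    delta_nir_2: float
    K_nir_1: float
    K_nir_2: float
    h_nir_1: float
    h_nir_2: float

    def __post_init__(self):
        _check_positive(self, ["K_nir_1", "K_nir_2", "h_nir_1", "h_nir_2"])
        _check_nonnegative(self, ["delta_nir_1", "delta_nir_2"])


@dataclass(frozen=True)
class PotentialParams:
    """Parameters of the nominal membrane potential U(s).

    ``delta_pmf`` is the unsubscripted numerator weight of the second Hill
    term; ``omega_1``/``omega_2`` weight the third term in the denominator/
    numerator, so U(s) -> omega_2/omega_1 as s -> infinity.  ``omega_1 > 0``
    keeps U bounded.
    """

    K_pmf_1: float
    K_pmf_2: float
    K_pmf_3: float
    h_pmf_1: float
    h_pmf_2: float
    h_pmf_3: float
    delta_pmf: float
    omega_1: float
    omega_2: float

    def __post_init__(self):
        _check_positive(
            self,
            ["K_pmf_1", "K_pmf_2", "K_pmf_3", "h_pmf_1", "h_pmf_2", "h_pmf_3", "omega_1"],
        )
        _check_nonnegative(self, ["delta_pmf", "omega_2"])


@dataclass(frozen=True)
class TranslocationParams:
    """Rate constants of NrfA/NrfB shuttling between cytoplasm and periplasm.

    ``kt_nrf_cp`` (s^-1) is the baseline cytoplasm->periplasm rate,
    ``kt_nrf_pc`` (s^-1) the reverse rate, and ``d_U`` (dimensionless) couples
    the forward rate to the nominal potential.
    """

    kt_nrf_cp: float
    kt_nrf_pc: float
    d_U: float

    def __post_init__(self):
        _check_nonnegative(self, ["kt_nrf_cp", "kt_nrf_pc", "d_U"])


def _as_nonnegative(x, name):
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(~np.isfinite(x)):
        raise ValueError(f"{name} must be finite and >= 0")
    return x


def eval_m_nrf(u, p: NrfExpressionParams):
    """Evaluate the *nrf* operon expression efficiency at nitrite ``u`` (mM).

    m_Nrf(u) = [(1 + d1 (u/K1)^h1) / (1 + (u/K1)^h1)]
             * [(1 + d2 (u/K2)^h2) / (1 + (u/K2)^h2)]

    Equals 1 at u = 0 and is strictly positive.
    """
    u = _as_nonnegative(u, "u")
    x1 = (u / p.K_nrf_1) ** p.h_nrf_1
    x2 = (u / p.K_nrf_2) ** p.h_nrf_2
    out = (1.0 + p.delta_nrf_1 * x1) / (1.0 + x1) * (1.0 + p.delta_nrf_2 * x2) / (1.0 + x2)
    return out if out.ndim else float(out)


def eval_m_nir(u, p: NirExpressionParams):
    """Evaluate the *nir* operon expression efficiency at nitrite ``u`` (mM).

    m_Nir(u) = (1 + d1 (u/K1)^h1 + d2 (u/K2)^h2) / (1 + (u/K1)^h1 + (u/K2)^h2)

    Equals 1 at u = 0; tends to d2 as u -> infinity when h2 > h1.
    """
    u = _as_nonnegative(u, "u")
    x1 = (u / p.K_nir_1) ** p.h_nir_1
    x2 = (u / p.K_nir_2) ** p.h_nir_2
    out = (1.0 + p.delta_nir_1 * x1 + p.delta_nir_2 * x2) / (1.0 + x1 + x2)
    return out if out.ndim else float(out)


def eval_U(s, p: PotentialParams):
    """Evaluate the nominal membrane potential at added nitrite ``s`` (mM).

    U(s) = [y1 + delta*y2 + omega_2*y3] / [1 + y1 + y2 + omega_1*y3],
    y_i = (s/K_pmf_i)^h_pmf_i.

    U(0) = 0; U is bounded by max(1, delta_pmf, omega_2/omega_1) and tends to
    omega_2/omega_1 as s -> infinity.
    """
    s = _as_nonnegative(s, "s")
    y1 = (s / p.K_pmf_1) ** p.h_pmf_1
    y2 = (s / p.K_pmf_2) ** p.h_pmf_2
    y3 = (s / p.K_pmf_3) ** p.h_pmf_3
    out = (y1 + p.delta_pmf * y2 + p.omega_2 * y3) / (1.0 + y1 + y2 + p.omega_1 * y3)
    return out if out.ndim else float(out)


def eval_kt_cp(s, tp: TranslocationParams, pp: PotentialParams):
    """Potential-modulated cytoplasm->periplasm translocation rate (s^-1).

    kt(s) = kt_nrf_cp * (1 + d_U * U(s)) >= kt_nrf_cp.
    """
    out = tp.kt_nrf_cp * (1.0 + tp.d_U * np.asarray(eval_U(s, pp)))
    return out if out.ndim else float(out)

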