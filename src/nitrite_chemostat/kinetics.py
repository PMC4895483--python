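"""Kinetic core: state, parameters and right-hand side of the nitrite model.

The model tracks nitrite in a flow chemostat (``u``) and inside the cell
(``w``) together with sixteen protein species: the NirC transporter monomer,
its pentamer and the pentamer's two enzyme-substrate complexes, the NirB/NirD
monomers, NirB2 dimer, NirB2D trimer and its substrate complex, and the Nrf
pathway (cytoplasmic NrfA/NrfB monomers, periplasmic monomers, NrfAB dimer,
NrfA2B2 tetramer and its substrate complex).

Eleven elementary subsystems contribute to the assembled right-hand side:
chemostat flow, periplasmic NrfA reduction, NirC import/export, cytoplasmic
NirB reduction, synthesis, potential-modulated translocation, three complex
assembly subsystems and first-order degradation plus dilution.  Enzymatic
steps use a "disequilibrium" Michaelis-Menten form in which the
enzyme-substrate complex is an explicit state variable and the association
rate is k_dis * (E*S/K_M - ES); K_M is the ratio k_dis/k_assoc of the binding
step.  Bimolecular assembly steps are written as
k_dis * (complex - K_dis^-1 * A * B) so every elementary flux appears with
opposite signs in the species it couples, which makes total-nitrite
bookkeeping close exactly.

Units: concentrations in mM (per compartment volume), time in seconds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import NamedTuple

import numpy as np

from .regulatory import (
    NirExpressionParams,
    NrfExpressionParams,
    PotentialParams,
    TranslocationParams,
    eval_kt_cp,
    eval_m_nir,
    eval_m_nrf,
)

__all__ = [
    "SPECIES",
    "ChemostatParams",
    "CatalyticParams",
    "AssemblyParams",
    "TurnoverParams",
    "ModelParameters",
    "ModelState",
    "FluxDecomposition",
    "rhs",
    "rhs_array",
    "fluxes",
    "validate_params",
    "pack",
    "delta_peripl_range",
]

#: Fixed species order used for arrays, CSV serialization and the solver.
SPECIES = (
    "u", "w",
    "NirC", "NirC5", "NirC5u", "NirC5w",
    "NirB", "NirD", "NirB2", "NirB2D", "NirB2Dw",
    "NrfA_c", "NrfB_c", "NrfA", "NrfB", "NrfAB", "NrfA2B2", "NrfA2B2u",
)

#: Species subject to first-order degradation (ES complexes and nitrite
#: itself are lost through dilution only, as in the assembled system).
DEGRADABLE = (
    "NirC", "NirC5", "NirB", "NirD", "NirB2", "NirB2D",
    "NrfA_c", "NrfB_c", "NrfA", "NrfB", "NrfAB", "NrfA2B2",
)

#: Periplasmic protein species (an order of magnitude more stable than the
#: cytoplasmic pool).
PERIPLASMIC = ("NrfA", "NrfB", "NrfAB", "NrfA2B2")

LN2 = math.log(2.0)
#: Default degradation rate constants: 2 h half-life in the cytoplasm,
#: 20 h for the periplasmic fraction.
KD_CYTOPLASM = LN2 / 7200.0
KD_PERIPLASM = LN2 / 72000.0


def delta_peripl_range(frac_min: float = 0.08, frac_max: float = 0.40) -> tuple[float, float]:
    """Admissible cell-to-periplasm volume ratios for a periplasm occupying
    ``frac_min``..``frac_max`` of the cell volume.

    With the periplasm making 8-40 % of the cell volume the ratio spans
    1/0.40 = 2.5 to 1/0.08 = 12.5.
    """
    if not (0 < frac_min <= frac_max < 1):
        raise ValueError("periplasm volume fractions must satisfy 0 < min <= max < 1")
    return 1.0 / frac_max, 1.0 / frac_min


@dataclass(frozen=True)
class ChemostatParams:
    """Flow-vessel parameters.

    ``kflow`` (s^-1): dilution rate; equals the steady-state specific growth
    rate of the culture.  ``s_added`` (mM): nitrite concentration that would
    establish in the vessel without cells (inflow V_in = kflow * s_added).
    ``C``: cell volume fraction of the chemostat volume.
    """

    kflow: float
    s_added: float
    C: float


@dataclass(frozen=True)
class CatalyticParams:
    """Turnover constants (s^-1), Michaelis constants (mM) and ES-complex
    dissociation rate constants (s^-1) of the four catalytic steps."""

    k_cat_nrf: float
    k_cat_nirB: float
    k_cat_nirC_in: float
    k_cat_nirC_out: float
    K_M_nrf: float
    K_M_nirB: float
    K_M_nirC_in: float
    K_M_nirC_out: float
    k_dis_nrfA2B2u: float
    k_dis_nirB2Dw: float
    k_dis_nirC5u: float
    k_dis_nirC5w: float


@dataclass(frozen=True)
class AssemblyParams:
    """Equilibrium dissociation constants (mM; K_dis_C5 is the fourth root of
    the pentamer rate ratio) and reverse rate constants (s^-1) of the five
    complex-formation reactions."""

    K_dis_AB: float
    K_dis_A2B2: float
    K_dis_B2: float
    K_dis_B2D: float
    K_dis_C5: float
    k_dis_AB: float
    k_dis_A2B2: float
    k_dis_B2: float
    k_dis_B2D: float
    k_dis_C5: float


def _default_kd() -> dict[str, float]:
    kd = {name: KD_CYTOPLASM for name in DEGRADABLE}
    for name in PERIPLASMIC:
        kd[name] = KD_PERIPLASM
    return kd


@dataclass(frozen=True)
class TurnoverParams:
    """Synthesis rate constants (mM/s), per-species degradation constants
    (s^-1) and the cell-to-periplasm volume ratio ``delta_peripl``.

    NrfA and NrfB share one synthesis constant (equimolar translation from
    the *nrf* operon); NirC translation is at least five-fold that of NirB.
    """

    ks_nrf: float
    ks_nir_B: float
    ks_nir_C: float
    ks_nir_D: float
    delta_peripl: float
    k_d: dict[str, float] = field(default_factory=_default_kd)

    def kd_of(self, species: str) -> float:
        return self.k_d.get(species, 0.0)


@dataclass(frozen=True)
class ModelParameters:
    """Complete parameter aggregate for one model version.

    ``nrf_expr_const``/``nir_expr_const`` optionally pin the corresponding
    expression efficiency to a constant (used by the constitutive-*nrf*
    model variant); ``None`` means the Hill function is evaluated.
    """

    chemostat: ChemostatParams
    catalytic: CatalyticParams
    assembly: AssemblyParams
    turnover: TurnoverParams
    nrf_expr: NrfExpressionParams
    nir_expr: NirExpressionParams
    potential: PotentialParams
    transloc: TranslocationParams
    nrf_expr_const: float | None = None
    nir_expr_const: float | None = None
    name: str = "default"

    def m_nrf(self, u):
        if self.nrf_expr_const is not None:
            return self.nrf_expr_const * np.ones_like(np.asarray(u, dtype=float)) \
                if np.ndim(u) else self.nrf_expr_const
        return eval_m_nrf(u, self.nrf_expr)

    def m_nir(self, u):
        if self.nir_expr_const is not None:
            return self.nir_expr_const * np.ones_like(np.asarray(u, dtype=float)) \
                if np.ndim(u) else self.nir_expr_const
        return eval_m_nir(u, self.nir_expr)

    def kt_cp(self, s):
        return eval_kt_cp(s, self.transloc, self.potential)

    def with_s(self, s_added: float) -> "ModelParameters":
        return replace(self, chemostat=replace(self.chemostat, s_added=float(s_added)))


@dataclass
class ModelState:
    """The 18 concentration variables, in mM, in their own compartments."""

    u: float = 0.0
    w: float = 0.0
    NirC: float = 0.0
    NirC5: float = 0.0
    NirC5u: float = 0.0
    NirC5w: float = 0.0
    NirB: float = 0.0
    NirD: float = 0.0
    NirB2: float = 0.0
    NirB2D: float = 0.0
    NirB2Dw: float = 0.0
    NrfA_c: float = 0.0
    NrfB_c: float = 0.0
    NrfA: float = 0.0
    NrfB: float = 0.0
    NrfAB: float = 0.0
    NrfA2B2: float = 0.0
    NrfA2B2u: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in SPECIES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "ModelState":
        y = np.asarray(y, dtype=float)
        if y.shape != (len(SPECIES),):
            raise ValueError(f"state array must have shape ({len(SPECIES)},), got {y.shape}")
        return cls(**dict(zip(SPECIES, (float(v) for v in y))))

    def check_nonnegative(self, tol: float = 0.0):
        for n in SPECIES:
            if getattr(self, n) < -tol:
                raise ValueError(f"state component {n} is negative: {getattr(self, n)}")


@dataclass(frozen=True)
class FluxDecomposition:
    """The per-cell-volume nitrite rates plotted in the flux-decomposition
    analysis (mM/s): periplasmic reduction, NirC import and export,
    cytoplasmic reduction, their NrfA+NirB total, and the population-level
    consumption rate kflow*(s - u)/C."""

    J_nrfA: float
    J_import: float
    J_export: float
    J_nirB: float
    J_total: float
    J_population: float


class PackedParams(NamedTuple):
    """Flat scalar view of ModelParameters for the hot RHS path.

    ``kt_eff`` is precomputed from ``s_added`` since the nominal potential
    depends on the added nitrite, not on the state.
    """

    kflow: float
    s: float
    C: float
    k_cat_nrf: float
    k_cat_nirB: float
    k_cat_in: float
    k_cat_out: float
    KM_nrf: float
    KM_nirB: float
    KM_in: float
    KM_out: float
    kdis_nrfu: float
    kdis_b2dw: float
    kdis_c5u: float
    kdis_c5w: float
    K_AB: float
    K_A2B2: float
    K_B2: float
    K_B2D: float
    K_C5: float
    kdis_AB: float
    kdis_A2B2: float
    kdis_B2: float
    kdis_B2D: float
    kdis_C5: float
    ks_nrf: float
    ks_B: float
    ks_C: float
    ks_D: float
    dp: float
    kt_eff: float
    kt_pc: float
    kd: tuple
    mnrf_const: float
    mnir_const: float
    d1n: float
    d2n: float
    K1n: float
    K2n: float
    h1n: float
    h2n: float
    d1r: float
    d2r: float
    K1r: float
    K2r: float
    h1r: float
    h2r: float


def pack(params: ModelParameters, s: float | None = None) -> PackedParams:
    """Flatten ``params`` for ``rhs_array``; ``s`` overrides the added nitrite."""
    ch, ca, asb, tu = params.chemostat, params.catalytic, params.assembly, params.turnover
    s_val = ch.s_added if s is None else float(s)
    kd = tuple(tu.kd_of(name) for name in SPECIES)
    ne, re_ = params.nrf_expr, params.nir_expr
    return PackedParams(
        kflow=ch.kflow, s=s_val, C=ch.C,
        k_cat_nrf=ca.k_cat_nrf, k_cat_nirB=ca.k_cat_nirB,
        k_cat_in=ca.k_cat_nirC_in, k_cat_out=ca.k_cat_nirC_out,
        KM_nrf=ca.K_M_nrf, KM_nirB=ca.K_M_nirB, KM_in=ca.K_M_nirC_in, KM_out=ca.K_M_nirC_out,
        kdis_nrfu=ca.k_dis_nrfA2B2u, kdis_b2dw=ca.k_dis_nirB2Dw,
        kdis_c5u=ca.k_dis_nirC5u, kdis_c5w=ca.k_dis_nirC5w,
        K_AB=asb.K_dis_AB, K_A2B2=asb.K_dis_A2B2, K_B2=asb.K_dis_B2,
        K_B2D=asb.K_dis_B2D, K_C5=asb.K_dis_C5,
        kdis_AB=asb.k_dis_AB, kdis_A2B2=asb.k_dis_A2B2, kdis_B2=asb.k_dis_B2,
        kdis_B2D=asb.k_dis_B2D, kdis_C5=asb.k_dis_C5,
        ks_nrf=tu.ks_nrf, ks_B=tu.ks_nir_B, ks_C=tu.ks_nir_C, ks_D=tu.ks_nir_D,
        dp=tu.delta_peripl,
        kt_eff=float(params.kt_cp(s_val)), kt_pc=params.transloc.kt_nrf_pc,
        kd=kd,
        mnrf_const=-1.0 if params.nrf_expr_const is None else float(params.nrf_expr_const),
        mnir_const=-1.0 if params.nir_expr_const is None else float(params.nir_expr_const),
        d1n=ne.delta_nrf_1, d2n=ne.delta_nrf_2, K1n=ne.K_nrf_1, K2n=ne.K_nrf_2,
        h1n=ne.h_nrf_1, h2n=ne.h_nrf_2,
        d1r=re_.delta_nir_1, d2r=re_.delta_nir_2, K1r=re_.K_nir_1, K2r=re_.K_nir_2,
        h1r=re_.h_nir_1, h2r=re_.h_nir_2,
    )


def _elementary_fluxes(y, pk: PackedParams):
    """All elementary process rates at state ``y`` (flat array).

    Returns (binding, catalysis, assembly, translocation, synthesis) tuples;
    binding rates are *net association* rates, assembly rates are *net
    formation* rates, so each appears with a + in the product species and a
    - in the reactants.
    """
    (u, w, NirC, NirC5, NirC5u, NirC5w, NirB, NirD, NirB2, NirB2D, NirB2Dw,
     NrfAc, NrfBc, NrfA, NrfB, NrfAB, NrfA2B2, NrfA2B2u) = y

    b_nrf = pk.kdis_nrfu * (u * NrfA2B2 / pk.KM_nrf - NrfA2B2u)
    b_in = pk.kdis_c5u * (u * NirC5 / pk.KM_in - NirC5u)
    b_out = pk.kdis_c5w * (w * NirC5 / pk.KM_out - NirC5w)
    b_nirb = pk.kdis_b2dw * (w * NirB2D / pk.KM_nirB - NirB2Dw)

    cat_nrf = pk.k_cat_nrf * NrfA2B2u
    cat_in = pk.k_cat_in * NirC5u
    cat_out = pk.k_cat_out * NirC5w
    cat_nirb = pk.k_cat_nirB * NirB2Dw

    a_c5 = pk.kdis_C5 * (NirC ** 5 / pk.K_C5 ** 4 - NirC5)
    a_ab = pk.kdis_AB * (NrfA * NrfB / pk.K_AB - NrfAB)
    a_a2b2 = pk.kdis_A2B2 * (NrfAB * NrfAB / pk.K_A2B2 - NrfA2B2)
    a_b2 = pk.kdis_B2 * (NirB * NirB / pk.K_B2 - NirB2)
    a_b2d = pk.kdis_B2D * (NirB2 * NirD / pk.K_B2D - NirB2D)

    t_A = pk.kt_eff * NrfAc - pk.kt_pc * NrfA
    t_B = pk.kt_eff * NrfBc - pk.kt_pc * NrfB

    # Hill terms are evaluated at max(u, 0): fractional powers of transient
    # tiny negative excursions (root-solver trial steps) would otherwise NaN
    up = u if u > 0.0 else 0.0
    if pk.mnrf_const >= 0.0:
        mnrf = pk.mnrf_const
    else:
        x1 = (up / pk.K1n) ** pk.h1n
        x2 = (up / pk.K2n) ** pk.h2n
        mnrf = (1.0 + pk.d1n * x1) / (1.0 + x1) * (1.0 + pk.d2n * x2) / (1.0 + x2)
    if pk.mnir_const >= 0.0:
        mnir = pk.mnir_const
    else:
        x1 = (up / pk.K1r) ** pk.h1r
        x2 = (up / pk.K2r) ** pk.h2r
        mnir = (1.0 + pk.d1r * x1 + pk.d2r * x2) / (1.0 + x1 + x2)

    return (
        (b_nrf, b_in, b_out, b_nirb),
        (cat_nrf, cat_in, cat_out, cat_nirb),
        (a_c5, a_ab, a_a2b2, a_b2, a_b2d),
        (t_A, t_B),
        (pk.ks_nrf * mnrf, pk.ks_B * mnir, pk.ks_C * mnir, pk.ks_D * mnir),
    )


def rhs_array(y: np.ndarray, pk: PackedParams) -> np.ndarray:
    """Time derivative of the flat state vector (mM/s).

    Assembled by summing the per-subsystem contributions: chemostat flow,
    the four disequilibrium catalytic subsystems, synthesis, translocation,
    the three assembly subsystems, and degradation + dilution.
    """
    (b_nrf, b_in, b_out, b_nirb), (cat_nrf, cat_in, cat_out, cat_nirb), \
        (a_c5, a_ab, a_a2b2, a_b2, a_b2d), (t_A, t_B), \
        (syn_nrf, syn_B, syn_C, syn_D) = _elementary_fluxes(y, pk)

    kflow = pk.kflow
    kd = pk.kd
    dy = np.empty(18)
    # chemostat nitrite: inflow/outflow, periplasmic binding and NirC
    # binding remove u (scaled by the cell volume fraction), export returns it
    dy[0] = kflow * (pk.s - y[0]) + pk.C * (-b_nrf - b_in + cat_out)
    # intracellular nitrite: import delivers, export/NirB binding removes
    dy[1] = cat_in - b_out - b_nirb - kflow * y[1]
    # NirC monomer / pentamer / ES complexes
    dy[2] = syn_C - 5.0 * a_c5 - (kd[2] + kflow) * y[2]
    dy[3] = a_c5 + cat_in + cat_out - b_in - b_out - (kd[3] + kflow) * y[3]
    dy[4] = b_in - cat_in - kflow * y[4]
    dy[5] = b_out - cat_out - kflow * y[5]
    # NirB / NirD / dimers / trimer / ES complex
    dy[6] = syn_B - 2.0 * a_b2 - (kd[6] + kflow) * y[6]
    dy[7] = syn_D - a_b2d - (kd[7] + kflow) * y[7]
    dy[8] = a_b2 - a_b2d - (kd[8] + kflow) * y[8]
    dy[9] = a_b2d - b_nirb + cat_nirb - (kd[9] + kflow) * y[9]
    dy[10] = b_nirb - cat_nirb - kflow * y[10]
    # cytoplasmic Nrf monomers
    dy[11] = syn_nrf - t_A - (kd[11] + kflow) * y[11]
    dy[12] = syn_nrf - t_B - (kd[12] + kflow) * y[12]
    # periplasmic monomers (translocation concentrates by delta_peripl)
    dy[13] = pk.dp * t_A - a_ab - (kd[13] + kflow) * y[13]
    dy[14] = pk.dp * t_B - a_ab - (kd[14] + kflow) * y[14]
    # NrfAB dimer, NrfA2B2 tetramer, ES complex
    dy[15] = a_ab - 2.0 * a_a2b2 - (kd[15] + kflow) * y[15]
    dy[16] = a_a2b2 - b_nrf + cat_nrf - (kd[16] + kflow) * y[16]
    dy[17] = b_nrf - cat_nrf - kflow * y[17]
    return dy


def jac_array(y: np.ndarray, pk: PackedParams) -> np.ndarray:
    """Analytic Jacobian d(rhs)/dy of :func:`rhs_array` (18 x 18).

    Every flux term is linear or low-order polynomial in the state, so the
    partials are assembled term-by-term alongside the RHS structure; the
    expression-efficiency derivatives use the closed-form Hill slopes.
    """
    (u, w, NirC, NirC5, NirC5u, NirC5w, NirB, NirD, NirB2, NirB2D, NirB2Dw,
     NrfAc, NrfBc, NrfA, NrfB, NrfAB, NrfA2B2, NrfA2B2u) = y
    kflow = pk.kflow
    kd = pk.kd

    bn_u = pk.kdis_nrfu * NrfA2B2 / pk.KM_nrf
    bn_T = pk.kdis_nrfu * u / pk.KM_nrf
    bi_u = pk.kdis_c5u * NirC5 / pk.KM_in
    bi_5 = pk.kdis_c5u * u / pk.KM_in
    bo_w = pk.kdis_c5w * NirC5 / pk.KM_out
    bo_5 = pk.kdis_c5w * w / pk.KM_out
    bb_w = pk.kdis_b2dw * NirB2D / pk.KM_nirB
    bb_d = pk.kdis_b2dw * w / pk.KM_nirB
    ac_C = pk.kdis_C5 * 5.0 * NirC ** 4 / pk.K_C5 ** 4
    aab_A = pk.kdis_AB * NrfB / pk.K_AB
    aab_B = pk.kdis_AB * NrfA / pk.K_AB
    a2_AB = pk.kdis_A2B2 * 2.0 * NrfAB / pk.K_A2B2
    ab2_B = pk.kdis_B2 * 2.0 * NirB / pk.K_B2
    abd_2 = pk.kdis_B2D * NirD / pk.K_B2D
    abd_D = pk.kdis_B2D * NirB2 / pk.K_B2D

    up = u if u > 0.0 else 0.0
    dmnrf = 0.0
    dmnir = 0.0
    if up > 0.0:
        if pk.mnrf_const < 0.0:
            x1 = (up / pk.K1n) ** pk.h1n
            x2 = (up / pk.K2n) ** pk.h2n
            dx1 = pk.h1n * x1 / up
            dx2 = pk.h2n * x2 / up
            g1 = (1.0 + pk.d1n * x1) / (1.0 + x1)
            g2 = (1.0 + pk.d2n * x2) / (1.0 + x2)
            dmnrf = ((pk.d1n - 1.0) * dx1 / (1.0 + x1) ** 2) * g2 \
                + g1 * ((pk.d2n - 1.0) * dx2 / (1.0 + x2) ** 2)
        if pk.mnir_const < 0.0:
            x1 = (up / pk.K1r) ** pk.h1r
            x2 = (up / pk.K2r) ** pk.h2r
            dx1 = pk.h1r * x1 / up
            dx2 = pk.h2r * x2 / up
            num = 1.0 + pk.d1r * x1 + pk.d2r * x2
            den = 1.0 + x1 + x2
            dmnir = (pk.d1r * dx1 + pk.d2r * dx2) / den - num * (dx1 + dx2) / den ** 2

    J = np.zeros((18, 18))
    # du/dt
    J[0, 0] = -kflow + pk.C * (-bn_u - bi_u)
    J[0, 3] = -pk.C * bi_5
    J[0, 4] = pk.C * pk.kdis_c5u
    J[0, 5] = pk.C * pk.k_cat_out
    J[0, 16] = -pk.C * bn_T
    J[0, 17] = pk.C * pk.kdis_nrfu
    # dw/dt
    J[1, 1] = -bo_w - bb_w - kflow
    J[1, 3] = -bo_5
    J[1, 4] = pk.k_cat_in
    J[1, 5] = pk.kdis_c5w
    J[1, 9] = -bb_d
    J[1, 10] = pk.kdis_b2dw
    # NirC
    J[2, 0] = pk.ks_C * dmnir
    J[2, 2] = -5.0 * ac_C - (kd[2] + kflow)
    J[2, 3] = 5.0 * pk.kdis_C5
    # NirC5
    J[3, 0] = -bi_u
    J[3, 1] = -bo_w
    J[3, 2] = ac_C
    J[3, 3] = -pk.kdis_C5 - bi_5 - bo_5 - (kd[3] + kflow)
    J[3, 4] = pk.k_cat_in + pk.kdis_c5u
    J[3, 5] = pk.k_cat_out + pk.kdis_c5w
    # NirC5u
    J[4, 0] = bi_u
    J[4, 3] = bi_5
    J[4, 4] = -pk.kdis_c5u - pk.k_cat_in - kflow
    # NirC5w
    J[5, 1] = bo_w
    J[5, 3] = bo_5
    J[5, 5] = -pk.kdis_c5w - pk.k_cat_out - kflow
    # NirB
    J[6, 0] = pk.ks_B * dmnir
    J[6, 6] = -2.0 * ab2_B - (kd[6] + kflow)
    J[6, 8] = 2.0 * pk.kdis_B2
    # NirD
    J[7, 0] = pk.ks_D * dmnir
    J[7, 7] = -abd_D - (kd[7] + kflow)
    J[7, 8] = -abd_2
    J[7, 9] = pk.kdis_B2D
    # NirB2
    J[8, 6] = ab2_B
    J[8, 7] = -abd_D
    J[8, 8] = -pk.kdis_B2 - abd_2 - (kd[8] + kflow)
    J[8, 9] = pk.kdis_B2D
    # NirB2D
    J[9, 1] = -bb_w
    J[9, 7] = abd_D
    J[9, 8] = abd_2
    J[9, 9] = -pk.kdis_B2D - bb_d - (kd[9] + kflow)
    J[9, 10] = pk.kdis_b2dw + pk.k_cat_nirB
    # NirB2Dw
    J[10, 1] = bb_w
    J[10, 9] = bb_d
    J[10, 10] = -pk.kdis_b2dw - pk.k_cat_nirB - kflow
    # NrfA_c / NrfB_c
    J[11, 0] = pk.ks_nrf * dmnrf
    J[11, 11] = -pk.kt_eff - (kd[11] + kflow)
    J[11, 13] = pk.kt_pc
    J[12, 0] = pk.ks_nrf * dmnrf
    J[12, 12] = -pk.kt_eff - (kd[12] + kflow)
    J[12, 14] = pk.kt_pc
    # NrfA / NrfB (periplasm)
    J[13, 11] = pk.dp * pk.kt_eff
    J[13, 13] = -pk.dp * pk.kt_pc - aab_A - (kd[13] + kflow)
    J[13, 14] = -aab_B
    J[13, 15] = pk.kdis_AB
    J[14, 12] = pk.dp * pk.kt_eff
    J[14, 13] = -aab_A
    J[14, 14] = -pk.dp * pk.kt_pc - aab_B - (kd[14] + kflow)
    J[14, 15] = pk.kdis_AB
    # NrfAB
    J[15, 13] = aab_A
    J[15, 14] = aab_B
    J[15, 15] = -pk.kdis_AB - 2.0 * a2_AB - (kd[15] + kflow)
    J[15, 16] = 2.0 * pk.kdis_A2B2
    # NrfA2B2
    J[16, 0] = -bn_u
    J[16, 15] = a2_AB
    J[16, 16] = -pk.kdis_A2B2 - bn_T - (kd[16] + kflow)
    J[16, 17] = pk.kdis_nrfu + pk.k_cat_nrf
    # NrfA2B2u
    J[17, 0] = bn_u
    J[17, 16] = bn_T
    J[17, 17] = -pk.kdis_nrfu - pk.k_cat_nrf - kflow
    return J


def _validate_state_array(y: np.ndarray):
    if np.any(~np.isfinite(y)):
        raise ValueError("state contains NaN/Inf")
    if np.any(y < 0):
        bad = [SPECIES[i] for i in np.nonzero(y < 0)[0]]
        raise ValueError(f"state components must be nonnegative; negative: {bad}")


def rhs(state: ModelState, params: ModelParameters, s: float | None = None) -> ModelState:
    """Time derivative of ``state`` under ``params`` (mM/s), as a ModelState.

    Raises for negative state components or non-finite parameters.
    """
    y = state.to_array()
    _validate_state_array(y)
    pk = pack(params, s)
    flat = [v for v in pk if isinstance(v, float)] + list(pk.kd)
    if not all(math.isfinite(v) for v in flat):
        raise ValueError("parameters contain NaN/Inf")
    return ModelState.from_array(rhs_array(y, pk))


def fluxes(state: ModelState, params: ModelParameters, s: float | None = None) -> FluxDecomposition:
    """Catalytic nitrite rates at ``state`` (mM/s per cell volume).

    ``J_population`` is the consumption rate inferred at the population level
    from the chemostat balance, kflow*(s - u)/C.  For a cell-free vessel
    (C = 0) it is undefined and signalled explicitly as NaN.
    """
    y = state.to_array()
    _validate_state_array(y)
    ca = params.catalytic
    ch = params.chemostat
    s_val = ch.s_added if s is None else float(s)
    j_nrf = ca.k_cat_nrf * state.NrfA2B2u
    j_imp = ca.k_cat_nirC_in * state.NirC5u
    j_exp = ca.k_cat_nirC_out * state.NirC5w
    j_nirb = ca.k_cat_nirB * state.NirB2Dw
    if ch.C > 0:
        j_pop = ch.kflow * (s_val - state.u) / ch.C
    else:
        j_pop = math.nan
    return FluxDecomposition(
        J_nrfA=j_nrf, J_import=j_imp, J_export=j_exp, J_nirB=j_nirb,
        J_total=j_nrf + j_nirb, J_population=j_pop,
    )


def _positive(report, label, value):
    if not np.isfinite(value) or value <= 0:
        report.append(f"{label} must be finite and > 0, got {value!r}")


def _nonnegative(report, label, value):
    if not np.isfinite(value) or value < 0:
        report.append(f"{label} must be finite and >= 0, got {value!r}")


def validate_params(params: ModelParameters) -> list[str]:
    """Check every type invariant; returns the list of violations (empty = valid)."""
    rep: list[str] = []
    ch = params.chemostat
    _positive(rep, "chemostat.kflow", ch.kflow)
    _nonnegative(rep, "chemostat.s_added", ch.s_added)
    if not np.isfinite(ch.C) or not (0.0 <= ch.C <= 1.0):
        rep.append(f"chemostat.C must lie in [0, 1], got {ch.C!r}")
    for f in fields(CatalyticParams):
        _positive(rep, f"catalytic.{f.name}", getattr(params.catalytic, f.name))
    for f in fields(AssemblyParams):
        _positive(rep, f"assembly.{f.name}", getattr(params.assembly, f.name))
    tu = params.turnover
    for nm in ("ks_nrf", "ks_nir_B", "ks_nir_C", "ks_nir_D"):
        _nonnegative(rep, f"turnover.{nm}", getattr(tu, nm))
    for sp, v in tu.k_d.items():
        if sp not in SPECIES:
            rep.append(f"turnover.k_d has unknown species {sp!r}")
        else:
            _nonnegative(rep, f"turnover.k_d[{sp}]", v)
    lo, hi = delta_peripl_range()
    if not np.isfinite(tu.delta_peripl) or not (lo <= tu.delta_peripl <= hi):
        rep.append(
            f"turnover.delta_peripl must lie in the admissible {lo}-{hi} range "
            f"(periplasm 8-40 % of cell volume), got {tu.delta_peripl!r}"
        )
    if tu.ks_nir_C < 5.0 * tu.ks_nir_B:
        rep.append(
            "turnover.ks_nir_C must be at least 5x turnover.ks_nir_B "
            f"(NirC translation ratio), got {tu.ks_nir_C!r} < 5*{tu.ks_nir_B!r}"
        )
    # regulatory blocks validate on construction; re-check constants here
    for nm in ("nrf_expr_const", "nir_expr_const"):
        v = getattr(params, nm)
        if v is not None and (not np.isfinite(v) or v < 0):
            rep.append(f"{nm} must be finite and >= 0, got {v!r}")
    return rep
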