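"""Named model variants: parameter-level transformations of a base set.

Each constructor is pure (the base is untouched) and idempotent, and stamps
the variant name into ``ModelParameters.name`` so scans record provenance.

* ``no_potential``: decouples translocation from the membrane potential
  (d_U = 0) and compensates with a 5.5-fold constitutive translocation rate
  (kt_nrf_cp = 0.055 1/s), isolating the purely genetic regulation of the
  periplasmic reductase.
* ``constitutive_nrf``: constitutive *nrf* expression (m_Nrf = 1) with the
  *nir* branch silenced (m_Nir = 0), a reduced shared synthesis constant and
  a re-shaped potential profile; demonstrates that potential-driven
  translocation alone can carry the accumulation curve.
* ``export`` / ``free_intracellular``: a 300-fold tighter export Michaelis
  constant (0.003 mM) with a raised NirC synthesis rate.  The two printed
  override lists name the same constant two ways (the export-binding
  dissociation constant K_dis,NirC5w of the assembled system *is* the
  export K_M), so both constructors produce the same parameter set; they are
  kept separate because they document different claims (high export share
  vs. an order-of-magnitude shift of intracellular nitrite, both leaving the
  accumulation curve intact).
"""

from __future__ import annotations

from dataclasses import replace

from .kinetics import ModelParameters
from .regulatory import PotentialParams

__all__ = [
    "make_no_potential_variant",
    "make_constitutive_nrf_variant",
    "make_export_variant",
    "make_free_intracellular_variant",
    "VARIANTS",
]

NO_POTENTIAL_KT_CP = 0.055  # s^-1; 5.5x the 0.01 s^-1 baseline
CONSTITUTIVE_KS_NRF = 4.5e-6  # mM/s
EXPORT_KM_OUT = 0.003  # mM
EXPORT_KS_NIRC = 1.1e-4  # mM/s


def make_no_potential_variant(base: ModelParameters) -> ModelParameters:
    """Potential-free version: d_U = 0, kt_nrf_cp = 0.055 1/s."""
    return replace(
        base,
        transloc=replace(base.transloc, d_U=0.0, kt_nrf_cp=NO_POTENTIAL_KT_CP),
        name="no_potential",
    )


def make_constitutive_nrf_variant(base: ModelParameters) -> ModelParameters:
    """Constitutive *nrf* expression with the *nir* branch off.

    The printed override list (K1 = 0.11, h1 = 2, delta2 = 0.0375,
    K2 = 0.6, h2 = 8, omega2 = 0.005, K3 = 2.2, h3 = 15) re-shapes the
    potential profile feeding translocation -- the only nitrite-dependent
    input left once expression is constitutive.
    """
    potential = PotentialParams(
        K_pmf_1=0.11, h_pmf_1=2.0,
        K_pmf_2=0.6, h_pmf_2=8.0, delta_pmf=0.0375,
        K_pmf_3=2.2, h_pmf_3=15.0,
        omega_1=base.potential.omega_1, omega_2=0.005,
    )
    return replace(
        base,
        nrf_expr_const=1.0,
        nir_expr_const=0.0,
        turnover=replace(base.turnover, ks_nrf=CONSTITUTIVE_KS_NRF),
        potential=potential,
        name="constitutive_nrf",
    )


def make_export_variant(base: ModelParameters) -> ModelParameters:
    """Tight-export version: K_M_nirC_out = 0.003 mM, ks_nir_C = 1.1e-4 mM/s."""
    return replace(
        base,
        catalytic=replace(base.catalytic, K_M_nirC_out=EXPORT_KM_OUT),
        turnover=replace(base.turnover, ks_nir_C=EXPORT_KS_NIRC),
        name="export",
    )


def make_free_intracellular_variant(base: ModelParameters) -> ModelParameters:
    """Same overrides as the export variant (K_dis,NirC5w = 3 uM is the
    export K_M): leaves u*(s) intact while shifting w*(s) by orders of
    magnitude, showing the intracellular level is a free characteristic."""
    return replace(make_export_variant(base), name="free_intracellular")


VARIANTS = {
    "no_potential": make_no_potential_variant,
    "constitutive_nrf": make_constitutive_nrf_variant,
    "export": make_export_variant,
    "free_intracellular": make_free_intracellular_variant,
}
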