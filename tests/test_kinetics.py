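"""Kinetic core: RHS correctness, conservation bookkeeping, Jacobian."""

from dataclasses import replace

import numpy as np
import pytest

from nitrite_chemostat.kinetics import (
    SPECIES,
    ModelParameters,
    ModelState,
    delta_peripl_range,
    fluxes,
    jac_array,
    pack,
    rhs,
    rhs_array,
    validate_params,
)


def monolithic_rhs(y, pk):
    """Hand-written 18-equation RHS, coded independently of the package's
    subsystem-assembled implementation (the disequilibrium system in full)."""
    (u, w, NirC, NirC5, NirC5u, NirC5w, NirB, NirD, NirB2, NirB2D, NirB2Dw,
     NrfAc, NrfBc, NrfA, NrfB, NrfAB, NrfA2B2, NrfA2B2u) = y
    up = max(u, 0.0) if isinstance(u, (int, float)) else u  # symbolic-safe
    x1, x2 = (up / pk.K1n) ** pk.h1n, (up / pk.K2n) ** pk.h2n
    mnrf = (1 + pk.d1n * x1) / (1 + x1) * (1 + pk.d2n * x2) / (1 + x2) \
        if pk.mnrf_const < 0 else pk.mnrf_const
    z1, z2 = (up / pk.K1r) ** pk.h1r, (up / pk.K2r) ** pk.h2r
    mnir = (1 + pk.d1r * z1 + pk.d2r * z2) / (1 + z1 + z2) \
        if pk.mnir_const < 0 else pk.mnir_const
    kf = pk.kflow
    kt, ktp, dp = pk.kt_eff, pk.kt_pc, pk.dp
    kd = pk.kd
    return np.array([
        kf * (pk.s - u) + pk.C * (
            -pk.kdis_nrfu * (u * NrfA2B2 / pk.KM_nrf - NrfA2B2u)
            - pk.kdis_c5u * (u * NirC5 / pk.KM_in - NirC5u)
            + pk.k_cat_out * NirC5w),
        pk.k_cat_in * NirC5u
        - pk.kdis_c5w * (w * NirC5 / pk.KM_out - NirC5w)
        - pk.kdis_b2dw * (w * NirB2D / pk.KM_nirB - NirB2Dw) - kf * w,
        pk.ks_C * mnir - 5 * pk.kdis_C5 * (NirC ** 5 / pk.K_C5 ** 4 - NirC5)
        - (kd[2] + kf) * NirC,
        pk.kdis_C5 * (NirC ** 5 / pk.K_C5 ** 4 - NirC5)
        + pk.k_cat_in * NirC5u + pk.k_cat_out * NirC5w
        - pk.kdis_c5u * (u * NirC5 / pk.KM_in - NirC5u)
        - pk.kdis_c5w * (w * NirC5 / pk.KM_out - NirC5w) - (kd[3] + kf) * NirC5,
        pk.kdis_c5u * (u * NirC5 / pk.KM_in - NirC5u)
        - (pk.k_cat_in + kf) * NirC5u,
        pk.kdis_c5w * (w * NirC5 / pk.KM_out - NirC5w)
        - (pk.k_cat_out + kf) * NirC5w,
        pk.ks_B * mnir - 2 * pk.kdis_B2 * (NirB ** 2 / pk.K_B2 - NirB2)
        - (kd[6] + kf) * NirB,
        pk.ks_D * mnir - pk.kdis_B2D * (NirB2 * NirD / pk.K_B2D - NirB2D)
        - (kd[7] + kf) * NirD,
        pk.kdis_B2 * (NirB ** 2 / pk.K_B2 - NirB2)
        - pk.kdis_B2D * (NirB2 * NirD / pk.K_B2D - NirB2D) - (kd[8] + kf) * NirB2,
        pk.kdis_B2D * (NirB2 * NirD / pk.K_B2D - NirB2D)
        - pk.kdis_b2dw * (w * NirB2D / pk.KM_nirB - NirB2Dw)
        + pk.k_cat_nirB * NirB2Dw - (kd[9] + kf) * NirB2D,
        pk.kdis_b2dw * (w * NirB2D / pk.KM_nirB - NirB2Dw)
        - (pk.k_cat_nirB + kf) * NirB2Dw,
        pk.ks_nrf * mnrf - (kt * NrfAc - ktp * NrfA) - (kd[11] + kf) * NrfAc,
        pk.ks_nrf * mnrf - (kt * NrfBc - ktp * NrfB) - (kd[12] + kf) * NrfBc,
        dp * (kt * NrfAc - ktp * NrfA)
        - pk.kdis_AB * (NrfA * NrfB / pk.K_AB - NrfAB) - (kd[13] + kf) * NrfA,
        dp * (kt * NrfBc - ktp * NrfB)
        - pk.kdis_AB * (NrfA * NrfB / pk.K_AB - NrfAB) - (kd[14] + kf) * NrfB,
        pk.kdis_AB * (NrfA * NrfB / pk.K_AB - NrfAB)
        - 2 * pk.kdis_A2B2 * (NrfAB ** 2 / pk.K_A2B2 - NrfA2B2) - (kd[15] + kf) * NrfAB,
        pk.kdis_A2B2 * (NrfAB ** 2 / pk.K_A2B2 - NrfA2B2)
        - pk.kdis_nrfu * (u * NrfA2B2 / pk.KM_nrf - NrfA2B2u)
        + pk.k_cat_nrf * NrfA2B2u - (kd[16] + kf) * NrfA2B2,
        pk.kdis_nrfu * (u * NrfA2B2 / pk.KM_nrf - NrfA2B2u)
        - (pk.k_cat_nrf + kf) * NrfA2B2u,
    ])


def random_states(rng, n):
    for _ in range(n):
        y = rng.uniform(0.0, 1e-2, len(SPECIES))
        y[0] = rng.uniform(0, 5)
        y[1] = rng.uniform(0, 0.05)
        yield y


class TestRhs:
    def test_zero_state_only_inflow_survives(self, params):
        p = replace(params, chemostat=replace(params.chemostat, kflow=1e-3, s_added=2.0))
        d = rhs(ModelState(), p)
        assert d.u == pytest.approx(2e-3)
        for name in SPECIES[1:]:
            if name in ("NirC", "NirB", "NirD", "NrfA_c", "NrfB_c"):
                continue  # protein synthesis is always on (m(0) = 1)
            assert getattr(d, name) == pytest.approx(0.0, abs=1e-15)

    def test_assembled_rhs_equals_monolithic_oracle(self, params, rng):
        pk = pack(params, 2.0)
        for y in random_states(rng, 1000):
            got = rhs_array(y, pk)
            want = monolithic_rhs(y, pk)
            np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-18)

    def test_negative_state_rejected(self, params):
        s = ModelState()
        s.u = -1.0
        with pytest.raises(ValueError, match="nonnegative"):
            rhs(s, params)

    def test_nan_params_rejected(self, params):
        bad = replace(params, catalytic=replace(params.catalytic, k_cat_nrf=float("nan")))
        with pytest.raises(ValueError, match="NaN"):
            rhs(ModelState(u=1.0), bad)

    def test_nitrite_bookkeeping_closes(self, params, rng):
        """d/dt of total nitrite equals inflow - outflow - reduction -
        dilution of nitrite-bearing intracellular species, with each side
        computed independently."""
        ch = params.chemostat
        pk = pack(params, 2.0)
        for y in random_states(rng, 200):
            d = rhs_array(y, pk)
            C = ch.C
            # left: total-nitrite derivative assembled from the state derivative
            lhs = d[0] + C * (d[1] + d[4] + d[5] + d[10]) + C * d[17]
            # right: flow and reaction bookkeeping computed from the state
            state = ModelState.from_array(y)
            fl = fluxes(state, params, 2.0)
            rhs_val = (ch.kflow * (2.0 - y[0])
                       - C * (fl.J_nrfA + fl.J_nirB)
                       - C * ch.kflow * (y[1] + y[4] + y[5] + y[10] + y[17]))
            assert lhs == pytest.approx(rhs_val, rel=1e-9, abs=1e-16)

    def test_jacobian_matches_symbolic_derivative(self, params, rng):
        """The hand-coded analytic Jacobian equals the computer-algebra
        derivative of the independently written monolithic RHS."""
        import sympy as sp

        pk = pack(params, 1.5)
        y_sym = sp.symbols("y0:18", positive=True)
        f_sym = sp.Matrix(monolithic_rhs(np.array(y_sym, dtype=object), pk))
        J_sym = sp.lambdify([y_sym], f_sym.jacobian(sp.Matrix(y_sym)), "numpy")
        for y in random_states(rng, 10):
            y = np.maximum(y, 1e-12)  # positive, matching the symbols' domain
            J = jac_array(y, pk)
            J_ref = np.asarray(J_sym(y), dtype=float)
            np.testing.assert_allclose(J, J_ref, rtol=1e-9, atol=1e-12)


def test_nitrite_bookkeeping_symbolic(params):
    """Computer-algebra cross-check: the nitrite-weighted sum of RHS
    components reduces exactly to inflow - outflow - catalysis - dilution."""
    import sympy as sp

    y = sp.symbols("y0:18", nonnegative=True)
    # symbolic pack: replace the s and kt_eff floats with symbols
    pk = pack(params, 1.0)._replace(
        kt_eff=sp.Symbol("kt_eff", positive=True),
        s=sp.Symbol("s", positive=True))
    d = monolithic_rhs(np.array(y, dtype=object), pk)
    C = pk.C
    total = d[0] + C * (d[1] + d[4] + d[5] + d[10]) + C * d[17]
    expected = (pk.kflow * (pk.s - y[0])
                - C * (pk.k_cat_nrf * y[17] + pk.k_cat_nirB * y[10])
                - C * pk.kflow * (y[1] + y[4] + y[5] + y[10] + y[17]))
    diff = sp.expand(total - expected)
    # rate constants enter as floats, so exact cancellation leaves
    # representation-level dust in the coefficients
    residual_coeffs = sp.Poly(diff, *y).coeffs() if diff != 0 else [0]
    assert all(abs(c) < 1e-12 for c in residual_coeffs)


def test_pentamer_subsystem_reaches_mass_action_equilibrium(params):
    """With every other process switched off, integrating the model relaxes
    the NirC pool to the fifth-order equilibrium NirC5 = NirC^5 / K^4."""
    from nitrite_chemostat.steady_state import integrate

    ca = params.catalytic
    off = 1e-300  # positivity is required; effectively zero
    p = replace(
        params,
        chemostat=replace(params.chemostat, kflow=1e-30, s_added=0.0),
        catalytic=replace(ca, k_cat_nrf=off, k_cat_nirB=off,
                          k_cat_nirC_in=off, k_cat_nirC_out=off,
                          k_dis_nrfA2B2u=off, k_dis_nirB2Dw=off,
                          k_dis_nirC5u=off, k_dis_nirC5w=off),
        turnover=replace(params.turnover, ks_nrf=0.0, ks_nir_B=0.0,
                         ks_nir_C=0.0, ks_nir_D=0.0, k_d={}),
    )
    init = ModelState(NirC=0.3)
    final = integrate(p, 0.0, t_end=1e6, init=init).final
    K = params.assembly.K_dis_C5
    expected = final.NirC ** 5 / K ** 4
    assert final.NirC5 == pytest.approx(expected, rel=1e-6)
    # and monomer units are conserved
    assert final.NirC + 5 * final.NirC5 == pytest.approx(0.3, rel=1e-6)


class TestValidation:
    def test_default_params_valid(self, params):
        assert validate_params(params) == []

    def test_delta_peripl_bound_violation_named(self, params):
        bad = replace(params, turnover=replace(params.turnover, delta_peripl=20.0))
        report = validate_params(bad)
        assert any("delta_peripl" in r and "2.5" in r and "12.5" in r for r in report)

    def test_translation_ratio_violation(self, params):
        tu = params.turnover
        bad = replace(params, turnover=replace(tu, ks_nir_C=tu.ks_nir_B))
        report = validate_params(bad)
        assert any("ks_nir_C" in r for r in report)

    def test_delta_peripl_range_arithmetic(self):
        lo, hi = delta_peripl_range(0.08, 0.40)
        assert lo == pytest.approx(2.5)
        assert hi == pytest.approx(12.5)


class TestModelState:
    def test_array_round_trip(self, rng):
        y = rng.uniform(0, 1, len(SPECIES))
        s = ModelState.from_array(y)
        np.testing.assert_array_equal(s.to_array(), y)

    def test_species_order_documented(self):
        assert SPECIES[0] == "u" and SPECIES[1] == "w"
        assert len(SPECIES) == 18
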