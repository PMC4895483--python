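"""The phenomenological Hill inputs: printed-formula fidelity and limits."""

import numpy as np
import pytest

from nitrite_chemostat.regulatory import (
    NirExpressionParams,
    NrfExpressionParams,
    PotentialParams,
    TranslocationParams,
    eval_U,
    eval_kt_cp,
    eval_m_nir,
    eval_m_nrf,
)

from conftest import (
    random_nir_params,
    random_nrf_params,
    random_potential_params,
    random_transloc_params,
)


# independent one-line re-implementations of the printed formulas, kept
# deliberately separate from the library code
def _oracle_m_nrf(u, d1, d2, K1, K2, h1, h2):
    return ((1 + d1 * (u / K1) ** h1) / (1 + (u / K1) ** h1)
            * (1 + d2 * (u / K2) ** h2) / (1 + (u / K2) ** h2))


def _oracle_m_nir(u, d1, d2, K1, K2, h1, h2):
    return ((1 + d1 * (u / K1) ** h1 + d2 * (u / K2) ** h2)
            / (1 + (u / K1) ** h1 + (u / K2) ** h2))


def _oracle_U(s, K1, K2, K3, h1, h2, h3, delta, w1, w2):
    y1, y2, y3 = (s / K1) ** h1, (s / K2) ** h2, (s / K3) ** h3
    return (y1 + delta * y2 + w2 * y3) / (1 + y1 + y2 + w1 * y3)


NRF_EXAMPLE = NrfExpressionParams(delta_nrf_1=6.0, delta_nrf_2=0.03, K_nrf_1=0.15,
                                  K_nrf_2=1.6, h_nrf_1=2.0, h_nrf_2=6.0)
NIR_EXAMPLE = NirExpressionParams(delta_nir_1=2.0, delta_nir_2=40.0, K_nir_1=0.5,
                                  K_nir_2=3.0, h_nir_1=1.5, h_nir_2=4.0)


class TestExpressionEfficiencies:
    def test_equal_one_at_zero_nitrite(self, rng):
        for _ in range(50):
            assert eval_m_nrf(0.0, random_nrf_params(rng)) == pytest.approx(1.0)
            assert eval_m_nir(0.0, random_nir_params(rng)) == pytest.approx(1.0)

    def test_identity_fold_changes_give_unity(self):
        p = NrfExpressionParams(1.0, 1.0, 0.3, 2.0, 2.0, 4.0)
        u = np.linspace(0, 10, 31)
        assert np.allclose(eval_m_nrf(u, p), 1.0)

    def test_nrf_example_matches_direct_arithmetic(self):
        got = eval_m_nrf(0.15, NRF_EXAMPLE)
        want = _oracle_m_nrf(0.15, 6.0, 0.03, 0.15, 1.6, 2.0, 6.0)
        assert got == pytest.approx(want, rel=1e-14)
        assert got == pytest.approx(3.5 * (1 + 0.03 * (0.15 / 1.6) ** 6)
                                    / (1 + (0.15 / 1.6) ** 6), rel=1e-12)

    def test_nir_example_matches_direct_arithmetic(self):
        got = eval_m_nir(3.0, NIR_EXAMPLE)
        want = _oracle_m_nir(3.0, 2.0, 40.0, 0.5, 3.0, 1.5, 4.0)
        assert got == pytest.approx(want, rel=1e-14)

    def test_nir_dominant_exponent_limit(self):
        # with h2 > h1 the second term dominates: m_nir -> delta_nir_2
        assert eval_m_nir(1e6, NIR_EXAMPLE) == pytest.approx(40.0, rel=1e-3)

    def test_negative_nitrite_rejected(self):
        with pytest.raises(ValueError):
            eval_m_nrf(-0.1, NRF_EXAMPLE)
        with pytest.raises(ValueError):
            eval_m_nir(-0.1, NIR_EXAMPLE)

    def test_positive_everywhere(self, rng):
        u = np.geomspace(1e-4, 50, 40)
        for _ in range(20):
            assert np.all(eval_m_nrf(u, random_nrf_params(rng)) > 0)
            assert np.all(eval_m_nir(u, random_nir_params(rng)) > 0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            NrfExpressionParams(6.0, 0.03, -0.15, 1.6, 2.0, 6.0)
        with pytest.raises(ValueError):
            NirExpressionParams(-1.0, 40.0, 0.5, 3.0, 1.5, 4.0)


class TestNominalPotential:
    def test_zero_at_zero(self, rng):
        for _ in range(20):
            assert eval_U(0.0, random_potential_params(rng)) == 0.0

    def test_large_s_limit_is_omega_ratio(self, params):
        pp = params.potential
        assert eval_U(1e8, pp) == pytest.approx(pp.omega_2 / pp.omega_1, rel=1e-2)

    def test_bounded_on_dense_grid(self, rng):
        s = np.concatenate([[0.0], np.geomspace(1e-4, 1e3, 500)])
        for _ in range(30):
            pp = random_potential_params(rng)
            bound = max(1.0, pp.delta_pmf, pp.omega_2 / pp.omega_1)
            vals = eval_U(s, pp)
            assert np.all(vals <= bound + 1e-12)
            assert np.all(vals >= 0)

    def test_default_profile_peaks_between_point1_and_1_mM(self, params):
        s = np.geomspace(0.01, 10, 2000)
        vals = np.asarray(eval_U(s, params.potential))
        s_max = s[np.argmax(vals)]
        assert 0.1 <= s_max <= 1.0

    def test_negative_s_rejected(self, params):
        with pytest.raises(ValueError):
            eval_U(-1.0, params.potential)


class TestTranslocationRate:
    def test_zero_coupling_returns_baseline(self, params):
        tp = TranslocationParams(kt_nrf_cp=0.01, kt_nrf_pc=0.001, d_U=0.0)
        s = np.geomspace(0.01, 7, 20)
        assert np.allclose(eval_kt_cp(s, tp, params.potential), 0.01)

    def test_zero_s_returns_baseline(self, params):
        assert eval_kt_cp(0.0, params.transloc, params.potential) == pytest.approx(
            params.transloc.kt_nrf_cp)

    def test_affine_form_hand_arithmetic(self):
        # kt_cp * (1 + d_U * U) = 0.01 * (1 + 9 * 0.5) = 0.055
        pp = PotentialParams(K_pmf_1=1.0, K_pmf_2=1.0, K_pmf_3=1.0, h_pmf_1=1.0,
                             h_pmf_2=1.0, h_pmf_3=1.0, delta_pmf=1.0,
                             omega_1=1.0, omega_2=1.0)
        # this parameterization gives U(s) = 3x/(1+3x) -> U(1)=0.75; pick s with U=0.5
        s = 1.0 / 3.0
        assert eval_U(s, pp) == pytest.approx(0.5)
        tp = TranslocationParams(kt_nrf_cp=0.01, kt_nrf_pc=0.001, d_U=9.0)
        assert eval_kt_cp(s, tp, pp) == pytest.approx(0.055)

    def test_monotone_in_coupling_coefficient(self, params, rng):
        s = 0.4
        prev = -np.inf
        for d_U in np.linspace(0, 20, 15):
            tp = TranslocationParams(kt_nrf_cp=0.01, kt_nrf_pc=0.001, d_U=d_U)
            val = eval_kt_cp(s, tp, params.potential)
            assert val >= prev
            prev = val

    def test_at_least_baseline(self, rng):
        for _ in range(30):
            tp = random_transloc_params(rng)
            pp = random_potential_params(rng)
            s = rng.uniform(0, 10)
            assert eval_kt_cp(s, tp, pp) >= tp.kt_nrf_cp - 1e-15


class TestPropertyBased:
    """Hypothesis sweeps over admissible parameters (derandomized)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    pos = st.floats(0.01, 10.0, allow_nan=False)
    fold = st.floats(0.0, 50.0, allow_nan=False)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(d1=fold, d2=fold, K1=pos, K2=pos, h1=st.floats(0.5, 8.0), h2=st.floats(0.5, 8.0),
           u=st.floats(0.0, 20.0))
    def test_expression_unity_at_zero_and_positive(self, d1, d2, K1, K2, h1, h2, u):
        p = NrfExpressionParams(d1, d2, K1, K2, h1, h2)
        q = NirExpressionParams(d1, d2, K1, K2, h1, h2)
        assert eval_m_nrf(0.0, p) == pytest.approx(1.0)
        assert eval_m_nir(0.0, q) == pytest.approx(1.0)
        assert eval_m_nrf(u, p) > 0
        assert eval_m_nir(u, q) > 0

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(K1=pos, K2=pos, K3=pos, h1=st.floats(0.5, 8.0), h2=st.floats(0.5, 8.0),
           h3=st.floats(0.5, 8.0), delta=st.floats(0.0, 5.0), w1=st.floats(0.1, 50.0),
           w2=st.floats(0.0, 5.0), s=st.floats(0.0, 100.0))
    def test_potential_bounded_nonnegative(self, K1, K2, K3, h1, h2, h3, delta, w1, w2, s):
        p = PotentialParams(K_pmf_1=K1, K_pmf_2=K2, K_pmf_3=K3, h_pmf_1=h1,
                            h_pmf_2=h2, h_pmf_3=h3, delta_pmf=delta,
                            omega_1=w1, omega_2=w2)
        val = eval_U(s, p)
        assert 0.0 <= val <= max(1.0, delta, w2 / w1) + 1e-12


def test_all_formulas_match_oracles_on_random_pairs(rng):
    """Library evaluations agree with independent re-implementations to
    machine precision on 1000 random (parameter, input) pairs."""
    for _ in range(1000):
        u = rng.uniform(0, 10)
        which = rng.integers(3)
        if which == 0:
            p = random_nrf_params(rng)
            assert eval_m_nrf(u, p) == pytest.approx(_oracle_m_nrf(
                u, p.delta_nrf_1, p.delta_nrf_2, p.K_nrf_1, p.K_nrf_2,
                p.h_nrf_1, p.h_nrf_2), rel=1e-13)
        elif which == 1:
            p = random_nir_params(rng)
            assert eval_m_nir(u, p) == pytest.approx(_oracle_m_nir(
                u, p.delta_nir_1, p.delta_nir_2, p.K_nir_1, p.K_nir_2,
                p.h_nir_1, p.h_nir_2), rel=1e-13)
        else:
            p = random_potential_params(rng)
            assert eval_U(u, p) == pytest.approx(_oracle_U(
                u, p.K_pmf_1, p.K_pmf_2, p.K_pmf_3, p.h_pmf_1, p.h_pmf_2,
                p.h_pmf_3, p.delta_pmf, p.omega_1, p.omega_2), rel=1e-13, abs=1e-15)
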