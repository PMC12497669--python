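"""Forward-model correctness: convolution recursion, tissue models, identities."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renoperf import (
    Curve,
    ParameterBounds,
    SevenCompParams,
    TwoCompParams,
    derived_flows,
    exp_propagate,
    exp_residue,
    seven_comp_tissue,
    two_comp_tissue,
)
from renoperf.kinetic import FLOW_PER_SECOND

from .oracles import ode_seven_comp, ode_two_comp, quadrature_conv


def random_params(rng) -> SevenCompParams:
    b = ParameterBounds.seven_comp_default()
    lo = b.lower.copy()
    lo[0] = 0.5  # keep mtt_pa well away from 0 for the ODE comparison
    x = rng.uniform(lo, b.upper)
    x[7] = rng.uniform(50, 500)  # f_cor
    x[8:] = rng.uniform(0.1, 0.6, 2)
    return SevenCompParams.from_array(x)


class TestExpConvolution:
    def test_steady_state_of_normalized_propagator(self):
        mtt = 4.0
        c = Curve(np.arange(0, 20 * mtt, 0.5), np.ones(160))
        out = exp_propagate(c, mtt)
        assert abs(out.v[-1] - 1.0) < 1e-6

    def test_zero_input_gives_zero_output(self):
        c = Curve(np.arange(10.0), np.zeros(10))
        assert np.all(exp_propagate(c, 3.0).v == 0)
        assert np.all(exp_residue(c, 3.0).v == 0)

    @pytest.mark.parametrize("mtt", [1.0, 5.0, 30.0])
    def test_propagate_matches_quadrature(self, triangular_bolus, mtt):
        got = exp_propagate(triangular_bolus, mtt).v
        ref = quadrature_conv(lambda u: np.exp(-u / mtt) / mtt, triangular_bolus)
        auc = np.trapezoid(ref, triangular_bolus.t)
        err = np.trapezoid(np.abs(got - ref), triangular_bolus.t)
        assert err < 1e-3 * auc

    def test_residue_matches_quadrature(self, triangular_bolus):
        mtt = 5.0
        got = exp_residue(triangular_bolus, mtt).v
        ref = quadrature_conv(lambda u: np.exp(-u / mtt), triangular_bolus)
        auc = np.trapezoid(ref, triangular_bolus.t)
        assert np.trapezoid(np.abs(got - ref), triangular_bolus.t) < 1e-3 * auc

    def test_residue_is_mtt_times_propagate(self, aif):
        mtt = 7.3
        r = exp_residue(aif, mtt).v
        h = exp_propagate(aif, mtt).v
        np.testing.assert_allclose(r, mtt * h, rtol=1e-12)

    @pytest.mark.parametrize("bad_mtt", [0.0, -1.0, np.nan])
    def test_invalid_mtt_rejected(self, aif, bad_mtt):
        with pytest.raises(ValueError):
            exp_propagate(aif, bad_mtt)

    def test_nonuniform_grid_rejected(self):
        with pytest.raises(ValueError):
            Curve(np.array([0.0, 1.0, 3.0]), np.zeros(3))


@settings(derandomize=True, max_examples=30, deadline=None)
@given(
    mtt=st.floats(0.5, 150.0),
    scale=st.floats(0.1, 50.0),
    seed=st.integers(0, 2**16),
)
def test_convolution_identities_hold_for_arbitrary_inputs(mtt, scale, seed):
    """R = MTT·H and linearity hold for any finite input curve."""
    rng = np.random.default_rng(seed)
    c = Curve(np.arange(40) * 1.6, rng.uniform(0, 1, 40))
    h = exp_propagate(c, mtt)
    r = exp_residue(c, mtt)
    np.testing.assert_allclose(r.v, mtt * h.v, rtol=1e-12)
    scaled = exp_propagate(c.with_values(scale * c.v), mtt)
    np.testing.assert_allclose(scaled.v, scale * h.v, rtol=1e-9, atol=1e-12)


class TestSevenCompTissue:
    def test_zero_aif_gives_zero_tissue(self, truth, aif):
        zero = aif.with_values(np.zeros(aif.n))
        c_cor, c_med = seven_comp_tissue(truth, zero)
        assert np.all(c_cor.v == 0) and np.all(c_med.v == 0)

    def test_pure_vascular_cortex_when_no_filtration_or_medullary_flow(self, aif):
        p = SevenCompParams(2, 8, 60, 40, 70, 30, 40, 240.0, 0.0, 0.0)
        c_cor, c_med = seven_comp_tissue(p, aif)
        assert np.allclose(c_med.v, 0.0)
        F = p.f_cor * FLOW_PER_SECOND
        expected = F * (
            exp_residue(aif, p.mtt_pa).v
            + exp_residue(exp_propagate(aif, p.mtt_pa), p.mtt_pv).v
        )
        np.testing.assert_allclose(c_cor.v, expected, rtol=1e-12)

    def test_matches_coupled_ode_oracle(self, aif):
        rng = np.random.default_rng(123)
        for _ in range(5):
            p = random_params(rng)
            c_cor, c_med = seven_comp_tissue(p, aif)
            ref_cor, ref_med = ode_seven_comp(p, aif)
            tol = 0.005
            assert np.max(np.abs(c_cor.v - ref_cor)) < tol * ref_cor.max()
            assert np.max(np.abs(c_med.v - ref_med)) < tol * ref_med.max()

    def test_auc_conservation(self, aif):
        # horizon 30x the largest MTT; area identity from mass conservation
        rng = np.random.default_rng(7)
        for _ in range(20):
            p = random_params(rng)
            horizon = 30 * max(p.to_array()[:7])
            t = np.arange(0, horizon, 1.6)
            bolus = np.zeros_like(t)
            bolus[(t >= 10) & (t < 30)] = 1.0
            a = Curve(t, bolus)
            c_cor, c_med = seven_comp_tissue(p, a)
            F = p.f_cor * FLOW_PER_SECOND
            expected = (
                F
                * a.auc()
                * (
                    p.mtt_pa
                    + (1 - p.e_ff) * p.mtt_pv
                    + (1 - p.e_ff) * p.e_med * p.mtt_vr
                    + p.e_ff * (p.mtt_pt + p.mtt_lh + p.mtt_dt + p.mtt_cd)
                )
            )
            got = c_cor.auc() + c_med.auc()
            assert abs(got - expected) < 0.01 * expected

    def test_linearity_in_flow_and_aif(self, truth, aif):
        c_cor, c_med = seven_comp_tissue(truth, aif)
        p2 = SevenCompParams.from_array(
            np.concatenate([truth.to_array()[:7], [2 * truth.f_cor, truth.e_med, truth.e_ff]])
        )
        d_cor, d_med = seven_comp_tissue(p2, aif)
        np.testing.assert_allclose(d_cor.v, 2 * c_cor.v, rtol=1e-12)
        e_cor, e_med_ = seven_comp_tissue(truth, aif.with_values(3 * aif.v))
        np.testing.assert_allclose(e_med_.v, 3 * c_med.v, rtol=1e-12)

    def test_causality_shift(self, truth, spec, aif):
        # prepending a zero block shifts outputs identically
        k = 10
        t2 = np.arange(aif.n + k) * aif.dt
        shifted = Curve(t2, np.concatenate([np.zeros(k), aif.v]))
        c_cor, c_med = seven_comp_tissue(truth, aif)
        s_cor, s_med = seven_comp_tissue(truth, shifted)
        np.testing.assert_allclose(s_cor.v[k:], c_cor.v, rtol=1e-9, atol=1e-14)
        assert np.all(s_cor.v[:k] == 0)


class TestTwoCompTissue:
    def test_no_tubular_flow_is_single_compartment(self, aif):
        p = TwoCompParams(f_p=200, t_p=10, f_t=0, t_t=60)
        out = two_comp_tissue(p, aif)
        expected = p.f_p * FLOW_PER_SECOND * exp_residue(aif, p.t_p).v
        np.testing.assert_allclose(out.v, expected, rtol=1e-12)

    def test_zero_aif(self, aif):
        p = TwoCompParams(200, 10, 50, 60)
        out = two_comp_tissue(p, aif.with_values(np.zeros(aif.n)))
        assert np.all(out.v == 0)

    def test_matches_ode_oracle(self, aif):
        p = TwoCompParams(f_p=180, t_p=12, f_t=45, t_t=90)
        got = two_comp_tissue(p, aif).v
        ref = ode_two_comp(p, aif)
        assert np.max(np.abs(got - ref)) < 0.005 * ref.max()


class TestDerivedFlows:
    def test_no_medullary_fraction_means_no_medullary_flow(self):
        p = SevenCompParams(1, 5, 60, 40, 70, 30, 40, 500.0, 0.0, 0.8)
        assert derived_flows(p).f_med == 0.0

    def test_printed_formula_values(self):
        p = SevenCompParams(1, 5, 60, 40, 70, 30, 40, 200.0, 0.25, 0.26)
        d = derived_flows(p)
        assert d.f_t == pytest.approx(52.0)
        assert d.f_med == pytest.approx(37.0)
        p2 = SevenCompParams(1, 5, 60, 40, 70, 30, 40, 200.0, 0.5, 0.25)
        assert derived_flows(p2).f_t == pytest.approx(50.0)

    def test_flow_budget_invariant(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = random_params(rng)
            d = derived_flows(p)
            assert d.f_med >= 0 and d.f_t >= 0
            assert d.f_med + d.f_t <= p.f_cor + 1e-9


class TestParameterBounds:
    def test_default_bounds_are_physiological(self):
        b = ParameterBounds.seven_comp_default()
        assert b.contains(SevenCompParams(1.5, 7.5, 60, 43, 77, 29, 41, 249, 0.4, 0.29).to_array())
        assert not b.contains(np.array([1.5, 7.5, 40, 43, 77, 29, 41, 249, 0.4, 0.29]))

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            ParameterBounds(lower=np.array([1.0]), upper=np.array([0.5]))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            SevenCompParams(0.0, 5, 60, 40, 70, 30, 40, 200, 0.2, 0.2)
        with pytest.raises(ValueError):
            SevenCompParams(1, 5, 60, 40, 70, 30, 40, 200, 1.2, 0.2)
        with pytest.raises(ValueError):
            TwoCompParams(100, 0.0, 50, 60)
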