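import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import modefit as mf
from modefit.deterministic import PreconditionConfig


class TestConstitutiveSteadyState:
    def test_closed_form_fixed_point(self, constitutive, theta_true):
        sss = mf.find_steady_states(constitutive, theta_true)
        assert sss.n_stable == 1
        x = sss.stable_states[0].state
        assert x == pytest.approx([5 / 0.03, 5 * 0.1 / (0.03 * 0.03)], rel=1e-9)

    def test_closed_form_over_random_draws(self, constitutive):
        """mRNA* = k_tx/d_mrna, Protein* = k_tx*k_tl/(d_mrna*d_prot)."""
        rng = np.random.default_rng(42)
        for _ in range(50):
            th = mf.ParameterSet(
                {
                    "k_tx": rng.uniform(0.5, 20),
                    "d_mrna": rng.uniform(0.01, 0.2),
                    "k_tl": rng.uniform(0.01, 0.5),
                    "d_prot": rng.uniform(0.01, 0.2),
                }
            )
            sss = mf.find_steady_states(constitutive, th)
            assert sss.n_stable == 1
            expect = [
                th["k_tx"] / th["d_mrna"],
                th["k_tx"] * th["k_tl"] / (th["d_mrna"] * th["d_prot"]),
            ]
            assert sss.stable_states[0].state == pytest.approx(expect, rel=1e-8)

    def test_eigenvalues_are_decay_rates(self, constitutive, theta_true):
        # triangular Jacobian of the linear system: eigenvalues -d_mrna, -d_prot
        lam, stable = mf.classify_stability(
            constitutive, theta_true, [5 / 0.03, 5 * 0.1 / 0.0009]
        )
        assert stable and lam == pytest.approx(-0.03, rel=1e-9)

    def test_ode_rhs_zero_at_fixed_point(self, constitutive, theta_true):
        rhs = mf.ode_rhs(constitutive, [5 / 0.03, 5 * 0.1 / 0.0009], theta_true)
        assert np.max(np.abs(rhs)) < 1e-12


@pytest.fixture(scope="module")
def nominal_sss(irf7):
    return mf.find_steady_states(irf7, irf7.default_parameters)


class TestIrf7SteadyStates:
    def test_bistable_at_nominal(self, nominal_sss):
        assert nominal_sss.n_stable == 2

    def test_residuals_small(self, irf7, nominal_sss):
        for s in nominal_sss.states:
            rhs = mf.ode_rhs(irf7, s.state, irf7.default_parameters)
            assert np.max(np.abs(rhs)) < 1e-9 * (1 + np.abs(s.state).max())

    def test_stimulated_branch_values(self, irf7, nominal_sss):
        # IFN balances its Hill amplification against decay: ~V_IFN/k_dIFN
        hi = max(nominal_sss.stable_states, key=lambda s: s.state[0])
        assert hi.state[0] == pytest.approx(124.70, abs=0.01)
        assert hi.state[1] == pytest.approx(22.00, rel=0.01)

    def test_basal_branch_values(self, irf7, nominal_sss):
        lo = min(nominal_sss.stable_states, key=lambda s: s.state[0])
        assert lo.state[0] == 0.0  # unstimulated branch is on the boundary
        names = irf7.species_names
        assert lo.state[names.index("mRNA")] == pytest.approx(1.20, abs=0.01)
        assert lo.state[names.index("IRF7")] == pytest.approx(13.62, rel=0.01)
        assert lo.state[names.index("IRF7dimer")] == pytest.approx(60.19, rel=0.01)

    def test_basal_observable_total(self, irf7, nominal_sss):
        lo = min(nominal_sss.stable_states, key=lambda s: s.state[0])
        total = irf7.observation.apply_state(irf7, lo.state)
        assert total == pytest.approx(80.43, rel=0.01)

    def test_all_stable_eigenvalues_negative(self, nominal_sss):
        for s in nominal_sss.stable_states:
            assert s.lambda_max < 0


class TestPrecondition:
    def _sss(self, constitutive, theta_true):
        return mf.find_steady_states(constitutive, theta_true)

    def test_true_params_pass_at_measured_mode(self, constitutive, theta_true):
        # Protein* = 555.56; band [0.95, 1.05] brackets the 543 a.u. mode
        res = mf.check_precondition(
            self._sss(constitutive, theta_true), [543.0], constitutive.observation, constitutive
        )
        assert res.passed and res.reason == "passed"

    def test_out_of_range_mode_fails(self, constitutive, theta_true):
        res = mf.check_precondition(
            self._sss(constitutive, theta_true), [400.0], constitutive.observation, constitutive
        )
        assert not res.passed and res.reason == "out of range"

    def test_count_mismatch(self, constitutive, theta_true):
        res = mf.check_precondition(
            self._sss(constitutive, theta_true),
            [500.0, 600.0],
            constitutive.observation,
            constitutive,
        )
        assert not res.passed and res.reason == "count mismatch"

    def test_no_stable_state_reason(self, constitutive):
        res = mf.check_precondition(
            mf.SteadyStateSet(states=[]), [543.0], constitutive.observation, constitutive
        )
        assert not res.passed and res.reason == "no stable state"

    @settings(max_examples=50, deadline=None)
    @given(
        mode=st.floats(min_value=1.0, max_value=2000.0),
        beta_low=st.floats(min_value=0.0, max_value=1.0),
        beta_up=st.floats(min_value=1.0, max_value=3.0),
        widen_low=st.floats(min_value=0.0, max_value=0.5),
        widen_up=st.floats(min_value=0.0, max_value=2.0),
    )
    def test_monotone_in_beta(self, mode, beta_low, beta_up, widen_low, widen_up):
        """Widening the acceptance band never flips a pass into a failure."""
        net = mf.build_constitutive_model()
        theta = mf.ParameterSet(mf.CONSTITUTIVE_TRUE_PARAMS)
        sss = mf.find_steady_states(net, theta)
        narrow = mf.check_precondition(
            sss, [mode], net.observation, net,
            PreconditionConfig(beta_low=beta_low, beta_up=beta_up),
        )
        wide = mf.check_precondition(
            sss, [mode], net.observation, net,
            PreconditionConfig(beta_low=max(0.0, beta_low - widen_low), beta_up=beta_up + widen_up),
        )
        assert not (narrow.passed and not wide.passed)

    def test_nominal_irf7_lower_mode_bracketing(self, irf7):
        """The basal total (~80.4) brackets the 77 a.u. mode exactly per the band."""
        sss = mf.find_steady_states(irf7, irf7.default_parameters)
        lo = min(
            irf7.observation.apply_state(irf7, s.state) for s in sss.stable_states
        )
        res = mf.check_precondition(sss, [77.0, 1000.0], irf7.observation, irf7)
        lower_ok = res.pair_ok[0]
        assert lower_ok == (0.95 * lo <= 77.0 <= 1.05 * lo)


def test_beta_band_validation():
    with pytest.raises(ValueError):
        PreconditionConfig(beta_low=1.2).bands(1)
    with pytest.raises(ValueError):
        PreconditionConfig(beta_up=0.9).bands(1)
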