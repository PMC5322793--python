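import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import modefit as mf
from modefit.distributions import InputError


class TestBinning:
    @pytest.mark.parametrize("nm,expected", [(10000, 100), (4, 2), (2, 2), (3000, 55)])
    def test_sqrt_rule(self, nm, expected):
        assert mf.bin_count(nm) == expected

    def test_sqrt_rule_rejects_tiny(self):
        with pytest.raises(InputError):
            mf.bin_count(1)

    def test_symmetric_split(self):
        dist = mf.build_distributions([0.0], [np.array([1.0, 2.0, 3.0, 4.0])], L=2)
        assert dist.masses[0] == pytest.approx([0.5, 0.5])

    def test_degenerate_time_point_flagged(self):
        dist = mf.build_distributions([0.0], [np.full(10, 7.0)], L=4)
        assert dist.degenerate[0] and dist.masses[0].sum() == pytest.approx(1.0)

    def test_outliers_clipped_into_terminal_bins(self):
        ref = mf.build_distributions([0.0], [np.linspace(0, 10, 50)], L=5)
        sim = mf.build_distributions(
            [0.0], [np.array([-100.0, 5.0, 200.0])], L=5, edges=ref.edges
        )
        assert sim.masses[0][0] == pytest.approx(1 / 3)
        assert sim.masses[0][-1] == pytest.approx(1 / 3)

    @settings(max_examples=50, deadline=None)
    @given(
        values=st.lists(st.floats(min_value=-1e4, max_value=1e4), min_size=2, max_size=200),
        L=st.integers(min_value=2, max_value=50),
    )
    def test_masses_always_sum_to_one(self, values, L):
        dist = mf.build_distributions([0.0], [np.array(values)], L=L)
        assert dist.masses[0].sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(dist.masses[0] >= 0)


class TestObservation:
    def test_sum_of_observable_species(self, irf7):
        state = np.zeros(7)
        state[4:7] = [10, 2, 3]
        assert irf7.observation.apply_state(irf7, state) == 15.0

    def test_scale_factor_is_linear(self, irf7):
        from modefit.models import ObservationMap

        obs2 = ObservationMap(irf7.observation.observable_species, 2.0)
        state = np.zeros(7)
        state[4:7] = [13.62, 6.62, 60.19]
        assert obs2.apply_state(irf7, state) == pytest.approx(2 * 80.43)

    def test_table_total_of_basal_components(self, irf7):
        state = np.zeros(7)
        state[4:7] = [13.62, 6.62, 60.19]
        assert irf7.observation.apply_state(irf7, state) == pytest.approx(80.43)

    def test_ensemble_mapping_shape(self, constitutive, theta_true):
        ens = mf.simulate_ensemble(constitutive, theta_true, [0, 0], [50.0, 100.0], ns=8, base_seed=0)
        vals = mf.apply_observation(ens, constitutive.observation, constitutive)
        assert len(vals) == 2 and all(len(v) == 8 for v in vals)
        assert np.array_equal(vals[0], ens.states[:, 0, 1].astype(float))


class TestModeFinding:
    def test_two_clear_maxima(self):
        masses = np.array([0.1, 0.4, 0.1, 0.1, 0.3, 0.0])
        edges = np.arange(7.0)
        dist = mf.BinnedDistributionSet(
            times=np.array([0.0]), edges=(edges,), masses=(masses / masses.sum(),)
        )
        ms = mf.find_modes(dist, smooth_bins=1)
        assert len(ms.locations) == 2
        assert ms.locations == pytest.approx([1.5, 4.5])

    def test_unimodal_gaussian_sample(self):
        rng = np.random.default_rng(3)
        x = rng.normal(50, 5, size=10000)
        dist = mf.build_distributions([0.0], [x], L=mf.bin_count(10000))
        ms = mf.find_modes(dist)
        width = np.diff(dist.edges[0])[0]
        assert len(ms.locations) == 1
        assert abs(ms.locations[0] - 50) <= 2 * width

    def test_insilico_single_mode_near_543(self, insilico_small):
        dist = mf.distributions_from_events(insilico_small)
        ms = mf.find_modes(dist)
        width = np.diff(dist.edges[-1])[0]
        assert len(ms.locations) == 1
        assert abs(ms.locations[0] - 543) <= 3 * width

    def test_degenerate_distribution_rejected(self):
        dist = mf.build_distributions([0.0], [np.full(10, 7.0)], L=4)
        with pytest.raises(InputError):
            mf.find_modes(dist)

    def test_no_mode_error(self):
        # an unattainable prominence requirement leaves no qualifying peak
        masses = np.full(10, 0.1)
        dist = mf.BinnedDistributionSet(
            times=np.array([0.0]), edges=(np.arange(11.0),), masses=(masses,)
        )
        with pytest.raises(InputError, match="no mode"):
            mf.find_modes(dist, smooth_bins=1, min_prominence=5.0)


class TestObjective:
    def _dist(self, masses, edges=None):
        masses = np.asarray(masses, dtype=float)
        edges = np.arange(len(masses) + 1.0) if edges is None else edges
        return mf.BinnedDistributionSet(
            times=np.array([0.0]), edges=(edges,), masses=(masses,)
        )

    def test_identity_gives_zero(self):
        d = self._dist([0.25, 0.75])
        assert mf.objective_F(d, d) == 0.0

    def test_disjoint_support(self):
        assert mf.objective_F(self._dist([1.0, 0.0]), self._dist([0.0, 1.0])) == 2.0

    def test_hand_computed_value(self):
        assert mf.objective_F(self._dist([0.5, 0.5]), self._dist([0.25, 0.75])) == pytest.approx(0.125)

    def test_symmetry(self):
        a, b = self._dist([0.5, 0.5]), self._dist([0.1, 0.9])
        assert mf.objective_F(a, b) == mf.objective_F(b, a)

    def test_mismatched_grids_rejected(self):
        a = self._dist([0.5, 0.5])
        b = self._dist([0.5, 0.5], edges=np.array([0.0, 2.0, 4.0]))
        with pytest.raises(InputError):
            mf.objective_F(a, b)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(min_value=0.001, max_value=1), min_size=2, max_size=20))
    def test_nonnegative(self, weights):
        w = np.array(weights)
        a = self._dist(w / w.sum())
        b = self._dist(np.full(len(w), 1.0 / len(w)))
        assert mf.objective_F(a, b) >= 0.0


class TestConditionalObjective:
    def test_failed_precondition_short_circuits(self, constitutive, insilico_small):
        """A parameter set whose steady state is far from the mode is
        penalized without a single stochastic run."""
        bad = mf.ParameterSet({"k_tx": 1.0, "d_mrna": 0.03, "k_tl": 0.02, "d_prot": 0.03})
        value, pre, diag = mf.objective_Fcond(
            constitutive, bad, insilico_small, [543.0], mf.FcondConfig(ns=100), seed=0
        )
        assert not pre.passed
        assert value == pytest.approx(1e12)
        assert diag["n_ssa_runs"] == 0

    def test_true_params_score_well(self, constitutive, theta_true, insilico_small):
        """The generating parameters pass the filter and score far below the
        typical objective of random passing candidates."""
        cfg = mf.FcondConfig(ns=300)
        value, pre, diag = mf.objective_Fcond(
            constitutive, theta_true, insilico_small, [543.0], cfg, seed=1
        )
        assert pre.passed and diag["n_ssa_runs"] == 300
        # a passing-but-wrong candidate on the steady-state ridge
        other = mf.ParameterSet({"k_tx": 2.0, "d_mrna": 0.03, "k_tl": 0.25, "d_prot": 0.03})
        value_other, pre_other, _ = mf.objective_Fcond(
            constitutive, other, insilico_small, [543.0], cfg, seed=1
        )
        assert pre_other.passed
        assert value < value_other

    def test_deterministic_given_seed(self, constitutive, theta_true, insilico_small):
        cfg = mf.FcondConfig(ns=50)
        v1 = mf.objective_Fcond(constitutive, theta_true, insilico_small, [543.0], cfg, seed=5)[0]
        v2 = mf.objective_Fcond(constitutive, theta_true, insilico_small, [543.0], cfg, seed=5)[0]
        assert v1 == v2
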