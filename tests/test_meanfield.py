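import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import multicargo as mc
from multicargo import meanfield as mf
from multicargo.meanfield import TerminalEventError


@pytest.fixture(scope="module")
def uni2():
    return mc.uniform_profile(1.0)


class TestDisplacementMoments:
    def test_symmetric_first_moments_vanish(self, uniform_model_n4, pb_uniform):
        for m in (1, 2):
            lam = mf.displacement_moment(m, 1, 0.0, 2, uniform_model_n4, pb_uniform)
            assert lam == pytest.approx(0.0, abs=1e-14)

    def test_binding_second_moment_single_leg(self, uniform_model_n4, pb_uniform):
        # uniform kappa1, window second moment L^2/3, centre prefactor (1/2)^2
        lam = mf.displacement_moment(1, 2, 0.0, 1, uniform_model_n4, pb_uniform)
        assert lam == pytest.approx(1.0 / 12.0, rel=1e-9)

    def test_collective_step_moments(self, uniform_model_n4):
        m = uniform_model_n4
        m2 = mc.CargoModel(N=4, kappa1=m.kappa1, kappa2=m.kappa2, k3_rate=1.0, k3_step=0.1)
        assert mf.displacement_moment(3, 1, 0.0, 2, m2, None) == pytest.approx(0.1)
        assert mf.displacement_moment(3, 2, 0.0, 2, m2, None) == pytest.approx(0.01)

    def test_saturated_binding_and_terminal_unbinding(self, uniform_model_n4, pb_uniform):
        with pytest.raises(ValueError):
            mf.displacement_moment(1, 1, 0.0, 4, uniform_model_n4, pb_uniform)
        with pytest.raises(TerminalEventError):
            mf.displacement_moment(2, 1, 0.0, 1, uniform_model_n4, pb_uniform)


class TestRates:
    def test_mean_event_rates_uniform(self, pb_uniform, uni2):
        m = mc.CargoModel(N=10, kappa1=uni2, kappa2=mc.uniform_profile(1.0))
        assert mf.mean_event_rate(1, 0.0, 3, m, pb_uniform) == pytest.approx(7.0)
        assert mf.mean_event_rate(2, 0.0, 4, m, pb_uniform) == pytest.approx(4.0)
        assert mf.mean_event_rate(1, 0.0, 10, m, pb_uniform) == pytest.approx(0.0)

    def test_birth_death_rates(self, pb_uniform, uni2):
        m = mc.CargoModel(N=2, kappa1=uni2, kappa2=mc.uniform_profile(1.0))
        b, d = mf.birth_death_rates(0.0, m, pb_uniform)
        assert np.allclose(b, [2.0, 1.0]) and np.allclose(d, [1.0, 2.0])

    def test_no_binding_when_kappa1_zero(self, pb_uniform):
        m = mc.CargoModel(N=3, kappa1=mc.uniform_profile(0.0), kappa2=mc.uniform_profile(1.0))
        b, _ = mf.birth_death_rates(0.0, m, pb_uniform)
        assert np.all(b == 0.0)


class TestDwellTimes:
    def test_single_leg_exponential(self, pb_uniform, uni2):
        m = mc.CargoModel(N=1, kappa1=uni2, kappa2=mc.uniform_profile(1.0))
        assert mf.mean_dwell_time(0.0, m, pb_uniform) == pytest.approx(1.0)

    def test_two_leg_uniform(self, pb_uniform, uni2):
        m = mc.CargoModel(N=2, kappa1=uni2, kappa2=mc.uniform_profile(1.0))
        assert mf.mean_dwell_time(0.0, m, pb_uniform) == pytest.approx(1.5, rel=1e-12)

    def test_no_rebinding_gives_unit_dwell(self, pb_uniform):
        for N in (1, 3, 7):
            m = mc.CargoModel(N=N, kappa1=mc.uniform_profile(0.0), kappa2=mc.uniform_profile(1.0))
            assert mf.mean_dwell_time(0.0, m, pb_uniform) == pytest.approx(1.0)

    def test_vanishing_unbinding_gives_infinite_dwell(self, pb_uniform, uni2):
        m = mc.CargoModel(N=2, kappa1=uni2, kappa2=mc.uniform_profile(0.0))
        assert mf.mean_dwell_time(0.0, m, pb_uniform) == np.inf

    @given(st.integers(min_value=1, max_value=12), st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=60)
    def test_formula_matches_linear_solve_oracle(self, N, seed):
        rng = np.random.default_rng(seed)
        b = rng.uniform(0.05, 5.0, size=N)
        d = rng.uniform(0.05, 5.0, size=N)
        T = mf.dwell_time_from_rates(b, d)
        T_oracle = mf.mean_dwell_time_linear_solve(b, d)
        assert T == pytest.approx(T_oracle, rel=1e-10)


class TestSteadyStatePn:
    def test_two_leg_reflecting(self, pb_uniform, uni2):
        m = mc.CargoModel(N=2, kappa1=uni2, kappa2=mc.uniform_profile(1.0))
        Pn = mf.steady_state_Pn(0.0, m, pb_uniform, mode="reflecting")
        assert Pn == pytest.approx([2 / 3, 1 / 3])

    def test_single_leg_trivial(self, pb_uniform, uni2):
        m = mc.CargoModel(N=1, kappa1=uni2, kappa2=mc.uniform_profile(1.0))
        for mode in ("reflecting", "quasi_stationary"):
            assert mf.steady_state_Pn(0.0, m, pb_uniform, mode=mode) == pytest.approx([1.0])

    def test_modes_agree_within_tv_bound(self, pb_uniform, uni2):
        m = mc.CargoModel(N=10, kappa1=uni2, kappa2=mc.uniform_profile(1.0))
        pr = mf.steady_state_Pn(0.0, m, pb_uniform, mode="reflecting")
        pq = mf.steady_state_Pn(0.0, m, pb_uniform, mode="quasi_stationary")
        assert pr.sum() == pytest.approx(1.0, abs=1e-10)
        assert pq.sum() == pytest.approx(1.0, abs=1e-10)
        assert 0.5 * np.abs(pr - pq).sum() < 0.05

    def test_unknown_mode_rejected(self, pb_uniform, uniform_model_n4):
        with pytest.raises(ValueError):
            mf.steady_state_Pn(0.0, uniform_model_n4, pb_uniform, mode="absorbing")


class TestDriftAndNoise:
    def test_uniform_rates_no_drift(self, uniform_model_n4, pb_uniform):
        S1, S2 = mf.drift_and_noise(0.0, uniform_model_n4, pb_uniform)
        assert S1 == pytest.approx(0.0, abs=1e-12)
        assert S2 > 0

    def test_collective_drift_is_additive(self, pb_uniform, uni2):
        m = mc.CargoModel(N=4, kappa1=uni2, kappa2=mc.uniform_profile(1.0),
                          k3_rate=2.0, k3_step=0.05)
        S1, _ = mf.drift_and_noise(0.0, m, pb_uniform)
        assert S1 == pytest.approx(0.1, abs=1e-12)

    def test_bump_flank_attracts_to_centre(self, bump_model_n4, pb_uniform):
        lc = mc.characteristic_length(bump_model_n4.kappa1, 1.1)
        S1_left, _ = mf.drift_and_noise(-lc, bump_model_n4, pb_uniform)
        S1_right, _ = mf.drift_and_noise(lc, bump_model_n4, pb_uniform)
        assert S1_left > 0 and S1_right < 0

    def test_odd_drift_even_noise_for_even_rates(self, bump_model_n4, pb_uniform):
        for x in (0.5, 1.3, 2.4, 3.0):
            S1p, S2p = mf.drift_and_noise(x, bump_model_n4, pb_uniform)
            S1m, S2m = mf.drift_and_noise(-x, bump_model_n4, pb_uniform)
            assert S1p == pytest.approx(-S1m, abs=1e-12)
            assert S2p == pytest.approx(S2m, rel=1e-10)


class TestEffectiveTables:
    def test_uniform_rates_flat_tables(self, uniform_model_n4, pb_uniform):
        grid = np.linspace(-5, 5, 51)
        tab = mf.effective_tables(grid, uniform_model_n4, pb_uniform)
        assert np.allclose(tab.v_eff, 0.0, atol=1e-10)
        assert np.ptp(tab.D_eff) < 1e-12
        assert np.allclose(tab.Pn.sum(axis=1), 1.0, atol=1e-10)
        assert np.all(tab.S2 >= 0)

    def test_veff_consistent_with_drift_minus_noise_gradient(self, bump_model_n4, pb_uniform):
        grid = np.linspace(-8, 8, 161)
        tab = mf.effective_tables(grid, bump_model_n4, pb_uniform)
        dD = np.gradient(tab.D_eff, grid)
        assert np.allclose(tab.v_eff, tab.S1 - dD, atol=1e-12)

    def test_koff_is_reciprocal_dwell(self, uniform_model_n4, pb_uniform):
        grid = np.linspace(-1, 1, 5)
        tab = mf.effective_tables(grid, uniform_model_n4, pb_uniform)
        assert np.allclose(tab.k_off, 1.0 / 3.75)  # N=4 uniform chain

    def test_surrogate_diffusivity_exceeds_empirical(self, uniform_model_n4,
                                                     uniform_ensemble_n4, pb_uniform):
        from multicargo.analysis import empirical_pb

        pbe = empirical_pb(uniform_ensemble_n4)
        grid = np.array([0.0, 0.5])
        D_sur = mf.effective_tables(grid, uniform_model_n4, pb_uniform).D_eff[0]
        D_emp = mf.effective_tables(grid, uniform_model_n4, pbe).D_eff[0]
        assert D_sur > D_emp


class TestSmallCargoDrift:
    def test_uniform_rates_reduce_to_collective_drift(self, pb_uniform, uni2):
        m = mc.CargoModel(N=6, kappa1=uni2, kappa2=mc.uniform_profile(1.0),
                          k3_rate=2.0, k3_step=0.05)
        assert mf.small_cargo_drift(0.0, m, pb_uniform) == pytest.approx(0.1)

    def test_missing_derivative_signalled(self, pb_uniform):
        tab = mc.tabulated_profile([-5, 0, 5], [1.0, 2.0, 1.0])
        m = mc.CargoModel(N=4, kappa1=tab, kappa2=mc.uniform_profile(1.0))
        with pytest.raises(ValueError, match="derivative"):
            mf.small_cargo_drift(0.0, m, pb_uniform)

    def test_plateau_and_monotonicity_in_leg_count(self, bump):
        L, x = 0.25, -2.6
        pb = mf.uniform_bound_legs(L)
        vals = []
        for N in (1, 2, 4, 8, 16, 32, 64):
            m = mc.CargoModel(N=N, kappa1=bump, kappa2=mc.uniform_profile(1.0), L=L)
            vals.append(mf.small_cargo_drift(x, m, pb))
        plateau = L * L * bump.derivative(x) / 3.0
        assert np.all(np.diff(vals) > 0)
        assert vals[-1] == pytest.approx(plateau, rel=0.15)


@pytest.fixture(scope="module")
def edge_model():
    return mc.CargoModel(
        N=6,
        kappa1=mc.uniform_profile(1.0, support=(-20.0, 0.0)),
        kappa2=mc.uniform_profile(1.0),
        domain=mc.Domain(-20.0, 2.0, "edged"),
    )


class TestEdgeDrift:
    def test_binding_term_pulls_into_substrate_at_edge(self, edge_model, pb_uniform):
        comp = mf.edge_drift(0.0, edge_model, pb_uniform, x_edge=0.0, side="right",
                             return_components=True)
        assert comp["binding"] < 0

    def test_unbinding_term_points_off_substrate(self, edge_model, pb_uniform):
        comp = mf.edge_drift(-0.3, edge_model, pb_uniform, x_edge=0.0, side="right",
                             return_components=True)
        assert comp["unbinding"] >= 0

    def test_interior_cargo_has_no_edge_binding_term(self, edge_model, pb_uniform):
        comp = mf.edge_drift(-1.0, edge_model, pb_uniform, x_edge=0.0, side="right",
                             return_components=True)
        assert comp["binding"] == 0.0

    def test_left_edge_mirror_symmetry(self, pb_uniform):
        right = mc.CargoModel(
            N=6, kappa1=mc.uniform_profile(1.0, support=(-20.0, 0.0)),
            kappa2=mc.uniform_profile(1.0), domain=mc.Domain(-20, 2, "edged"),
        )
        left = mc.CargoModel(
            N=6, kappa1=mc.uniform_profile(1.0, support=(0.0, 20.0)),
            kappa2=mc.uniform_profile(1.0), domain=mc.Domain(-2, 20, "edged"),
        )
        vr = mf.edge_drift(-0.4, right, pb_uniform, x_edge=0.0, side="right")
        vl = mf.edge_drift(0.4, left, pb_uniform, x_edge=0.0, side="left")
        assert vr == pytest.approx(-vl, rel=1e-9)


class TestFixedPoints:
    def test_symmetric_bump_single_stable_zero(self, bump_model_n4, pb_uniform):
        grid = np.linspace(-10, 10, 201)
        tab = mf.effective_tables(grid, bump_model_n4, pb_uniform)
        fps = mf.find_fixed_points(tab)
        assert len(fps) == 1
        assert fps[0].stable
        assert abs(fps[0].x) < 1e-6

    def test_collective_drift_shifts_stable_point(self, bump, pb_uniform):
        m = mc.CargoModel(N=4, kappa1=bump, kappa2=mc.uniform_profile(1.0),
                          k3_rate=2.0, k3_step=0.05)
        grid = np.linspace(-10, 10, 201)
        tab = mf.effective_tables(grid, m, pb_uniform)
        stable = [p for p in mf.find_fixed_points(tab) if p.stable]
        assert len(stable) == 1
        assert stable[0].x > 0.5  # shifted towards the step direction

    def test_uniform_rates_with_drift_have_no_fixed_points(self, pb_uniform, uni2):
        m = mc.CargoModel(N=4, kappa1=uni2, kappa2=mc.uniform_profile(1.0),
                          k3_rate=2.0, k3_step=0.05)
        grid = np.linspace(-10, 10, 101)
        tab = mf.effective_tables(grid, m, pb_uniform)
        assert mf.find_fixed_points(tab) == []
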