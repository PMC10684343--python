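import numpy as np
import pytest
from scipy import stats

import multicargo as mc
from multicargo import meanfield as mf
from multicargo.gillespie import (
    CargoState,
    propensities,
    sample_binding_position,
    simulate_cargo,
    simulate_ensemble,
)


def _rng(seed=0):
    return np.random.default_rng(seed)


class TestPropensities:
    def test_uniform_rates(self, uniform):
        model = mc.CargoModel(N=10, kappa1=uniform, kappa2=mc.uniform_profile(1.0))
        state = CargoState(bound_positions=np.array([-0.2, 0.0, 0.2]), centre=0.0)
        B, unbind, k3 = propensities(state, model)
        assert B == pytest.approx(7.0, rel=1e-6)
        assert np.allclose(unbind, 1.0)
        assert k3 == 0.0

    def test_no_free_legs(self, uniform):
        model = mc.CargoModel(N=2, kappa1=uniform, kappa2=mc.uniform_profile(1.0))
        state = CargoState(bound_positions=np.array([0.0, 0.1]), centre=0.05)
        B, _, _ = propensities(state, model)
        assert B == pytest.approx(0.0, abs=1e-9)

    def test_half_window_off_substrate(self):
        # cargo centred at the substrate edge: half the binding window is dark
        model = mc.CargoModel(
            N=4, kappa1=mc.uniform_profile(1.0, support=(-20.0, 0.0)),
            kappa2=mc.uniform_profile(1.0), domain=mc.Domain(-20, 2, "edged"),
        )
        state = CargoState(bound_positions=np.array([-0.1]), centre=0.0)
        B, _, _ = propensities(state, model)
        assert B == pytest.approx(3 * 0.5, rel=1e-3)


class TestBindingPositionSampling:
    def test_uniform_profile_gives_uniform_window(self, uniform):
        model = mc.CargoModel(N=4, kappa1=uniform, kappa2=mc.uniform_profile(1.0))
        state = CargoState(bound_positions=np.array([0.0]), centre=0.0)
        rng = _rng(1)
        draws = np.array([sample_binding_position(state, model, rng) for _ in range(20000)])
        ks = stats.kstest(draws, stats.uniform(loc=-1.0, scale=2.0).cdf)
        assert ks.pvalue > 0.01

    def test_bump_flank_draws_lean_inward(self, bump):
        model = mc.CargoModel(N=4, kappa1=bump, kappa2=mc.uniform_profile(1.0))
        lc = mc.characteristic_length(bump, 1.1)
        state = CargoState(bound_positions=np.array([lc]), centre=lc)
        rng = _rng(2)
        draws = np.array([sample_binding_position(state, model, rng) for _ in range(20000)])
        # quadrature mean of the normalized density kappa1 * S_H over the window
        y = np.linspace(lc - 1, lc + 1, 4001)
        w = bump(y)
        expected = np.trapezoid(y * w, y) / np.trapezoid(w, y)
        assert expected < lc
        assert draws.mean() == pytest.approx(expected, abs=3 * draws.std() / np.sqrt(draws.size))

    def test_dark_window_signalled(self):
        model = mc.CargoModel(
            N=4, kappa1=mc.uniform_profile(1.0, support=(-20.0, 0.0)),
            kappa2=mc.uniform_profile(1.0), domain=mc.Domain(-20, 5, "edged"),
        )
        state = CargoState(bound_positions=np.array([3.0]), centre=3.0)
        with pytest.raises(ValueError, match="zero density"):
            sample_binding_position(state, model, _rng(3))


class TestSimulateCargo:
    def test_single_leg_dwell_is_exponential(self, uniform):
        model = mc.CargoModel(N=1, kappa1=uniform, kappa2=mc.uniform_profile(1.0))
        ens = simulate_ensemble(model, 5000, 100.0, master_seed=7, x0=0.0)
        dw = ens.dwell_times()
        assert np.all(np.isfinite(dw))
        se = dw.std() / np.sqrt(dw.size)
        assert dw.mean() == pytest.approx(1.0, abs=3 * se)
        ks = stats.kstest(dw, stats.expon.cdf)
        assert ks.pvalue > 0.01

    def test_two_leg_dwell_matches_chain_formula(self, uniform):
        model = mc.CargoModel(N=2, kappa1=uniform, kappa2=mc.uniform_profile(1.0))
        ens = simulate_ensemble(model, 5000, 500.0, master_seed=8, x0=0.0)
        dw = ens.dwell_times()
        se = dw.std() / np.sqrt(dw.size)
        assert dw.mean() == pytest.approx(1.5, abs=3 * se)

    @pytest.mark.parametrize("N", [4, 10])
    def test_dwell_matches_meanfield_for_larger_cargo(self, N, uniform, pb_uniform):
        model = mc.CargoModel(N=N, kappa1=uniform, kappa2=mc.uniform_profile(1.0))
        expected = mf.mean_dwell_time(0.0, model, pb_uniform)
        ens = simulate_ensemble(model, 1500, 100 * expected, master_seed=9 + N, x0=0.0)
        dw = ens.dwell_times()
        dw = dw[np.isfinite(dw)]
        se = dw.std() / np.sqrt(dw.size)
        assert dw.mean() == pytest.approx(expected, abs=3 * se)

    def test_centre_is_mean_of_bound_legs(self, uniform_ensemble_n10):
        # replay the event log and verify the bookkeeping after every event
        for traj in list(uniform_ensemble_n10)[:50]:
            legs = [traj.x0]
            for m, xev, n_after, xa in zip(traj.m, traj.x_event, traj.n_after, traj.x_after):
                if m == 1:
                    legs.append(xev)
                elif m == 2:
                    j = int(np.argmin([abs(l - xev) for l in legs]))
                    legs.pop(j)
                else:
                    legs = [l + xev for l in legs]
                if legs:
                    assert abs(np.mean(legs) - xa) < 1e-10
            assert traj.detached == (traj.n_after[-1] == 0 if traj.times.size else False)

    def test_trajectory_times_strictly_increasing(self, uniform_ensemble_n4):
        for traj in list(uniform_ensemble_n4)[:200]:
            assert np.all(np.diff(traj.times) > 0)
            if traj.times.size:
                assert traj.n_after[0] in (0, 2)  # first event from the n=1 state

    def test_zero_mean_displacement_for_uniform_rates(self, uniform_ensemble_n4):
        X = uniform_ensemble_n4.positions_at(np.array([10.0]))
        d = X[np.isfinite(X[:, 0]), 0]
        se = d.std() / np.sqrt(d.size)
        assert abs(d.mean()) < 3 * se
        assert abs(stats.skew(d)) < 3 * np.sqrt(6.0 / d.size)


class TestEnsembles:
    def test_same_seed_reproduces_bitwise(self, uniform):
        model = mc.CargoModel(N=3, kappa1=uniform, kappa2=mc.uniform_profile(1.0))
        a = simulate_ensemble(model, 50, 10.0, master_seed=5, x0=0.0)
        b = simulate_ensemble(model, 50, 10.0, master_seed=5, x0=0.0)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.times, tb.times)
            assert np.array_equal(ta.x_after, tb.x_after)

    def test_different_seeds_same_law(self, uniform):
        model = mc.CargoModel(N=2, kappa1=uniform, kappa2=mc.uniform_profile(1.0))
        a = simulate_ensemble(model, 3000, 200.0, master_seed=1, x0=0.0)
        b = simulate_ensemble(model, 3000, 200.0, master_seed=2, x0=0.0)
        ks = stats.ks_2samp(a.dwell_times(), b.dwell_times())
        assert ks.pvalue > 0.01

    def test_empty_ensemble(self, uniform_model_n4):
        ens = simulate_ensemble(uniform_model_n4, 0, 10.0, master_seed=3)
        assert len(ens) == 0

    def test_occupancy_matches_quasi_stationary_law(self, uniform_model_n4, pb_uniform):
        from multicargo.analysis import estimate_Pn

        ens = simulate_ensemble(uniform_model_n4, 4000, 20.0, master_seed=11, x0=0.0)
        edges = np.linspace(-10, 10, 3)
        _, P, occ = estimate_Pn(ens, edges, t_range=(5.0, 20.0))
        pn_emp = np.nansum(P * occ[:, None], axis=0) / occ.sum()
        pn_qs = mf.steady_state_Pn(0.0, uniform_model_n4, pb_uniform, mode="quasi_stationary")
        assert 0.5 * np.abs(pn_emp - pn_qs).sum() < 0.02
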