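import numpy as np
import pytest

import multicargo as mc
from multicargo import analysis as an
from multicargo import meanfield as mf
from multicargo.gillespie import Ensemble, Trajectory, simulate_ensemble


def _brownian_ensemble(D, ntraj, t_max, dt, seed, model):
    """Synthetic pure-Brownian event tables with known diffusivity."""
    rng = np.random.default_rng(seed)
    trajs = []
    nst = int(t_max / dt)
    times = dt * np.arange(1, nst + 1)
    for i in range(ntraj):
        steps = rng.normal(0.0, np.sqrt(2 * D * dt), nst)
        x = np.cumsum(steps)
        trajs.append(
            Trajectory(
                x0=0.0, times=times, m=np.full(nst, 3, dtype=np.int8),
                x_event=steps, n_after=np.full(nst, 2, dtype=np.int16),
                x_after=x, t_max=t_max, detached=False, seed=i,
            )
        )
    return Ensemble(trajectories=trajs, model=model, master_seed=seed)


class TestMSD:
    def test_recovers_known_diffusivity(self, uniform_model_n4):
        D = 0.15
        dt = 0.01
        ens = _brownian_ensemble(D, 4000, 10.0, dt, 13, uniform_model_n4)
        # sample the step-function paths exactly on the update grid
        lags = dt * np.arange(1, int(10.0 / dt))
        mom = an.msd_and_diffusivities(ens, short_window=(0.05, 0.8),
                                       long_window=(2, 6), lags=lags)
        assert mom.D_short == pytest.approx(D, rel=0.02)
        assert mom.D_long == pytest.approx(D, rel=0.02)
        assert abs(mom.D_short - mom.D_long) < 3 * np.hypot(mom.zeta_short, mom.zeta_long)

    def test_short_time_diffusivity_exceeds_long(self, uniform_ensemble_n4):
        mom = an.msd_and_diffusivities(uniform_ensemble_n4,
                                       short_window=(0.05, 0.8), long_window=(2, 6))
        assert mom.D_short > mom.D_long
        assert np.all(np.isfinite(mom.msd[mom.counts > 0]))

    def test_msd_nonnegative_and_errors_positive(self, uniform_ensemble_n4):
        mom = an.msd_and_diffusivities(uniform_ensemble_n4)
        ok = mom.counts > 1
        assert np.all(mom.msd[ok] >= 0)
        assert np.all(mom.msd_se[ok] >= 0)
        assert mom.zeta_short > 0 and mom.zeta_long > 0

    def test_too_few_survivors_signalled(self, uniform_model_n4):
        ens = simulate_ensemble(uniform_model_n4, 20, 3.0, master_seed=4, x0=0.0)
        with pytest.raises(ValueError, match="too few"):
            an.msd_and_diffusivities(ens, long_window=(50.0, 60.0),
                                     lags=np.array([0.1, 0.5, 55.0, 56.0, 57.0]))


class TestBoundLegDistributions:
    def test_single_leg_is_point_mass_at_centre(self, uniform_ensemble_n4):
        h = an.estimate_bound_leg_distribution(uniform_ensemble_n4, n=1, bins=41)
        k = np.argmax(h["density"])
        assert abs(h["u"][k]) < 0.05
        assert h["density"][np.abs(h["u"]) > 0.1].sum() == 0.0

    def test_uniform_rates_symmetric_distribution(self, uniform_ensemble_n4):
        h = an.estimate_bound_leg_distribution(uniform_ensemble_n4, n=3, bins=41)
        u, dens = h["u"], h["density"]
        mean = np.trapezoid(u * dens, u)
        # time-weighted histogram: crude scale for the SE of the mean
        assert abs(mean) < 0.05
        assert np.trapezoid(dens, u) == pytest.approx(1.0, abs=0.02)

    def test_missing_leg_count_signalled(self, uniform_ensemble_n4):
        with pytest.raises(ValueError, match="no sojourns"):
            an.estimate_bound_leg_distribution(uniform_ensemble_n4, n=17)


class TestFitBoundLegs:
    def test_uniform_density_recovered(self):
        u = np.linspace(-0.975, 0.975, 40)
        dens = np.full_like(u, 0.5)
        params, fitted = an.fit_bound_leg_distribution(u, dens, L=1.0)
        assert np.max(np.abs(fitted - 0.5)) < 0.02

    def test_symmetric_fit_has_zero_mean(self, uniform_ensemble_n4):
        h = an.estimate_bound_leg_distribution(uniform_ensemble_n4, n=2, bins=41)
        params, fitted = an.fit_bound_leg_distribution(h["u"], h["density"], L=1.0)
        assert np.trapezoid(h["u"] * fitted, h["u"]) == pytest.approx(0.0, abs=1e-12)

    def test_fit_beats_uniform_surrogate_for_many_legs(self, uniform_ensemble_n10):
        h = an.estimate_bound_leg_distribution(uniform_ensemble_n10, n=8, bins=41)
        params, fitted = an.fit_bound_leg_distribution(h["u"], h["density"], L=1.0)
        ise_fit = np.sum((fitted - h["density"]) ** 2)
        ise_uni = np.sum((0.5 - h["density"]) ** 2)
        assert ise_fit < ise_uni

    def test_degenerate_histogram_signalled(self):
        u = np.linspace(-1, 1, 21)
        with pytest.raises(ValueError, match="degenerate"):
            an.fit_bound_leg_distribution(u, np.zeros_like(u), L=1.0)


class TestPnEstimation:
    def test_single_leg_occupancy_is_trivial(self, uniform):
        model = mc.CargoModel(N=1, kappa1=uniform, kappa2=mc.uniform_profile(1.0))
        ens = simulate_ensemble(model, 200, 10.0, master_seed=6, x0=0.0)
        _, P, occ = an.estimate_Pn(ens, np.linspace(-10, 10, 5))
        assert np.allclose(P[occ > 0], 1.0)

    def test_relaxation_towards_steady_state(self, uniform_model_n4, pb_uniform,
                                             uniform_ensemble_n4):
        edges = np.linspace(-10, 10, 3)
        pn_qs = mf.steady_state_Pn(0.0, uniform_model_n4, pb_uniform,
                                   mode="quasi_stationary")

        def tv(t0, t1):
            _, P, occ = an.estimate_Pn(uniform_ensemble_n4, edges, t_range=(t0, t1))
            pn = np.nansum(P * occ[:, None], axis=0) / occ.sum()
            return 0.5 * np.abs(pn - pn_qs).sum()

        assert tv(4.0, 12.0) < tv(0.0, 1.0)


class TestEmpiricalFields:
    def test_uniform_rates_drift_consistent_with_zero(self, uniform_ensemble_n4):
        edges = np.linspace(-10, 10, 21)
        f = an.empirical_drift_noise(uniform_ensemble_n4, edges, smoothing=1)
        ws = f.well_sampled(100)
        assert ws.sum() > 3
        assert np.all(np.abs(f.S1[ws]) < 4 * f.S1_se[ws])

    def test_routes_agree_for_uniform_rates(self, uniform_ensemble_n4):
        edges = np.linspace(-4, 4, 9)
        fB = an.empirical_drift_noise(uniform_ensemble_n4, edges, smoothing=1, route="events")
        fA = an.empirical_drift_noise(uniform_ensemble_n4, edges, smoothing=1, route="meanfield")
        ws = fB.well_sampled(200)
        agree = np.abs(fA.S2[ws] - fB.S2[ws]) <= 3 * fB.S2_se[ws]
        assert agree.mean() >= 0.8

    def test_unknown_route_rejected(self, uniform_ensemble_n4):
        with pytest.raises(ValueError):
            an.empirical_drift_noise(uniform_ensemble_n4, np.linspace(-1, 1, 5), route="x")


class TestStationaryDensity:
    def test_uniform_rates_flat_density(self, uniform_model_n4):
        ens = simulate_ensemble(uniform_model_n4, 3000, 20.0, master_seed=31,
                                x0_mode="uniform")
        x, dens, se = an.stationary_density(ens, np.linspace(-10, 10, 41))
        bw = x[1] - x[0]
        assert np.sum(dens) * bw == pytest.approx(1.0, rel=1e-12)
        assert np.all(np.abs(dens - 0.05) < 4 * np.maximum(se, 1e-4))

    def test_collective_drift_shifts_density_mean(self, bump):
        m = mc.CargoModel(N=4, kappa1=bump, kappa2=mc.uniform_profile(1.0),
                          k3_rate=2.0, k3_step=0.05)
        ens = simulate_ensemble(m, 1500, 100.0, master_seed=32, x0_mode="uniform")
        x, dens, _ = an.stationary_density(ens, np.linspace(-10, 10, 81))
        bw = x[1] - x[0]
        assert np.sum(x * dens) * bw > 0.05
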