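"""Analysis operators against closed forms and independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import psdcrowd as pc
from psdcrowd.analysis import expected_unbind_time, kusumi_msd, molecule_radius_nm
from psdcrowd.engine import EnsembleResult, Trajectory
from psdcrowd.lattice import ValidationError


def _synthetic_ensemble(positions):
    """Ensemble from raw (N, T, 2) unwrapped positions (times 0..T-1 ms)."""
    n, t, _ = positions.shape
    cfg = pc.make_config(width=10.0, height=10.0, duration=float(t - 1), n_walkers=n, seed=0)
    times = np.arange(t, dtype=float)
    wrapped = np.zeros((t, 2), dtype=np.int64)
    bound = np.zeros(t, dtype=bool)
    return EnsembleResult(
        config=cfg,
        trajectories=[Trajectory(times, positions[w], wrapped, bound) for w in range(n)],
        seed=0,
    )


class TestMSD:
    def test_stationary_trajectory_has_zero_msd(self):
        ens = _synthetic_ensemble(np.ones((1, 10, 2)) * 3.7)
        assert np.all(pc.compute_msd(ens).msd == 0.0)

    def test_matches_naive_double_loop_oracle(self):
        rng = np.random.default_rng(42)
        pos = rng.normal(size=(5, 10, 2))
        msd = pc.compute_msd(_synthetic_ensemble(pos)).msd
        expected = np.zeros(10)
        for t in range(10):
            acc = 0.0
            for w in range(5):
                dx = pos[w, t, 0] - pos[w, 0, 0]
                dy = pos[w, t, 1] - pos[w, 0, 1]
                acc += dx * dx + dy * dy
            expected[t] = acc / 5
        np.testing.assert_allclose(msd, expected, rtol=1e-12)

    def test_gaussian_walk_msd_matches_einstein_relation(self):
        D = pc.DEFAULT_D_FREE
        ens = pc.make_gaussian_walk_fixture(D, n_walkers=400, duration=500.0, seed=3)
        msd = pc.compute_msd(ens)
        pos = ens.unwrapped()
        disp_sq = ((pos - pos[:, :1, :]) ** 2).sum(axis=2)
        for t in (100, 250, 500):
            se = disp_sq[:, t].std(ddof=1) / np.sqrt(400)
            assert abs(msd.msd[t] - 4 * D * t) < 3 * se

    def test_crowding_orders_msd_curves(self):
        cfg = pc.make_config(width=1.0, height=1.0, duration=500.0, n_walkers=100, seed=31)
        at_end = []
        for C in (0.0, 0.2, 0.4, 0.6):
            fld = pc.make_obstacle_field(cfg, C=C, seed=100 + int(C * 10))
            at_end.append(pc.compute_msd(pc.simulate_ensemble(cfg, fld)).msd[-1])
        assert all(a > b for a, b in zip(at_end, at_end[1:]))

    def test_empty_ensemble_rejected(self):
        ens = _synthetic_ensemble(np.zeros((1, 10, 2)))
        ens.trajectories = []
        with pytest.raises(ValidationError):
            pc.compute_msd(ens)


class TestAlphaFit:
    @pytest.mark.parametrize("alpha", np.round(np.arange(0.1, 1.01, 0.1), 2).tolist())
    def test_recovers_exact_power_law(self, alpha):
        msd = pc.make_powerlaw_msd_fixture(2.0e-4, alpha, np.arange(0.0, 2001.0))
        fit = pc.fit_alpha(msd)
        assert fit.alpha == pytest.approx(alpha, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.D == pytest.approx(2.0e-4, rel=1e-9)

    def test_window_restricts_the_fit(self):
        # power law with a late-time kink: fitting the early window ignores it
        t = np.arange(0.0, 1001.0)
        msd = pc.make_powerlaw_msd_fixture(1e-3, 0.5, t)
        msd.msd[t > 500] = msd.msd[t > 500][0]
        early = pc.fit_alpha(msd, window=(10.0, 500.0))
        assert early.alpha == pytest.approx(0.5, abs=1e-9)

    def test_insufficient_points_rejected(self):
        msd = pc.make_powerlaw_msd_fixture(1e-3, 0.5, np.arange(0.0, 4.0))
        with pytest.raises(ValidationError):
            pc.fit_alpha(msd, window=(1.0, 3.0))

    def test_unphysical_exponent_warns(self):
        t = np.arange(0.0, 101.0)
        msd = pc.MSDCurve(t=t, msd=np.where(t > 0, 1e-3 * t**1.5, 0.0), n=1)
        with pytest.warns(UserWarning, match="outside"):
            pc.fit_alpha(msd)


class TestDapp:
    def test_median_converges_to_log2_times_D(self):
        # squared displacement of an isotropic 2-D Gaussian is exponential,
        # so the median D_app is ln(2) * D
        D = pc.DEFAULT_D_FREE
        ens = pc.make_gaussian_walk_fixture(D, n_walkers=10_000, duration=50.0, seed=8)
        dist = pc.compute_dapp(ens, t_obs=50.0)
        assert dist.median == pytest.approx(np.log(2) * D, rel=0.03)
        assert np.all(dist.values >= 0)

    def test_off_grid_time_rejected(self):
        ens = pc.make_gaussian_walk_fixture(1e-4, 10, 20.0, seed=1)
        with pytest.raises(ValidationError, match="t_obs"):
            pc.compute_dapp(ens, t_obs=10.5)


class TestKusumi:
    def test_exact_model_inversion(self):
        t = np.arange(0.0, 2001.0)
        L_true, D = 0.25, pc.DEFAULT_D_FREE
        msd = pc.MSDCurve(t=t, msd=kusumi_msd(t, L_true, D), n=400)
        fit = pc.fit_kusumi(msd, D_input=D)
        assert fit.L == pytest.approx(L_true, abs=1e-4)
        assert fit.residual < 1e-12

    def test_short_curve_rejected(self):
        msd = pc.MSDCurve(t=np.arange(3.0), msd=np.arange(3.0) * 1e-4, n=1)
        with pytest.raises(ValidationError):
            pc.fit_kusumi(msd, D_input=1e-4)


class TestResidenceTime:
    def test_normal_diffusion_identity(self):
        assert pc.residence_time(0.1, 1.0, 1e-4) == pytest.approx(0.01 / (4e-4))

    @pytest.mark.parametrize(
        "alpha, expected", [(0.3, 6.9e4), (0.4, 4.3e3)]
    )
    def test_anomalous_retention_of_average_psd(self, alpha, expected):
        # time to spread across a 125 nm PSD radius with slow anomalous exponents
        t = pc.residence_time(0.125, alpha, 0.138e-3)
        assert t == pytest.approx(expected, rel=0.02)

    def test_monotone_in_alpha_and_distance(self):
        alphas = np.linspace(0.2, 1.0, 9)
        ts = [pc.residence_time(0.25, a, 2e-4) for a in alphas]
        assert all(a > b for a, b in zip(ts, ts[1:]))
        dists = np.linspace(0.05, 0.5, 10)
        ts = [pc.residence_time(d, 0.5, 2e-4) for d in dists]
        assert all(a < b for a, b in zip(ts, ts[1:]))

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValidationError):
            pc.residence_time(0.1, 0.0)

    def test_powerlaw_fixture_inversion(self):
        # the time at which the power-law MSD reaches d^2 is the residence time
        D, alpha, d = 2e-4, 0.6, 0.2
        t_star = pc.residence_time(d, alpha, D)
        msd = pc.make_powerlaw_msd_fixture(D, alpha, np.array([0.0, t_star]))
        assert msd.msd[1] == pytest.approx(d**2, rel=1e-9)


class TestRetention:
    def test_frozen_walkers_inside_region(self):
        cfg = pc.make_config(width=1.0, height=1.0, duration=5.0, n_walkers=3, seed=0)
        psd = pc.PSDRegion.centered(cfg, 0.5)
        i0, _, j0, _ = psd.site_bounds(cfg)
        t = cfg.times
        wrapped = np.full((len(t), 2), [i0 + 1, j0 + 1], dtype=np.int64)
        trajs = [
            Trajectory(t, wrapped * cfg.dx, wrapped, np.zeros(len(t), bool)) for _ in range(3)
        ]
        ens = EnsembleResult(config=cfg, trajectories=trajs, seed=0)
        assert pc.retention_fraction(ens, psd, 5.0) == 1.0

    def test_off_grid_query_rejected(self):
        ens = pc.make_gaussian_walk_fixture(1e-4, 5, 20.0, seed=1)
        psd = pc.PSDRegion(0.0, 0.0, 1.0, 1.0)
        with pytest.raises(ValidationError, match="t_query"):
            pc.retention_fraction(ens, psd, 7.3)


class TestCalculators:
    def test_micromolar_dissociation_constants_map_to_pdz_range(self):
        assert pc.kd_to_kbt(1e-6) == pytest.approx(13.7, abs=0.05)
        assert pc.kd_to_kbt(10e-6) == pytest.approx(11.4, abs=0.05)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(kd=st.floats(1e-12, 0.99))
    def test_energy_is_linear_in_log_inverse_kd(self, kd):
        # halving ln(1/Kd) halves the energy
        assert pc.kd_to_kbt(np.sqrt(kd)) == pytest.approx(pc.kd_to_kbt(kd) / 2, rel=1e-9)

    def test_nonbinding_kd_rejected(self):
        with pytest.raises(ValidationError):
            pc.kd_to_kbt(1.0)

    def test_psd_mass_fraction_defaults(self):
        assert pc.psd_mass_fraction() == pytest.approx(42.7, abs=0.3)

    def test_psd_mass_fraction_linearity(self):
        full = pc.psd_mass_fraction(2.0e-15, 1e6, 2.0e-21)
        assert pc.psd_mass_fraction(1.0e-15, 1e6, 2.0e-21) == pytest.approx(full / 2)
        assert pc.psd_mass_fraction(1e6 * 1.4e-21, 1e6, 1.4e-21) == pytest.approx(100.0)

    def test_occupied_volume_of_canonical_psd(self):
        r = molecule_radius_nm(100_000.0)
        assert r == pytest.approx(3.05, abs=0.01)
        assert (4 / 3) * np.pi * r**3 == pytest.approx(119.0, abs=1.0)
        frac = pc.occupied_volume_fraction(10_000, 100_000.0, 3.06e6)
        assert frac == pytest.approx(0.39, abs=0.01)
        assert pc.occupied_volume_fraction(0, 100_000.0, 3.06e6) == 0.0

    def test_strongest_bond_unbinds_in_fractions_of_a_second(self):
        # 1 us attempt interval, 13 kBT barrier -> 1e-6 / e^-13 = 0.44
        assert expected_unbind_time(13.0) == pytest.approx(0.44, abs=0.005)
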