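"""Bell / Bell-Evans fitting, KDE reduction and the Arrhenius conversion."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest

from bondscape import (
    BondModel,
    DfsPoint,
    Environment,
    arrhenius_dg,
    bell_evans_force,
    bell_lifetime,
    bin_lifetimes,
    dfs_reduce,
    fit_bell,
    fit_bell_evans,
    generate_clamp_events,
    generate_dfs_events,
    kde_mode,
    rate_to_lifetime,
    thermal_energy,
)
from bondscape.core import ClampEvent, DomainError, FitError, InsufficientDataError
from bondscape.kinetics import LifetimeBin
from bondscape.synthetic import ExperimentConfig, most_probable_rupture_force


def _clamp_objects(df):
    return [
        ClampEvent(lifetime=float(l), force_step=float(f))
        for f, l in zip(df.force_step, df.lifetime)
    ]


class TestBinLifetimes:
    def test_single_bin_point_mass(self):
        events = [ClampEvent(lifetime=0.1, force_step=40.0) for _ in range(100)]
        (bin0,) = bin_lifetimes(events, n_bins=1)
        assert bin0.mean_force == pytest.approx(40.0)
        assert bin0.n == 100

    def test_uniform_forces_spread_evenly(self, rng):
        forces = rng.uniform(20, 60, 100)
        events = [ClampEvent(lifetime=0.1, force_step=float(f)) for f in forces]
        bins = bin_lifetimes(events, n_bins=4)
        assert len(bins) == 4
        assert all(15 <= b.n <= 35 for b in bins)
        assert sum(b.n for b in bins) == 100

    def test_too_few_events_rejected(self):
        events = [ClampEvent(lifetime=0.1, force_step=f) for f in (20.0, 40.0, 60.0)]
        with pytest.raises(InsufficientDataError):
            bin_lifetimes(events, n_bins=8)


class TestFitBell:
    def test_noiseless_bins_exact_recovery(self, env):
        t0, x_beta = 0.32, 0.57
        kbt = thermal_energy(env)
        bins = [
            LifetimeBin(mean_force=f, mean_lifetime=t0 * math.exp(-x_beta * f / kbt),
                        lifetime_sd=0.0, n=10)
            for f in (20.0, 45.0, 70.0, 95.0, 120.0)
        ]
        fit = fit_bell(bins, env)
        assert fit.t0 == pytest.approx(t0, rel=1e-6)
        assert fit.x_beta == pytest.approx(x_beta, rel=1e-6)

    def test_simulated_events_recover_within_ci(self, clamp_bond, env):
        df = generate_clamp_events(134, clamp_bond, rng=np.random.default_rng(77))
        fit = fit_bell(bin_lifetimes(_clamp_objects(df), 8), env)
        assert abs(fit.t0 - 0.32) <= fit.t0_ci
        assert abs(fit.x_beta - 0.57) <= fit.x_beta_ci

    def test_zero_force_spread_unidentifiable(self, env):
        bins = [
            LifetimeBin(mean_force=40.0, mean_lifetime=0.1, lifetime_sd=0.0, n=10)
            for _ in range(4)
        ]
        with pytest.raises(FitError):
            fit_bell(bins, env)

    def test_too_few_bins(self, env):
        bins = [
            LifetimeBin(mean_force=f, mean_lifetime=0.1, lifetime_sd=0.0, n=5)
            for f in (20.0, 40.0)
        ]
        with pytest.raises(InsufficientDataError):
            fit_bell(bins, env)


class TestKdeMode:
    def test_point_mass(self):
        assert kde_mode([5.0, 5.0, 5.0, 5.0, 5.0]) == 5.0

    def test_normal_mode_is_mean(self, rng):
        draws = rng.normal(40.0, 5.0, 10_000)
        assert kde_mode(draws) == pytest.approx(40.0, abs=0.5)

    def test_bimodal_taller_mode_wins(self, rng):
        sample = np.concatenate([rng.normal(10, 1, 7000), rng.normal(20, 1, 3000)])
        assert kde_mode(sample) == pytest.approx(10.0, abs=0.5)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            kde_mode([1.0, 2.0, 3.0])


class TestDfsReduce:
    def test_degenerate_group(self):
        df = pd.DataFrame(
            {"velocity": [3.1] * 6, "rupture_force": [40.0] * 6, "loading_rate": [1e4] * 6}
        )
        (point,) = dfs_reduce(df)
        assert point.mp_force == pytest.approx(40.0)
        assert point.mp_loading_rate == pytest.approx(1e4, rel=1e-9)
        assert point.n == 6

    def test_groups_ascending_velocity(self, inserted_bond):
        events = generate_dfs_events(ExperimentConfig(bond=inserted_bond, seed=5))
        points = dfs_reduce(events)
        velocities = [p.velocity for p in points]
        assert velocities == sorted(velocities)
        assert len(points) == 5

    def test_small_group_skipped_with_warning(self):
        df = pd.DataFrame(
            {"velocity": [1.0] * 3 + [3.1] * 8,
             "rupture_force": [30.0] * 3 + [40.0] * 8,
             "loading_rate": [1e3] * 3 + [1e4] * 8}
        )
        with pytest.warns(UserWarning, match="skipped"):
            points = dfs_reduce(df)
        assert len(points) == 1

    def test_modes_follow_generating_curve(self, inserted_bond):
        """KDE-reduced points lie on the Bell-Evans curve of the generating bond."""
        events = generate_dfs_events(
            ExperimentConfig(bond=inserted_bond, events_per_velocity=200, seed=17)
        )
        points = dfs_reduce(events)
        for p in points:
            predicted = float(most_probable_rupture_force(p.mp_loading_rate, inserted_bond))
            assert p.mp_force == pytest.approx(predicted, abs=2.5)


class TestFitBellEvans:
    def _noiseless_points(self, k0, x_beta, env, rates=(1e3, 1e4, 1e5, 1e6, 1e7)):
        return [
            DfsPoint(velocity=i + 1.0, mp_force=float(bell_evans_force(lr, k0, x_beta, env)),
                     mp_loading_rate=lr, n=92)
            for i, lr in enumerate(rates)
        ]

    def test_noiseless_exact_recovery(self, env):
        fit = fit_bell_evans(self._noiseless_points(2.0, 0.81, env), env)
        assert fit.k0 == pytest.approx(2.0, rel=1e-6)
        assert fit.x_beta == pytest.approx(0.81, rel=1e-6)
        assert fit.delta_g == pytest.approx(-math.log(1e-5 * fit.k0), abs=1e-12)

    def test_two_exact_points_solved(self, env):
        fit = fit_bell_evans(self._noiseless_points(0.03, 2.0, env, rates=(1e3, 1e5)), env)
        assert fit.k0 == pytest.approx(0.03, rel=1e-6)
        assert fit.x_beta == pytest.approx(2.0, rel=1e-6)
        assert math.isnan(fit.k0_ci)  # no residual degrees of freedom

    def test_negative_slope_rejected(self, env):
        points = [
            DfsPoint(velocity=v, mp_force=f, mp_loading_rate=lr, n=10)
            for v, f, lr in [(1.0, 60.0, 1e3), (3.0, 50.0, 1e4), (9.0, 40.0, 1e5)]
        ]
        with pytest.raises(FitError):
            fit_bell_evans(points, env)

    def test_insufficient_span_rejected(self, env):
        points = self._noiseless_points(2.0, 0.81, env, rates=(1e4, 2e4))
        with pytest.raises(InsufficientDataError):
            fit_bell_evans(points, env)

    def test_full_simulation_recovers_within_ci(self, inserted_bond, env):
        events = generate_dfs_events(ExperimentConfig(bond=inserted_bond, seed=23))
        fit = fit_bell_evans(dfs_reduce(events), env)
        assert abs(fit.x_beta - 0.81) <= fit.x_beta_ci
        assert abs(fit.k0 - 2.0) <= fit.k0_ci


class TestProtocolConsistency:
    def test_clamp_and_ramp_estimates_agree(self, inserted_bond, env):
        """Height-clamp t0 and 1/k0 from the ramp protocol agree for one bond."""
        clamp = generate_clamp_events(
            300, inserted_bond, force_range=(20.0, 60.0),
            rng=np.random.default_rng(31),
        )
        bell = fit_bell(bin_lifetimes(_clamp_objects(clamp), 8), env)
        ramp_events = generate_dfs_events(
            ExperimentConfig(bond=inserted_bond, events_per_velocity=150, seed=32)
        )
        evans = fit_bell_evans(dfs_reduce(ramp_events), env)
        joint = bell.t0_ci + evans.k0_ci / evans.k0**2  # d(1/k0) = dk0/k0^2
        assert abs(bell.t0 - 1.0 / evans.k0) <= joint


class TestArrhenius:
    @pytest.mark.parametrize(
        "k0, k0_err, dg, dg_err",
        [
            (0.03, 0.28, 15.0, 9.3),
            (2.0, 9.1, 10.8, 4.5),  # 0.28/0.03 etc. round to the printed precision
            (0.07, 0.84, 14.2, 12.0),
            (0.03, 0.31, 15.0, 10.3),
        ],
    )
    def test_barrier_heights_to_printed_precision(self, k0, k0_err, dg, dg_err):
        got_dg, got_err = arrhenius_dg(k0, k0_err, tau_d=1e-5)
        assert round(got_dg, 1) == dg
        assert round(got_err, 1) == dg_err

    def test_zero_barrier_identity(self):
        dg, _ = arrhenius_dg(1e5, tau_d=1e-5)
        assert dg == pytest.approx(0.0, abs=1e-12)

    def test_decade_decrement(self):
        dg1, _ = arrhenius_dg(0.1)
        dg2, _ = arrhenius_dg(1.0)
        assert dg1 - dg2 == pytest.approx(math.log(10), rel=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            arrhenius_dg(-1.0)
        with pytest.raises(DomainError):
            arrhenius_dg(1.0, tau_d=0.0)


class TestRateLifetime:
    @pytest.mark.parametrize("k0, lifetime", [(2.0, 0.5), (0.03, 33.3), (1.0, 1.0)])
    def test_reciprocal(self, k0, lifetime):
        assert rate_to_lifetime(k0) == pytest.approx(lifetime, abs=0.05)

    def test_domain_error(self):
        with pytest.raises(DomainError):
            rate_to_lifetime(0.0)


class TestBellLifetimeCurve:
    def test_decay_with_force(self, env):
        t20 = bell_lifetime(20.0, 0.32, 0.57, env)
        t40 = bell_lifetime(40.0, 0.32, 0.57, env)
        ratio_expected = math.exp(-0.57 * 20.0 / thermal_energy(env))
        assert t40 / t20 == pytest.approx(ratio_expected, rel=1e-12)
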