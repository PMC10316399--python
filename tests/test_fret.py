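"""Forward decay model: unit physics, analytic oracles, MC consistency."""

import numpy as np
import pytest

from gslnano import (
    DecayCurve,
    DomainModel,
    ProbeConfiguration,
    default_time_grid,
    donor_decay_snapshot,
    ensemble_decay,
    fret_efficiency,
    nanodomain_decay,
    uniform_plane_decay,
)
from gslnano.fret import gamma23_closed_form
from gslnano.membrane import _minimum_image

SIGMA = 0.005 / 0.65  # per-leaflet dye density at 0.5 mol%


def _probes(donor_xy, donor_leaf, acc_xy, acc_leaf, L, dz=4.0):
    donor_xy = np.atleast_2d(np.asarray(donor_xy, float))
    acc_xy = np.asarray(acc_xy, float).reshape(-1, 2)
    return ProbeConfiguration(
        donor_xy=donor_xy,
        donor_leaflet=np.asarray(donor_leaf, int),
        donor_in_domain=np.zeros(len(donor_xy), bool),
        acceptor_xy=acc_xy,
        acceptor_leaflet=np.asarray(acc_leaf, int),
        acceptor_in_domain=np.zeros(len(acc_xy), bool),
        box_length_nm=L,
        bilayer_separation_nm=dz,
    )


class TestSnapshot:
    def test_unquenched_donor(self, params):
        probes = _probes([[10.0, 10.0]], [0], np.empty((0, 2)), [], L=100.0)
        decay = donor_decay_snapshot(probes, params)
        tau_idx = 64  # grid channel width is tau/64
        assert decay.intensity[0] == pytest.approx(1.0)
        assert decay.intensity[tau_idx] == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_single_pair_at_forster_radius(self, params):
        r0 = params.forster_radius_nm
        probes = _probes([[10.0, 10.0]], [0], [[10.0 + r0, 10.0]], [0], L=100.0)
        decay = donor_decay_snapshot(probes, params)
        t = decay.time_ns
        np.testing.assert_allclose(
            decay.intensity, np.exp(-2.0 * t / params.donor_lifetime_ns), rtol=1e-12
        )

    def test_matches_brute_force_sum(self, params, rng):
        L, dz = 60.0, 4.0
        donor_xy = rng.uniform(0, L, (3, 2))
        acc_xy = rng.uniform(0, L, (5, 2))
        donor_leaf = np.array([0, 1, 0])
        acc_leaf = np.array([0, 0, 1, 1, 0])
        probes = _probes(donor_xy, donor_leaf, acc_xy, acc_leaf, L, dz)
        decay = donor_decay_snapshot(probes, params)

        # independent term-by-term evaluation
        t = decay.time_ns
        tau, r0 = params.donor_lifetime_ns, params.forster_radius_nm
        total = np.zeros_like(t)
        for i in range(3):
            rate = 1.0
            for j in range(5):
                d_lat = _minimum_image(donor_xy[i] - acc_xy[j], L)
                d2 = d_lat @ d_lat + (dz**2 if donor_leaf[i] != acc_leaf[j] else 0.0)
                rate += (r0**2 / d2) ** 3
            total += np.exp(-(t / tau) * rate)
        np.testing.assert_allclose(decay.intensity, total / 3.0, rtol=1e-10)

    def test_violating_excluded_volume_raises(self, params):
        probes = _probes([[10.0, 10.0]], [0], [[10.2, 10.0]], [0], L=100.0)
        with pytest.raises(ValueError, match="r_min"):
            donor_decay_snapshot(probes, params)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_model_decay_normalised_and_monotone(self, params, seed):
        rng = np.random.default_rng(seed)
        probes = _probes(
            rng.uniform(0, 80, (20, 2)), rng.integers(0, 2, 20),
            rng.uniform(0, 80, (30, 2)), rng.integers(0, 2, 30), L=80.0,
        )
        try:
            decay = donor_decay_snapshot(probes, params)
        except ValueError:
            return  # random draw violated the excluded volume; nothing to check
        assert decay.intensity[0] == pytest.approx(1.0)
        assert np.all(np.diff(decay.intensity) <= 1e-12)


class TestUniformPlaneOracle:
    def test_zero_density_is_pure_exponential(self, params):
        decay = uniform_plane_decay(0.0, params)
        np.testing.assert_allclose(
            decay.intensity, np.exp(-decay.time_ns / params.donor_lifetime_ns)
        )

    def test_closed_form_gamma23(self, params):
        t = default_time_grid(params)
        numeric = uniform_plane_decay(SIGMA, params, t, planes=[(SIGMA, 0.0)])
        closed = gamma23_closed_form(SIGMA, params, t)
        np.testing.assert_allclose(numeric.intensity[1:], closed[1:], rtol=1e-6)

    def test_exponent_linear_in_density(self, params):
        t = default_time_grid(params)[1:200]
        tau = params.donor_lifetime_ns
        f1 = uniform_plane_decay(SIGMA, params, t).intensity
        f2 = uniform_plane_decay(2 * SIGMA, params, t).intensity
        g1 = -np.log(f1) - t / tau
        g2 = -np.log(f2) - t / tau
        np.testing.assert_allclose(g2, 2.0 * g1, rtol=1e-8, atol=1e-12)


class TestEnsemble:
    def test_uniform_limit_matches_plane_oracle(self, params):
        L = 20 * params.forster_radius_nm
        model = DomainModel(radius_nm=1.0, area_fraction=0.0, box_length_nm=L)
        n = int(round(2 * SIGMA * L**2))
        ens = ensemble_decay(model, params, n, n, n_realizations=48, seed=5)
        per_leaf = (n / 2) / L**2
        oracle = uniform_plane_decay(
            0.0, params, ens.time_ns,
            planes=[(per_leaf, params.r_min_nm),
                    (per_leaf, model.bilayer_separation_nm)],
        )
        dev = np.abs(ens.intensity - oracle.intensity) / np.maximum(ens.mc_se, 1e-12)
        assert dev.max() <= 3.0

    def test_single_realization_and_determinism(self, params):
        model = DomainModel(
            radius_nm=8.0, area_fraction=0.3, box_length_nm=160.0,
            partition_donor=5.0, partition_acceptor=5.0,
        )
        a = ensemble_decay(model, params, 100, 100, n_realizations=1, seed=9)
        b = ensemble_decay(model, params, 100, 100, n_realizations=1, seed=9)
        assert np.array_equal(a.intensity, b.intensity)
        assert np.all(a.mc_se == 0)

    def test_mc_se_shrinks_with_realizations(self, params):
        model = DomainModel(
            radius_nm=8.0, area_fraction=0.3, box_length_nm=160.0,
            partition_donor=5.0, partition_acceptor=5.0,
        )
        few = ensemble_decay(model, params, 80, 80, n_realizations=25, seed=1)
        many = ensemble_decay(model, params, 80, 80, n_realizations=100, seed=1)
        sel = few.intensity > 0.01
        ratio = np.median(few.mc_se[sel][1:] / np.maximum(many.mc_se[sel][1:], 1e-15))
        assert 1.3 <= ratio <= 3.1  # expect ~2 = sqrt(100/25)

    def test_finite_size_stable_under_box_doubling(self, params):
        kwargs = dict(radius_nm=6.0, area_fraction=0.4,
                      partition_donor=5.0, partition_acceptor=5.0)
        small = DomainModel(box_length_nm=120.0, **kwargs)
        large = DomainModel(box_length_nm=240.0, **kwargs)
        a = nanodomain_decay(small, params, SIGMA, n_configs=10, seed=3)
        b = nanodomain_decay(large, params, SIGMA, n_configs=10, seed=4)
        se = np.sqrt(a.mc_se**2 + b.mc_se**2)
        dev = np.abs(a.intensity - b.intensity) / np.maximum(se, 1e-12)
        assert dev[a.intensity > 1e-3].max() <= 4.0


class TestPoissonFieldModel:
    def test_uniform_limit_equals_oracle_exactly(self, params):
        model = DomainModel(radius_nm=1.0, area_fraction=0.0, box_length_nm=150.0)
        semi = nanodomain_decay(model, params, SIGMA, seed=1)
        oracle = uniform_plane_decay(
            0.0, params, semi.time_ns,
            planes=[(SIGMA, params.r_min_nm),
                    (SIGMA, model.bilayer_separation_nm)],
        )
        np.testing.assert_allclose(semi.intensity, oracle.intensity, atol=1e-14)

    def test_agrees_with_sampled_monte_carlo(self, params):
        L = 150.0
        model = DomainModel(
            radius_nm=15.0, area_fraction=0.55, box_length_nm=L,
            partition_donor=20.0, partition_acceptor=20.0,
        )
        semi = nanodomain_decay(model, params, SIGMA, n_configs=8, seed=3)
        n = int(round(2 * SIGMA * L**2))
        samp = ensemble_decay(
            model, params, n, n, n_realizations=64, seed=5,
            max_donors_evaluated=4096,
        )
        se = np.sqrt(semi.mc_se**2 + samp.mc_se**2)
        dev = np.abs(semi.intensity - samp.intensity) / np.maximum(se, 1e-12)
        assert dev.max() <= 3.0

    def test_deterministic(self, params):
        model = DomainModel(
            radius_nm=15.0, area_fraction=0.5, box_length_nm=240.0,
            partition_donor=20.0, partition_acceptor=20.0,
        )
        a = nanodomain_decay(model, params, SIGMA, n_configs=3, seed=8)
        b = nanodomain_decay(model, params, SIGMA, n_configs=3, seed=8)
        assert np.array_equal(a.intensity, b.intensity)


class TestEfficiency:
    def test_unquenched_efficiency_zero(self, params):
        t = default_time_grid(params)
        decay = DecayCurve(time_ns=t, intensity=np.exp(-t / params.donor_lifetime_ns))
        assert fret_efficiency(decay, params.donor_lifetime_ns) == pytest.approx(
            0.0, abs=2e-4
        )

    def test_pair_at_forster_radius_gives_half(self, params):
        t = default_time_grid(params)
        decay = DecayCurve(
            time_ns=t, intensity=np.exp(-2.0 * t / params.donor_lifetime_ns)
        )
        assert fret_efficiency(decay, params.donor_lifetime_ns) == pytest.approx(
            0.5, abs=2e-4
        )

    def test_monotone_in_acceptor_density(self, params):
        t = default_time_grid(params)
        effs = [
            fret_efficiency(
                uniform_plane_decay(s, params, t), params.donor_lifetime_ns
            )
            for s in (0.0, SIGMA / 2, SIGMA, 2 * SIGMA)
        ]
        # grid truncation + trapezoid error allow ~1e-4 slack around 0
        assert all(-1e-3 <= e <= 1.0 for e in effs)
        assert np.all(np.diff(effs) > 0)

    def test_short_grid_warns(self, params):
        t = np.linspace(0, 2 * params.donor_lifetime_ns, 64)
        decay = DecayCurve(time_ns=t, intensity=np.exp(-t / params.donor_lifetime_ns))
        with pytest.warns(UserWarning, match="10 donor lifetimes"):
            fret_efficiency(decay, params.donor_lifetime_ns)


class TestDecayCurveValidation:
    def test_non_uniform_grid_rejected(self):
        with pytest.raises(ValueError):
            DecayCurve(time_ns=np.array([0.0, 1.0, 3.0]), intensity=np.ones(3))

    def test_increasing_intensity_rejected(self):
        with pytest.raises(ValueError):
            DecayCurve(
                time_ns=np.arange(3.0), intensity=np.array([1.0, 0.5, 0.8])
            )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            DecayCurve(time_ns=np.arange(3.0), counts=np.array([5, -1, 2]))
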