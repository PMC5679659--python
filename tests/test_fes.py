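"""Estimator stack: metadynamics reweighting, binless WHAM, PMF grids."""

import numpy as np
import pytest
from scipy.special import logsumexp

import memfes as m
from memfes.constants import KT_310
from memfes.engine import BiasState, ReplicaSpec, ReplicaTrajectory, bias_energy
from memfes.fes import metad_log_weights, metad_time_offset


def _manual_replica(z, times=None, window=(0.0, 30.0), bias=None,
                    bias_at=None, index=0):
    z = np.asarray(z, dtype=float)
    states = np.zeros((len(z), 3))
    states[:, 0] = z
    states[:, 1] = 90.0
    states[:, 2] = 90.0
    return ReplicaTrajectory(
        spec=ReplicaSpec(index), window=window,
        times=np.arange(len(z), dtype=float) if times is None else times,
        states=states,
        bias_at_frame=np.zeros(len(z)) if bias_at is None else bias_at,
        bias=bias or BiasState(sigma=1.0, w0=1.0, gamma=10.0, stride=500))


class TestTimeOffset:
    def test_no_hills_gives_zero_offset_and_equal_weights(self):
        traj = _manual_replica(np.linspace(0, 30, 50))
        t, c = metad_time_offset(traj.bias)
        assert len(t) == 0
        lw = metad_log_weights(traj)
        assert np.allclose(lw, 0.0)

    def test_offset_series_monotone_nondecreasing(self, small_campaign):
        for traj in small_campaign.replicas[:6]:
            _, c = metad_time_offset(traj.bias)
            assert np.all(np.diff(c) >= -1e-9)

    def test_static_bias_reduces_to_umbrella_reweighting(self):
        """With all hills at t=0 the estimator must equal standard umbrella
        reweighting: weights exp(+V(s)/kT) up to one constant."""
        rng = np.random.default_rng(5)
        land = m.double_well_1d()
        kT = KT_310
        bias = BiasState(sigma=2.0, w0=1.0, gamma=10.0, stride=1,
                        times=np.zeros(3), centers=np.array([5.0, 10.0, 15.0]),
                        heights=np.array([3.0, 2.0, 3.0]))
        z = rng.uniform(0, 30, 400)
        v = bias_energy(z, bias)
        traj = _manual_replica(z, times=np.arange(1, 401, dtype=float),
                               bias=bias, bias_at=v)
        lw = metad_log_weights(traj, kT)
        assert np.allclose(lw - lw[0], (v - v[0]) / kT, atol=1e-12)

    def test_double_well_free_energy_difference_recovered(self):
        """WT-MTD + time-independent reweighting recovers the analytic
        basin-to-basin free energy difference within 0.5 kJ/mol."""
        land = m.double_well_1d()
        params = m.LangevinParams(n_steps=120000, seed=4, frame_stride=10)
        traj = m.langevin_run(land, params)
        kT = KT_310
        lw = metad_log_weights(traj, kT)
        n0 = len(lw) // 5
        z, lw = traj.states[n0:, 0], lw[n0:]
        in_a, in_b = (z > 0) & (z < 10), (z >= 10) & (z < 25)
        df_est = -kT * (logsumexp(lw[in_b]) - logsumexp(lw[in_a]))
        g = np.linspace(0, 30, 3001)
        w = np.exp(-land.energy(g[:, None]) / kT)
        df_true = -kT * (np.log(w[(g >= 10) & (g < 25)].sum())
                         - np.log(w[(g > 0) & (g < 10)].sum()))
        assert df_est == pytest.approx(df_true, abs=0.5)


class TestWham:
    def test_single_window_zero_restraint_passes_weights_through(self):
        rng = np.random.default_rng(0)
        z = rng.uniform(0, 30, 500)
        scheme = m.WindowScheme(windows=((0.0, 30.0),), k=0.0)
        out = m.wham_combine([_manual_replica(z)], scheme)
        lw = out.log_weight
        assert np.allclose(lw - lw[0], 0.0, atol=1e-12)

    def test_linear_potential_slope_recovered_across_windows(self):
        """Two overlapping restrained windows on U = a z must reassemble the
        linear PMF with the right slope."""
        a, kT = 0.8, KT_310
        land = m.CallableLandscape(
            lambda p: a * p[:, 0],
            lambda p: np.stack([np.full(len(p), a)], axis=-1),
            domain=((0.0, 14.0),), names=("z",))
        scheme = m.build_window_scheme(0.0, 14.0, 8.0, 2.0, k=20.0)
        assert scheme.n_windows == 2
        params = m.LangevinParams(n_steps=60000, seed=6, frame_stride=10,
                                  hill_w0=0.0)
        camp = m.run_campaign(land, scheme, params=params, exchange_stride=0)
        cfg = m.EstimatorConfig(bulk_slab=(12.0, 14.0),
                                bin_width={"z": 1.0})
        pmf = m.reconstruct_pmf(camp, ["z"], cfg, equilibration=0.1,
                                with_errors=False)
        zc = pmf.centers(0)
        ok = np.isfinite(pmf.F)
        slope = np.polyfit(zc[ok], pmf.F[ok], 1)[0]
        assert slope == pytest.approx(a, abs=0.1)

    def test_gauge_invariance_under_window_bias_shift(self, small_campaign):
        cfg = m.EstimatorConfig()
        base = m.wham_combine(small_campaign.replicas, small_campaign.scheme,
                              cfg, equilibration=0.1)
        offsets = np.zeros(small_campaign.scheme.n_windows)
        offsets[3] = 10.0
        shifted = m.wham_combine(small_campaign.replicas,
                                 small_campaign.scheme, cfg,
                                 equilibration=0.1, bias_offsets=offsets)
        p0 = m.pmf_from_weights(base, ["z", "phi"], cfg)
        p1 = m.pmf_from_weights(shifted, ["z", "phi"], cfg)
        ok = np.isfinite(p0.F)
        assert np.nanmax(np.abs(p0.F[ok] - p1.F[ok])) < 1e-6

    def test_disconnected_windows_fail_with_named_gap(self):
        scheme = m.WindowScheme(windows=((0.0, 4.0), (3.0, 7.0)), k=10.0)
        r0 = _manual_replica(np.linspace(0.2, 2.0, 50), window=(0.0, 4.0))
        r1 = _manual_replica(np.linspace(5.0, 6.8, 50), window=(3.0, 7.0),
                             index=3)
        with pytest.raises(ValueError, match="overlap"):
            m.wham_combine([r0, r1], scheme)


class TestPMFGrid:
    def test_uniform_weights_uniform_samples_give_flat_zero_pmf(self):
        rng = np.random.default_rng(1)
        n = 200000
        cvs = np.stack([rng.uniform(0, 30, n), np.full(n, 90.0),
                        rng.uniform(0, 180, n)], axis=-1)
        ws = m.WeightedSamples(cvs=cvs, times=np.arange(n, dtype=float),
                               replica=np.zeros(n, dtype=int),
                               log_weight=np.zeros(n))
        pmf = m.pmf_from_weights(ws, ["z"], m.EstimatorConfig())
        assert np.nanmax(np.abs(pmf.F)) < 0.15

    def test_equals_direct_boltzmann_inversion_on_unbiased_samples(self):
        """Zero-bias path: the estimator must reduce exactly to a plain
        -kT ln histogram with the same reference."""
        rng = np.random.default_rng(2)
        z = rng.normal(15.0, 3.0, 5000).clip(0.01, 29.99)
        cvs = np.stack([z, np.full_like(z, 90.0), np.full_like(z, 90.0)],
                       axis=-1)
        ws = m.WeightedSamples(cvs=cvs, times=np.arange(len(z), dtype=float),
                               replica=np.zeros(len(z), dtype=int),
                               log_weight=np.zeros(len(z)))
        cfg = m.EstimatorConfig(bulk_slab=(10.0, 20.0))
        pmf = m.pmf_from_weights(ws, [("z", np.linspace(0, 30, 31))], cfg)
        hist, _ = np.histogram(z, bins=np.linspace(0, 30, 31))
        with np.errstate(divide="ignore"):
            f_direct = np.where(hist > 0, -cfg.kT * np.log(hist), np.nan)
        centers = pmf.centers(0)
        sel = (centers >= 10) & (centers <= 20) & np.isfinite(f_direct)
        f_direct -= f_direct[sel].mean()
        ok = np.isfinite(f_direct)
        assert np.allclose(pmf.F[ok], f_direct[ok], atol=1e-10)
        assert np.all(np.isnan(pmf.F[~ok]))

    def test_empty_reference_slab_rejected(self):
        z = np.linspace(0, 5, 100)
        cvs = np.stack([z, np.full_like(z, 90.0), np.full_like(z, 90.0)],
                       axis=-1)
        ws = m.WeightedSamples(cvs=cvs, times=np.arange(100, dtype=float),
                               replica=np.zeros(100, dtype=int),
                               log_weight=np.zeros(100))
        cfg = m.EstimatorConfig(bulk_slab=(20.0, 25.0))
        with pytest.raises(ValueError):
            m.pmf_from_weights(ws, [("z", np.linspace(0, 5, 6))], cfg)


class TestBlockErrors:
    def _ws(self, z, times):
        cvs = np.stack([z, np.full_like(z, 90.0), np.full_like(z, 90.0)],
                       axis=-1)
        return m.WeightedSamples(cvs=cvs, times=times,
                                 replica=np.zeros(len(z), dtype=int),
                                 log_weight=np.zeros(len(z)))

    def test_duplicated_halves_have_zero_error(self):
        rng = np.random.default_rng(3)
        half = rng.uniform(0, 30, 2000)
        z = np.concatenate([half, half])
        times = np.concatenate([np.arange(2000), 2000 + np.arange(2000)]) \
            .astype(float)
        err = m.block_errors(self._ws(z, times), 2,
                             [("z", np.linspace(0, 30, 16))],
                             m.EstimatorConfig(bulk_slab=(20.0, 30.0)))
        assert np.nanmax(err) < 1e-12

    def test_errors_nonnegative_and_shrink_with_sampling(self):
        rng = np.random.default_rng(4)
        cfg = m.EstimatorConfig(bulk_slab=(20.0, 30.0))
        axes = [("z", np.linspace(0, 30, 16))]
        small = self._ws(rng.uniform(0, 30, 2000),
                         np.arange(2000, dtype=float))
        big = self._ws(rng.uniform(0, 30, 50000),
                       np.arange(50000, dtype=float))
        e_small = m.block_errors(small, 5, axes, cfg)
        e_big = m.block_errors(big, 5, axes, cfg)
        assert np.nanmin(e_small) >= 0
        assert np.nanmedian(e_big) < np.nanmedian(e_small)
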