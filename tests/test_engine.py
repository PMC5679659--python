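"""Sampler: window scheme, replica layout, hills, Langevin, bias exchange."""

import numpy as np
import pytest

import memfes as m
from memfes.constants import KT_310
from memfes.engine import ReplicaSpec, exchange_log_prob


class TestWindowScheme:
    @pytest.mark.parametrize("zmin,zmax,n,first,last", [
        (0.0, 52.0, 17, (0.0, 4.0), (48.0, 52.0)),
        (0.0, 4.0, 1, (0.0, 4.0), (0.0, 4.0)),
        (0.0, 55.0, 18, (0.0, 4.0), (51.0, 55.0)),
    ])
    def test_tiling(self, zmin, zmax, n, first, last):
        s = m.build_window_scheme(zmin, zmax, 4, 1, k=10.0)
        assert s.n_windows == n
        assert s.windows[0] == first
        assert s.windows[-1] == last

    def test_adjacent_overlap_is_exactly_one_angstrom(self):
        s = m.build_window_scheme(0.0, 52.0, 4, 1)
        for (lo0, hi0), (lo1, hi1) in zip(s.windows, s.windows[1:]):
            assert hi0 - lo1 == pytest.approx(1.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            m.build_window_scheme(0, 52, 4, 4)
        with pytest.raises(ValueError):
            m.build_window_scheme(0, 2, 4, 1)


class TestReplicaLayout:
    def test_17_windows_give_51_replicas(self):
        s = m.build_window_scheme(0, 52, 4, 1)
        assert len(m.build_replica_layout(s)) == 51

    def test_18_windows_give_54_replicas(self):
        s = m.build_window_scheme(0, 55, 4, 1)
        assert len(m.build_replica_layout(s)) == 54

    def test_index_to_cv_mapping(self):
        s = m.build_window_scheme(0, 4, 4, 1)
        layout = m.build_replica_layout(s)
        assert [(r.window, r.cv_name) for r in layout] == \
            [(0, "z"), (0, "theta"), (0, "phi")]


class TestHills:
    def test_zero_local_bias_deposits_initial_height(self):
        assert m.hill_height(0.0, 1.0, 10.0, KT_310) == 1.0

    def test_one_tempering_unit_decays_by_e(self):
        assert m.hill_height((10 - 1) * KT_310, 1.0, 10.0, KT_310) \
            == pytest.approx(np.exp(-1.0))
        assert m.hill_height(23.193, 1.0, 10.0, 2.577) \
            == pytest.approx(np.exp(-1.0), rel=1e-6)

    def test_gamma_must_exceed_one(self):
        with pytest.raises(ValueError):
            m.hill_height(0.0, 1.0, 1.0)

    def test_heights_bounded_and_monotone(self):
        v = np.linspace(0, 50, 100)
        w = m.hill_height(v, 1.0, 10.0)
        assert np.all(w <= 1.0) and np.all(w > 0)
        assert np.all(np.diff(w) < 0)


class TestBiasAndRestraint:
    def test_no_hills_no_bias(self):
        b = m.BiasState(sigma=1.0, w0=1.0, gamma=10.0, stride=500)
        assert m.bias_energy([0.0, 5.0], b).tolist() == [0.0, 0.0]

    def test_single_hill_gaussian_value(self):
        b = m.BiasState(sigma=1.0, w0=1.0, gamma=10.0, stride=500,
                        times=np.array([1.0]), centers=np.array([0.0]),
                        heights=np.array([1.0]))
        assert m.bias_energy(1.0, b)[0] == pytest.approx(np.exp(-0.5))

    def test_restraint_zero_inside_quadratic_outside(self):
        z = np.array([1.0, 3.9, -1.0, 6.0])
        e = m.restraint_energy(z, (0.0, 4.0), k=10.0)
        assert e[0] == 0.0 and e[1] == 0.0
        assert e[2] == pytest.approx(5.0)      # 10/2 * 1^2
        assert e[3] == pytest.approx(20.0)     # 10/2 * 2^2


class TestLangevin:
    def test_equipartition_in_harmonic_well(self):
        k = 2.0
        land = m.harmonic_1d(k=k)
        params = m.LangevinParams(n_steps=200000, seed=3, frame_stride=5,
                                  mobility=(0.01, 2.0, 2.0))
        traj = m.langevin_run(land, params, metadynamics=False)
        var = traj.states[400:, 0].var()
        assert var == pytest.approx(KT_310 / k, rel=0.05)

    def test_zero_temperature_descends_to_minimum(self):
        land = m.double_well_1d()
        params = m.LangevinParams(kT=0.0, n_steps=3000, seed=0,
                                  mobility=(0.05, 2, 2), frame_stride=100)
        traj = m.langevin_run(land, params, metadynamics=False)
        final = traj.states[-1, 0]
        assert min(abs(final - 5.0), abs(final - 15.0)) < 0.2

    def test_same_seed_identical_trajectory(self, landscape):
        scheme = m.build_window_scheme(-10, 2, 4, 1)
        params = m.LangevinParams(n_steps=2000, seed=7)
        a = m.run_campaign(landscape, scheme, params=params)
        b = m.run_campaign(landscape, scheme, params=params)
        for ra, rb in zip(a.replicas, b.replicas):
            assert np.array_equal(ra.states, rb.states)
            assert np.array_equal(ra.bias.heights, rb.bias.heights)


class TestExchange:
    def _empty_bias(self):
        return m.BiasState(sigma=1.0, w0=1.0, gamma=10.0, stride=500)

    def test_identical_biases_always_accepted(self):
        rng = np.random.default_rng(0)
        b = self._empty_bias()
        for _ in range(20):
            assert m.attempt_exchange(
                ReplicaSpec(0), ReplicaSpec(1),
                np.array([1.0, 90, 90]), np.array([2.0, 90, 90]),
                b, b, (0, 4), (0, 4), k=10.0, rng=rng)

    def test_deep_restraint_violation_effectively_rejected(self):
        # swapping a walker 2 A outside its window at k=1000 kJ/mol/A^2
        logp = exchange_log_prob(
            np.array([2.0, 90, 90]), np.array([6.0, 90, 90]),
            self._empty_bias(), self._empty_bias(),
            (0.0, 4.0), (4.0, 8.0), ReplicaSpec(3), ReplicaSpec(4),
            k=1000.0, kT=2.577)
        assert logp == pytest.approx(-2 * 2000.0 / 2.577, rel=1e-6)

    def test_non_adjacent_pair_rejected(self):
        b = self._empty_bias()
        with pytest.raises(ValueError):
            m.attempt_exchange(ReplicaSpec(0), ReplicaSpec(2),
                               np.zeros(3), np.zeros(3), b, b,
                               (0, 4), (0, 4), 10.0,
                               np.random.default_rng(0))

    def test_exchange_preserves_equilibrium_histograms(self):
        """With exchanges on or off, each restrained replica must sample the
        same stationary distribution (chi-squared two-sample test)."""
        from scipy.stats import chi2_contingency
        land = m.double_well_1d()
        scheme = m.build_window_scheme(0.0, 30.0, 16.5, 3.0, k=5.0)
        params = m.LangevinParams(n_steps=60000, seed=21, frame_stride=10,
                                  hill_w0=0.0)
        on = m.run_campaign(land, scheme, params=params, exchange_stride=200)
        off = m.run_campaign(land, scheme, params=params, exchange_stride=0)
        assert on.exchange_attempts > 0 and off.exchange_attempts == 0
        edges = np.linspace(0, 30, 16)
        z_on = on.replicas[0].states[200::20, 0]   # thin against autocorrelation
        z_off = off.replicas[0].states[200::20, 0]
        h_on, _ = np.histogram(z_on, bins=edges)
        h_off, _ = np.histogram(z_off, bins=edges)
        keep = (h_on + h_off) >= 5
        _, p, _, _ = chi2_contingency(np.stack([h_on[keep], h_off[keep]]))
        assert p > 1e-3

    def test_acceptance_rate_is_a_probability(self, small_campaign):
        assert 0.0 <= small_campaign.acceptance_rate <= 1.0


class TestCampaign:
    def test_zero_steps_yield_empty_run_without_error(self, landscape):
        scheme = m.build_window_scheme(-10, -6, 4, 1)
        params = m.LangevinParams(n_steps=0, seed=0)
        out = m.run_campaign(landscape, scheme, params=params)
        assert len(out.replicas) == 3
        for r in out.replicas:
            assert r.bias.n_hills == 0
            assert len(r.times) <= 1

    def test_double_well_campaign_visits_both_wells_per_spanning_window(self):
        land = m.double_well_1d()   # wells at z=5 and z=15
        scheme = m.build_window_scheme(0.0, 30.0, 16.5, 3.0, k=5.0)
        params = m.LangevinParams(n_steps=40000, seed=13, frame_stride=10)
        out = m.run_campaign(land, scheme, params=params, exchange_stride=250)
        for r in out.replicas:
            lo, hi = r.window
            if lo <= 5.0 and hi >= 15.0 and r.spec.cv_index == 0:
                z = r.biased_cv
                assert (np.abs(z - 5.0) < 1.5).any()
                assert (np.abs(z - 15.0) < 1.5).any()

    def test_divergent_step_aborts_with_diagnostic(self):
        land = m.harmonic_1d(k=1e6, domain=((-5.0, 5.0),))
        params = m.LangevinParams(n_steps=100, seed=0, mobility=(1.0, 2, 2))
        with pytest.raises(RuntimeError, match="divergent"):
            m.langevin_run(land, params, metadynamics=False)
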