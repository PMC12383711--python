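"""Spiking cube: construction, LIF dynamics, STDP rule, block
presentation and weight snapshots."""

import numpy as np
import pytest

from ecodec import snn
from ecodec.config import SnnConfig


def make_cube(**kw):
    params = SnnConfig(**kw)
    return snn.build_cube(seed=7, params=params)


class TestBuildCube:
    def test_same_seed_reproduces_weights(self):
        a = snn.build_cube(seed=5)
        b = snn.build_cube(seed=5)
        assert np.array_equal(a.mag, b.mag)
        assert np.array_equal(a.sign, b.sign)

    def test_no_self_connections(self):
        cube = snn.build_cube(seed=0)
        assert np.all(np.diag(cube.mag) == 0)
        assert np.all(np.diag(cube.sign) == 0)

    def test_dale_sign_per_presynaptic_neuron(self):
        cube = snn.build_cube(seed=0)
        off = ~np.eye(cube.n, dtype=bool)
        for i in range(cube.n):
            row = cube.sign[i][off[i]]
            assert len(np.unique(row)) == 1

    def test_exp_decay_kernel_favors_near_pairs(self):
        # Monte-Carlo over seeds: expected |w| of the nearest pair exceeds
        # that of the farthest pair under the decaying kernel
        coords = snn.default_electrode_grid()
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        d[np.diag_indices_from(d)] = np.inf
        near = np.unravel_index(np.argmin(d), d.shape)
        far = np.unravel_index(np.argmax(np.where(np.isinf(d), -1, d)),
                               d.shape)
        near_w, far_w = [], []
        for seed in range(30):
            cube = snn.build_cube(seed=seed)
            near_w.append(cube.mag[near])
            far_w.append(cube.mag[far])
        assert np.mean(near_w) > np.mean(far_w)

    def test_linear_kernel_grows_with_distance(self):
        coords = snn.default_electrode_grid()
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        d[np.diag_indices_from(d)] = np.inf
        near = np.unravel_index(np.argmin(d), d.shape)
        far = np.unravel_index(np.argmax(np.where(np.isinf(d), -1, d)),
                               d.shape)
        near_w, far_w = [], []
        for seed in range(30):
            cube = snn.build_cube(seed=seed, params=SnnConfig(
                distance_kernel="linear_proportional"))
            near_w.append(cube.mag[near])
            far_w.append(cube.mag[far])
        assert np.mean(far_w) > np.mean(near_w)

    def test_duplicate_coordinates_warn_and_jitter(self):
        coords = snn.default_electrode_grid()
        coords[1] = coords[0]
        with pytest.warns(UserWarning, match="duplicate"):
            cube = snn.build_cube(coords, seed=0)
        assert not np.array_equal(cube.coords[0], cube.coords[1])

    def test_wrong_coordinate_count_raises(self):
        with pytest.raises(ValueError):
            snn.build_cube(np.zeros((10, 2)), seed=0)


class TestLifStep:
    def test_rest_is_equilibrium(self):
        cube = snn.build_cube(seed=0)
        v0 = cube.v.copy()
        for _ in range(100):
            spikes = snn.lif_step(cube, np.zeros(cube.n), 0.1)
            assert not spikes.any()
        assert np.allclose(cube.v, v0)

    def test_subthreshold_current_never_spikes(self):
        p = SnnConfig()
        cube = snn.build_cube(seed=0, params=p)
        # rheobase: R*I = V_th - V_rest = 15 mV -> I = 1.5 nA
        current = np.full(cube.n, 1.4)
        for _ in range(20000):
            assert not snn.lif_step(cube, current, 0.1).any()

    def test_suprathreshold_rate_matches_closed_form(self):
        p = SnnConfig(dt_ms=0.05)
        cube = snn.build_cube(seed=0, params=p)
        cube.mag[:] = 0.0  # isolated neurons
        current = np.full(cube.n, 2.5)
        times = []
        for step in range(60000):  # 3 s at 0.05 ms
            if snn.lif_step(cube, current, p.dt_ms)[0]:
                times.append(cube.t_now)
        measured = 1000.0 * (len(times) - 1) / (times[-1] - times[0])
        expected = snn.lif_rate_closed_form(2.5, p)
        assert measured == pytest.approx(expected, rel=0.02)

    def test_non_finite_current_rejected(self):
        cube = snn.build_cube(seed=0)
        with pytest.raises(ValueError):
            snn.lif_step(cube, np.full(cube.n, np.nan), 0.1)


class TestStdpUpdate:
    def test_pre_before_post_potentiates_by_formula(self):
        p = SnnConfig(a_plus=0.01, tau_plus_ms=20.0)
        cube = snn.build_cube(seed=1, params=p)
        i, j = 2, 5
        w0 = cube.mag[i, j]
        snn.stdp_update(cube, [(10.0, i), (15.0, j)])
        assert cube.mag[i, j] - w0 == pytest.approx(
            0.01 * np.exp(-0.25), rel=1e-12)

    def test_post_before_pre_depresses(self):
        cube = snn.build_cube(seed=1)
        i, j = 2, 5
        w0 = cube.mag[i, j]
        snn.stdp_update(cube, [(10.0, j), (15.0, i)])
        assert cube.mag[i, j] < w0

    def test_no_spikes_no_change(self):
        cube = snn.build_cube(seed=1)
        mag0 = cube.mag.copy()
        snn.stdp_update(cube, [])
        assert np.array_equal(cube.mag, mag0)

    def test_magnitudes_stay_in_bounds_under_fuzz(self):
        p = SnnConfig(a_plus=0.05, a_minus=0.06, w_max=1.0)
        cube = snn.build_cube(seed=3, params=p)
        rng = np.random.default_rng(0)
        t = 0.0
        events = []
        for _ in range(20000):
            t += rng.exponential(2.0)
            events.append((t, int(rng.integers(cube.n))))
        snn.stdp_update(cube, events)
        assert cube.mag.min() >= 0.0
        assert cube.mag.max() <= p.w_max


class TestPresentBlock:
    def test_zero_features_from_rest_silent_and_static(self):
        cube = snn.build_cube(seed=2)
        mag0 = cube.mag.copy()
        rates = snn.present_block(cube, np.zeros((59, cube.n)), 100.0)
        assert np.all(rates == 0)
        assert np.array_equal(cube.mag, mag0)

    def test_rate_bound_under_huge_drive(self):
        p = SnnConfig()
        cube = snn.build_cube(seed=2, params=p)
        cube.gain = 1.0
        window = 100.0
        rates = snn.present_block(cube, np.full((59, cube.n), 1e4), window)
        assert np.all(rates > 0)
        # asymptotic ISI bound plus the one extra spike a finite window fits
        assert np.all(rates <= 1000.0 / (p.t_ref_ms + p.dt_ms)
                      + 1000.0 / window)

    def test_bit_deterministic_with_frozen_stdp(self):
        p = SnnConfig(stdp_on=False)
        rng = np.random.default_rng(8)
        feats = np.abs(rng.normal(1000, 200, (59, 64)))
        a = snn.build_cube(seed=4, params=p)
        b = snn.build_cube(seed=4, params=p)
        a.gain = b.gain = 2e-3
        for _ in range(3):
            ra = snn.present_block(a, feats, 100.68)
            rb = snn.present_block(b, feats, 100.68)
            assert np.array_equal(ra, rb)
        assert np.array_equal(a.v, b.v)
        assert np.array_equal(a.mag, b.mag)

    def test_matches_stepwise_reference_without_synapses(self):
        # fused kernel vs the step-by-step LIF reference on isolated
        # neurons under the same zero-order-hold drive
        p = SnnConfig(stdp_on=False, syn_gain_na=0.0)
        cube = snn.build_cube(seed=5, params=p)
        cube.mag[:] = 0.0
        cube.gain = 1.0
        rng = np.random.default_rng(9)
        feats = np.abs(rng.normal(2.0, 0.5, (59, 64)))
        ref = cube.copy()
        window = 100.0
        rates = snn.present_block(cube, feats, window)
        n_steps = int(round(window / p.dt_ms))
        counts = np.zeros(64)
        for step in range(n_steps):
            row = min(int(step * p.dt_ms * 59 / window), 58)
            counts += snn.lif_step(ref, feats[row], p.dt_ms)
        assert np.array_equal(rates, counts / (window / 1000.0))

    def test_repeated_presentation_stabilises_weights(self):
        p = SnnConfig(a_plus=2e-3, a_minus=2.4e-3)
        cube = snn.build_cube(seed=6, params=p)
        rng = np.random.default_rng(10)
        feats = np.abs(rng.normal(1500, 300, (59, 64)))
        cube.gain = 1.5e-3
        deltas = []
        prev = cube.mag.copy()
        for _ in range(20):
            snn.present_block(cube, feats, 100.0)
            deltas.append(np.linalg.norm(cube.mag - prev))
            prev = cube.mag.copy()
        assert np.mean(deltas[-5:]) <= np.mean(deltas[:5])


class TestCalibration:
    def test_gain_satisfies_closed_form_identity(self, rng):
        cube = snn.build_cube(seed=0)
        feats = np.abs(rng.normal(1000, 100, (20, 59, 64)))
        gain = snn.calibrate_gain(cube, feats)
        med = np.median(feats)
        target_current = snn.current_for_rate(
            cube.params.target_rate_hz, cube.params)
        assert gain * med == pytest.approx(target_current, rel=1e-12)

    def test_rate_inversion_round_trip(self):
        p = SnnConfig()
        for rate in (5.0, 20.0, 80.0, 200.0):
            current = snn.current_for_rate(rate, p)
            assert snn.lif_rate_closed_form(current, p) == pytest.approx(
                rate, rel=1e-9)

    def test_subrheobase_rate_is_zero(self):
        p = SnnConfig()
        assert snn.lif_rate_closed_form(1.0, p) == 0.0


class TestSnapshot:
    def test_round_trip_and_shape(self, tmp_path):
        cube = snn.build_cube(seed=0)
        path = tmp_path / "w.csv"
        snn.snapshot_weights(cube, path)
        back = np.loadtxt(path, delimiter=",")
        assert back.shape == (64, 64)
        assert np.allclose(back, cube.weights)

    def test_snapshot_unchanged_by_zero_input(self, tmp_path):
        cube = snn.build_cube(seed=0)
        snn.snapshot_weights(cube, tmp_path / "before.csv")
        snn.present_block(cube, np.zeros((59, cube.n)), 100.0)
        snn.snapshot_weights(cube, tmp_path / "after.csv")
        assert (tmp_path / "before.csv").read_text() == \
            (tmp_path / "after.csv").read_text()
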