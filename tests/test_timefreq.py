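"""Complex demodulation and the derived spectral measures."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.signal import hilbert

from oscmmn.simulate import (
    AlphaDesync,
    NoiseSpec,
    SimConfig,
    StimulusSchedule,
    ThetaReset,
    generate_epochs,
    generate_schedule,
)
from oscmmn.timefreq import (
    EdgeHandlingError,
    PairingError,
    TFRGrid,
    complex_demodulate,
    itpl,
    itpl_change,
    match_standard_trials,
    non_phase_locked_power_change,
    overall_power_change,
    phase_locked_power,
)

FS = 1000.0
N = 901


def _sine_epochs(maker, amp, freq, phase, n_ch=2):
    t = (-300.0 + np.arange(N)) / 1000.0
    sig = amp * np.cos(2 * np.pi * freq * t + phase)
    return maker(np.tile(sig, (1, n_ch, 1)), fs=FS, t0=-300.0)


def _grid(values, freqs, lats):
    return TFRGrid(
        values=np.asarray(values, dtype=complex),
        frequencies_hz=np.asarray(freqs, dtype=float),
        latencies_ms=np.asarray(lats, dtype=float),
        channel_names=[f"ch{i}" for i in range(np.asarray(values).shape[1])],
        edge_mask=np.zeros(len(lats), dtype=bool),
        sampling_rate_hz=FS,
    )


class TestComplexDemodulate:
    def test_recovers_amplitude_and_phase_of_pure_sine(self, epochs_maker):
        # independent oracle: analytic signal via the Hilbert transform
        amp, freq, phase = 2.0, 10.0, 0.7
        ep = _sine_epochs(epochs_maker, amp, freq, phase)
        analytic = hilbert(ep.data[0, 0])
        tfr = complex_demodulate(ep, np.array([10.0]))
        ok = ~tfr.edge_mask
        idx = np.round((tfr.latencies_ms[ok] + 300.0)).astype(int)
        v = tfr.values[0, 0, 0, ok]
        # demodulated envelope convention: magnitude = analytic amplitude / 2
        np.testing.assert_allclose(2 * np.abs(v), np.abs(analytic[idx]), rtol=0.02)
        inst_phase = np.angle(analytic[idx] * np.exp(-2j * np.pi * freq * ep.times_ms[idx] / 1000.0))
        dphi = np.angle(np.exp(1j * (np.angle(v) - inst_phase)))
        assert np.abs(dphi).max() < 0.05

    def test_off_frequency_attenuation(self, epochs_maker):
        ep = _sine_epochs(epochs_maker, 2.0, 10.0, 0.0)
        tfr = complex_demodulate(ep, np.array([10.0, 30.0]))
        ok = ~tfr.edge_mask
        on = np.abs(tfr.values[0, 0, 0, ok]).mean()
        off = np.abs(tfr.values[0, 0, 1, ok]).max()
        assert off < 0.05 * on

    def test_zero_input_gives_zero_grid(self, epochs_maker):
        ep = epochs_maker(np.zeros((2, 3, N)))
        tfr = complex_demodulate(ep)
        assert np.abs(tfr.values).max() == 0.0

    def test_axes_and_grid_shape(self, epochs_maker, rng):
        ep = epochs_maker(rng.normal(size=(2, 3, N)))
        tfr = complex_demodulate(ep)
        assert tfr.values.shape == (2, 3, 24, 37)
        assert np.all(np.diff(tfr.frequencies_hz) == 2.0)
        assert np.all(np.diff(tfr.latencies_ms) == 25.0)
        assert tfr.latencies_ms[0] == -300.0

    def test_spectral_and_time_domain_paths_agree(self, epochs_maker, rng):
        import oscmmn.timefreq as tf

        ep = epochs_maker(rng.normal(size=(2, 2, N)))
        fast = complex_demodulate(ep)
        orig = tf._integer_bin_length
        tf._integer_bin_length = lambda *a, **k: None
        try:
            slow = complex_demodulate(ep)
        finally:
            tf._integer_bin_length = orig
        scale = np.abs(slow.values).max()
        assert np.abs(fast.values - slow.values).max() / scale < 0.02

    def test_nyquist_guard_and_short_epochs(self, epochs_maker):
        ep = epochs_maker(np.zeros((1, 2, N)))
        with pytest.raises(ValueError, match="Nyquist"):
            complex_demodulate(ep, np.array([600.0]))
        short = epochs_maker(np.zeros((1, 2, 100)))
        with pytest.raises(EdgeHandlingError):
            complex_demodulate(short, np.array([10.0]), filter_bandwidth_hz=4.0)


class TestPowerDecomposition:
    def test_total_power_identity(self, epochs_maker, rng):
        # law of total power under the subtraction definition, via the API
        ep = epochs_maker(rng.normal(size=(8, 3, N)))
        tfr = complex_demodulate(ep)
        baseline = (-300.0, 0.0)
        ov = overall_power_change(tfr, baseline).values
        npl = non_phase_locked_power_change(tfr, baseline).values
        pl = phase_locked_power(tfr)
        bl = tfr.latency_mask(baseline)
        pl_change = pl - pl[..., bl].mean(axis=-1, keepdims=True)
        np.testing.assert_allclose(ov - npl, pl_change, atol=1e-12 * np.abs(ov).max())

    def test_phase_locked_trials_leave_no_residual(self, epochs_maker):
        ep = _sine_epochs(epochs_maker, 1.5, 10.0, 0.3)
        data = np.repeat(ep.data, 6, axis=0)
        tfr = complex_demodulate(epochs_maker(data), np.array([10.0]))
        resid = tfr.values - tfr.values.mean(axis=0, keepdims=True)
        assert np.abs(resid).max() < 1e-10 * np.abs(tfr.values).max()

    def test_overall_power_is_phase_blind(self, rng):
        # same amplitudes, aligned vs scrambled phases -> identical overall power
        lats = np.arange(-300.0, 601.0, 25.0)
        amp = rng.uniform(0.5, 2.0, size=(10, 2, 3, len(lats)))
        aligned = _grid(amp * np.exp(1j * 0.4), [4, 6, 8], lats)
        phases = rng.uniform(-np.pi, np.pi, size=amp.shape)
        scrambled = _grid(amp * np.exp(1j * phases), [4, 6, 8], lats)
        np.testing.assert_allclose(
            overall_power_change(aligned).values,
            overall_power_change(scrambled).values,
            atol=1e-12,
        )

    def test_uniform_phase_residual_fraction(self, rng):
        # n trials of unit amplitude, uniform phase: E residual = (1 - 1/n) A^2
        n = 8
        lats = np.arange(-300.0, 601.0, 25.0)
        phases = rng.uniform(-np.pi, np.pi, size=(n, 4, 6, len(lats)))
        tfr = _grid(np.exp(1j * phases), np.arange(4, 16, 2), lats)
        resid = tfr.values - tfr.values.mean(axis=0, keepdims=True)
        frac = (np.abs(resid) ** 2).mean()
        assert frac == pytest.approx(1 - 1 / n, rel=0.02)

    def test_residual_isolates_unlocked_component(self, rng, epochs_maker):
        # locked 10 Hz + unlocked 30 Hz mixture: the residual's power at
        # 30 Hz matches the unlocked component alone within 5%
        t = (-300.0 + np.arange(N)) / 1000.0
        n = 40
        locked = 2.0 * np.cos(2 * np.pi * 10 * t + 0.3)
        phases = rng.uniform(-np.pi, np.pi, n)
        unlocked = np.stack([1.2 * np.cos(2 * np.pi * 30 * t + p) for p in phases])
        mix = epochs_maker((locked + unlocked)[:, None, :])
        alone = epochs_maker(unlocked[:, None, :])
        freqs = np.array([30.0])
        tfr_mix = complex_demodulate(mix, freqs)
        tfr_alone = complex_demodulate(alone, freqs)
        ok = ~tfr_mix.edge_mask
        resid = tfr_mix.values - tfr_mix.values.mean(axis=0, keepdims=True)
        p_resid = (np.abs(resid[..., ok]) ** 2).mean()
        p_alone = (np.abs(tfr_alone.values[..., ok]) ** 2).mean()
        assert p_resid == pytest.approx(p_alone, rel=0.05)

    def test_single_trial_rejected(self, epochs_maker):
        ep = epochs_maker(np.zeros((1, 2, N)))
        tfr = complex_demodulate(ep, np.array([10.0]))
        with pytest.raises(ValueError):
            non_phase_locked_power_change(tfr)


class TestITPL:
    lats = np.arange(-300.0, 601.0, 25.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1), n=st.integers(2, 24))
    def test_bounded_in_unit_interval(self, seed, n):
        r = np.random.default_rng(seed)
        vals = r.uniform(0.1, 5.0, (n, 2, 2, 5)) * np.exp(1j * r.uniform(-np.pi, np.pi, (n, 2, 2, 5)))
        lats = np.arange(5) * 25.0 - 300.0
        out = itpl(_grid(vals, [4, 6], lats)).values
        assert np.all(out >= -1e-12) and np.all(out <= 1 + 1e-12)

    def test_identical_phases_give_one(self):
        tfr = _grid(np.full((5, 2, 3, len(self.lats)), 1.7 * np.exp(0.9j)), [4, 6, 8], self.lats)
        np.testing.assert_allclose(itpl(tfr).values, 1.0, atol=1e-12)

    def test_evenly_spaced_phases_give_zero(self):
        n = 6
        phases = 2 * np.pi * np.arange(n) / n
        vals = np.exp(1j * phases)[:, None, None, None] * np.ones((n, 2, 2, len(self.lats)))
        tfr = _grid(vals, [4, 6], self.lats)
        np.testing.assert_allclose(itpl(tfr).values, 0.0, atol=1e-12)

    def test_amplitude_scaling_invariance(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=(7, 3, 4, len(self.lats)))
        base = _grid(np.exp(1j * phases), np.arange(4, 12, 2), self.lats)
        amps = rng.uniform(0.1, 10.0, size=phases.shape)
        scaled = _grid(amps * np.exp(1j * phases), np.arange(4, 12, 2), self.lats)
        np.testing.assert_allclose(itpl(base).values, itpl(scaled).values, rtol=1e-12)

    def test_uniform_phase_mean_square(self, rng):
        # E[ITPL^2] = 1/n for uniform phases
        n = 20
        phases = rng.uniform(-np.pi, np.pi, size=(n, 10, 10, len(self.lats)))
        tfr = _grid(np.exp(1j * phases), np.arange(4, 24, 2), self.lats)
        r2 = itpl(tfr).values ** 2
        assert r2.mean() == pytest.approx(1 / n, rel=0.05)

    def test_zero_magnitude_cells_excluded(self):
        vals = np.full((4, 1, 1, len(self.lats)), np.exp(0.5j))
        vals[0, 0, 0, 0] = 0.0
        tfr = _grid(vals, [6], self.lats)
        m = itpl(tfr)
        assert m.n_excluded_cells == 1
        assert m.values[0, 0, 0] == pytest.approx(1.0)

    def test_baseline_subtracted_variant(self, rng):
        phases = rng.uniform(-np.pi, np.pi, size=(9, 2, 2, len(self.lats)))
        m = itpl(_grid(np.exp(1j * phases), [4, 6], self.lats))
        mc = itpl_change(m, (-300.0, 0.0))
        bl = (self.lats >= -300) & (self.lats <= 0)
        np.testing.assert_allclose(mc.values[..., bl].mean(axis=-1), 0.0, atol=1e-12)


def test_tfr_hdf5_roundtrip(tmp_path, epochs_maker, rng):
    ep = epochs_maker(rng.normal(size=(2, 2, N)))
    tfr = complex_demodulate(ep, np.array([6.0, 12.0]))
    path = tmp_path / "tfr.h5"
    ep.to_hdf5(path)  # TFR stored alongside the epoch container
    tfr.to_hdf5(path)
    back = TFRGrid.from_hdf5(path)
    np.testing.assert_array_equal(back.values, tfr.values)
    np.testing.assert_array_equal(back.edge_mask, tfr.edge_mask)
    assert back.channel_names == tfr.channel_names


class TestLinearity:
    def test_complex_average_subtraction_equals_time_domain(self, epochs_maker, rng):
        # demodulation is linear: subtracting the complex trial-average
        # equals demodulating (trial - time-domain average)
        data = rng.normal(size=(6, 2, N))
        ep = epochs_maker(data)
        tfr = complex_demodulate(ep, np.array([6.0, 12.0]))
        resid_freq = tfr.values - tfr.values.mean(axis=0, keepdims=True)
        ep_resid = epochs_maker(data - data.mean(axis=0, keepdims=True))
        resid_time = complex_demodulate(ep_resid, np.array([6.0, 12.0])).values
        np.testing.assert_allclose(resid_freq, resid_time, atol=1e-9 * np.abs(tfr.values).max())


class TestMatchStandards:
    def _setup(self):
        sched = generate_schedule(6, (4, 1, 1), seed=10)
        cfg = SimConfig(
            n_channels=8,
            evoked_components=[],
            theta_reset=ThetaReset(amplitude_uv=0.0),
            alpha_desync=AlphaDesync(amplitude_uv=0.0),
            noise=NoiseSpec(rms_uv=1.0),
            seed=1,
        )
        return sched, generate_epochs(sched, cfg)

    def test_selects_preceding_standard_per_deviant(self):
        sched, ep = self._setup()
        matched, report = match_standard_trials(ep, sched)
        assert matched.n_trials == 6 == report.n_matched
        assert set(matched.condition) == {"standard"}
        kinds = sched.kinds
        for ev in matched.event_ids:
            assert kinds[ev] == "standard" and kinds[ev + 1] == "deviant"

    def test_rejected_standard_drops_pair(self):
        sched, ep = self._setup()
        dev_events = sched.indices("deviant")
        drop_event = dev_events[0] - 1
        keep = ep.event_ids != drop_event
        matched, report = match_standard_trials(ep.select_trials(keep), sched)
        assert report.n_matched == 5
        assert report.dropped_deviant_events == [int(dev_events[0])]

    def test_deviant_first_event_is_pairing_error(self):
        sched = StimulusSchedule(
            events=[(0.0, "deviant"), (800.0, "standard")],
            isi_range_ms=(612, 642),
            duration_ms=200,
        )
        ep = self._setup()[1]
        with pytest.raises(PairingError):
            match_standard_trials(ep, sched)

    def test_missing_event_ids_is_pairing_error(self, epochs_maker):
        sched, ep = self._setup()
        plain = epochs_maker(np.zeros((2, 2, 10)))
        with pytest.raises(PairingError):
            match_standard_trials(plain, sched)


class TestBandwidthRobustness:
    def test_itpl_contrast_stable_across_bandwidths(self):
        # the deviant > standard theta phase-locking contrast must not
        # depend on the envelope-filter bandwidth choice
        sched = generate_schedule(15, (4, 1, 1), seed=21)
        cfg = SimConfig.default(seed=21, n_channels=16)
        ep = generate_epochs(sched, cfg, event_subset=sched.deviant_and_preceding_standard_indices())
        dev = ep.pick_condition("deviant")
        std, _ = match_standard_trials(ep, sched)
        freqs = np.array([4.0, 6.0, 8.0])
        for bw in (2.0, 4.0, 8.0):
            tfr_d = complex_demodulate(dev, freqs, filter_bandwidth_hz=bw)
            tfr_s = complex_demodulate(std, freqs, filter_bandwidth_hz=bw)
            win = (tfr_d.latencies_ms >= 50) & (tfr_d.latencies_ms <= 250)
            d = itpl(tfr_d).values[:, 1, win].mean()
            s = itpl(tfr_s).values[:, 1, win].mean()
            assert d > s, f"bandwidth {bw}"
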