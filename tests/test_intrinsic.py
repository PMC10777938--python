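"""Intrinsic feature extraction: constructed-trace oracles, simulation oracles,
and invariants (scale invariance of CV ISI, monotone firing curves)."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vipcinq import intrinsic as intr
from vipcinq.synth import (
    NeuronModelParams,
    StimulusDescriptor,
    SweepFamily,
    simulate_family,
    simulate_sweep,
)
from vipcinq.synth.protocols import firing_protocol, rin_protocol, sag_protocol


def piecewise_trace(breakpoints, values, rate_khz, length_ms):
    t = np.arange(int(length_ms * rate_khz)) / rate_khz
    return np.interp(t, breakpoints, values)


def make_family(sweeps, rate_khz, length_ms):
    return SweepFamily(rate_khz, length_ms, sweeps, "current")


class TestRmp:
    def test_constant_segment(self):
        assert intr.measure_rmp(np.full(2000, -65.0), 10.0) == -65.0

    def test_noisy_segment_within_standard_error(self):
        rng = np.random.default_rng(0)
        seg = -65.0 + rng.normal(0, 0.5, 50_000)
        rmp = intr.measure_rmp(seg, 50.0)
        assert abs(rmp - (-65.0)) < 3 * 0.5 / np.sqrt(len(seg))
        assert rmp == pytest.approx(np.mean(seg))  # direct-mean oracle

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            intr.measure_rmp(np.array([]), 10.0)
        with pytest.raises(ValueError, match="shorter"):
            intr.measure_rmp(np.full(500, -65.0), 10.0)  # 50 ms at 10 kHz


def ohmic_family(r_mv_per_pa=0.1, noise_sd=0.0, seed=0, rate=10.0, v0=-65.0):
    rng = np.random.default_rng(seed)
    sweeps = []
    for amp in np.arange(-50.0, 21.0, 10.0):
        stim = StimulusDescriptor(amp, 200, 500)
        dv = amp * r_mv_per_pa
        tr = piecewise_trace(
            [0, 199.99, 200, 699.99, 700, 1000],
            [v0, v0, v0 + dv, v0 + dv, v0, v0],
            rate,
            1000,
        )
        if noise_sd:
            tr = tr + rng.normal(0, noise_sd, len(tr))
        sweeps.append((stim, tr))
    return make_family(sweeps, rate, 1000)


class TestRin:
    def test_ideal_ohmic_family_exact(self):
        assert intr.measure_rin(ohmic_family()) == pytest.approx(100.0, abs=1e-6)

    def test_noisy_family_matches_ols_oracle(self):
        fam = ohmic_family(noise_sd=0.1, seed=3)
        rin = intr.measure_rin(fam)
        # closed-form OLS oracle on the same steady-state points
        xs, ys = [], []
        for stim, tr in fam.sweeps:
            xs.append(stim.amplitude)
            ys.append(np.mean(tr[int(600 * 10) : int(700 * 10)]) - np.mean(tr[: 2000]))
        xs, ys = np.array(xs), np.array(ys)
        slope = np.sum((xs - xs.mean()) * (ys - ys.mean())) / np.sum((xs - xs.mean()) ** 2)
        assert rin == pytest.approx(slope * 1000.0, rel=1e-9)
        assert rin == pytest.approx(100.0, rel=0.05)

    def test_passive_cell_recovers_inverse_leak(self, passive_params):
        fam = simulate_family(passive_params, rin_protocol(), 50.0, 0)
        assert intr.measure_rin(fam) == pytest.approx(
            1000.0 / passive_params.leak_conductance, rel=0.02
        )

    def test_insufficient_sweeps_rejected(self):
        fam = ohmic_family()
        small = make_family(fam.sweeps[:2], 10.0, 1000)
        with pytest.raises(ValueError, match=">= 3"):
            intr.measure_rin(small)

    def test_zero_current_spread_rejected(self):
        stim = StimulusDescriptor(10.0, 200, 500)
        tr = np.zeros(10_000)
        fam = make_family([(stim, tr)] * 3, 10.0, 1000)
        with pytest.raises(ValueError, match="spread"):
            intr.measure_rin(fam)


def planted_spike_trace(peak_times_ms, rate_khz, length_ms, baseline=-65.0):
    tr = np.full(int(length_ms * rate_khz), baseline)
    for t in peak_times_ms:
        i = int(round(t * rate_khz))
        tr[i - 2 : i + 3] = [-20.0, 5.0, 15.0, 5.0, -20.0]
    return tr


class TestSpikeDetection:
    def test_flat_sweep_zero_spikes(self):
        train = intr.detect_spikes(np.full(10_000, -65.0), 10.0)
        assert train.n_spikes == 0

    def test_planted_spikes_recovered_at_peak_times(self):
        times = [100.0 + 50.0 * k for k in range(7)]
        tr = planted_spike_trace(times, 10.0, 600.0)
        train = intr.detect_spikes(tr, 10.0)
        assert train.n_spikes == 7
        assert np.allclose(train.peak_times_ms, times, atol=0.1)

    def test_simulated_sweep_count_matches_model_reset_log(self, wt_families):
        _, firing, _ = wt_families
        for (stim, tr), truth in zip(firing.sweeps, firing.spike_truth):
            assert intr.detect_spikes(tr, firing.sampling_rate_khz).n_spikes == len(truth)

    def test_merge_window_collapses_double_crossings(self):
        tr = np.full(5000, -65.0)
        tr[1000:1003] = [10.0, -1.0, 10.0]  # dips below cutoff for < 1 ms
        assert intr.detect_spikes(tr, 10.0).n_spikes == 1


def counted_firing_family(counts, amps, rate=10.0):
    sweeps = []
    for amp, k in zip(amps, counts):
        times = [250.0 + 40.0 * j for j in range(k)]
        sweeps.append(
            (StimulusDescriptor(amp, 200, 800), planted_spike_trace(times, rate, 1200))
        )
    return make_family(sweeps, rate, 1200)


class TestFiringOutput:
    def test_constructed_counts(self):
        fam = counted_firing_family([0, 0, 3, 8, 12], [25, 50, 75, 100, 125])
        fo = intr.firing_output(fam)
        assert fo.rheobase_pa == 75.0
        assert fo.max_firing_frequency_hz == pytest.approx(15.0)
        assert fo.firing_curve == [(25, 0), (50, 0), (75, 3), (100, 8), (125, 12)]

    def test_no_spikes_missing_rheobase(self):
        fam = counted_firing_family([0, 0, 0], [25, 50, 75])
        fo = intr.firing_output(fam)
        assert fo.rheobase_pa is None
        assert fo.max_firing_frequency_hz == 0.0

    def test_mixed_durations_rejected(self):
        s1 = (StimulusDescriptor(50.0, 200, 800), np.full(12_000, -65.0))
        s2 = (StimulusDescriptor(100.0, 200, 400), np.full(12_000, -65.0))
        fam = make_family([s1, s2], 10.0, 1200)
        with pytest.raises(ValueError, match="durations"):
            intr.firing_output(fam)

    def test_simulated_rheobase_brackets_analytic_threshold_current(self, vip_params):
        # EIF rheobase: I_rh = gL (VT - EL) - gL * dT, minus the small
        # depolarizing H-current at rest; brute force over the sweep family
        p = vip_params
        i_rh = p.leak_conductance * (p.intrinsic_threshold - p.leak_reversal) - (
            p.leak_conductance * p.spike_threshold_slope_factor
        )
        fam = simulate_family(p, firing_protocol(), 50.0, 0)
        fo = intr.firing_output(fam)
        levels = np.array([s.amplitude for s, _ in fam.sweeps])
        first_above = levels[levels > i_rh].min()
        assert fo.rheobase_pa <= first_above  # H-current can only lower it
        assert fo.rheobase_pa >= first_above - 25.0  # within one coarse step

    def test_rheobase_coarse_vs_fine_protocol(self, vip_params):
        coarse = intr.firing_output(
            simulate_family(vip_params, firing_protocol(), 50.0, 0)
        ).rheobase_pa
        fine_levels = tuple(float(a) for a in range(25, 151, 5))
        fine = intr.firing_output(
            simulate_family(vip_params, firing_protocol(levels_pa=fine_levels), 50.0, 0)
        ).rheobase_pa
        assert coarse >= fine
        assert coarse - fine < 25.0


class TestApWaveform:
    def test_sine_third_derivative_maximum(self):
        # V(t) = sin(t): d3V/dt3 = -cos(t), maximal at t = pi where V = 0
        t = np.linspace(0.0, 2 * np.pi, 20_001)
        v = np.sin(t)
        d3 = intr.third_derivative(v, t[1] - t[0])
        interior = slice(100, -100)
        i = 100 + int(np.argmax(d3[interior]))
        assert t[i] == pytest.approx(np.pi, abs=0.01)
        assert abs(v[i]) < 0.01

    def test_constructed_spike_threshold_amplitude_half_width(self):
        # slow 1 mV/ms approach to -40, then symmetric fast flanks crossing
        # -15 mV (the half-amplitude level) 0.6 ms apart around a +10 peak
        rate = 50.0
        tr = piecewise_trace(
            [0, 200, 225, 225.6, 226.5, 230, 1200],
            [-65, -65, -40, 10, -65, -65, -65],
            rate,
            1200,
        )
        fam = make_family([(StimulusDescriptor(125.0, 200, 800), tr)], rate, 1200)
        thr, amp, hw = intr.ap_waveform_features(fam, rheobase_pa=75.0)
        assert thr == pytest.approx(-40.0, abs=0.5)
        assert amp == pytest.approx(50.0, abs=0.6)
        assert hw == pytest.approx(0.6, abs=0.02)

    def test_simulated_threshold_matches_dense_grid_brute_force(self, vip_params):
        # oracle: 500 kHz simulation, same smoothing in time units, direct
        # argmax of the third difference before the first spike peak
        fam50 = simulate_family(vip_params, firing_protocol(), 50.0, 0)
        rheo = intr.firing_output(fam50).rheobase_pa
        thr50, _, _ = intr.ap_waveform_features(fam50, rheo)

        stim = StimulusDescriptor(rheo + 50.0, 200, 800)
        sw = simulate_sweep(vip_params, stim, 500.0, 0, 1200.0)
        dt = 1.0 / 500.0
        v = sw.voltage_mv
        win = int(round(0.1 * 500.0))
        kernel = np.ones(win) / win
        vs = np.convolve(np.pad(v, win // 2, mode="edge"), kernel, mode="same")[
            win // 2 : win // 2 + len(v)
        ]
        d3 = vs.copy()
        for _ in range(3):
            d3 = np.gradient(d3, dt)
        peak_idx = int(round(sw.spike_times_ms[0] / dt))
        lo = peak_idx - int(round(2.0 * 500.0))
        thr_oracle = vs[lo + int(np.argmax(d3[lo:peak_idx]))]
        assert abs(thr50 - thr_oracle) < 1.0

    def test_missing_sweep_rejected(self):
        fam = counted_firing_family([3], [100])
        with pytest.raises(ValueError, match="no sweep at rheobase"):
            intr.ap_waveform_features(fam, rheobase_pa=75.0)

    def test_spikeless_sweep_rejected(self):
        fam = counted_firing_family([0], [125])
        with pytest.raises(ValueError, match="no spike"):
            intr.ap_waveform_features(fam, rheobase_pa=75.0)


class TestCvIsi:
    def test_periodic_train_zero(self):
        train = intr.SpikeTrain(np.arange(10) * 50.0, np.full(10, 15.0))
        assert intr.cv_isi(train) == 0.0

    def test_known_isis(self):
        # ISIs {10, 20, 30}: population sd sqrt(200/3) = 8.1650, mean 20
        times = np.cumsum([0.0, 10.0, 20.0, 30.0])
        assert intr.cv_isi(times) == pytest.approx(0.40825, abs=1e-5)

    def test_three_spikes_rejected(self):
        with pytest.raises(intr.InsufficientSpikesError):
            intr.cv_isi(np.array([0.0, 10.0, 20.0]))

    @given(
        isis=st.lists(st.floats(1.0, 1000.0), min_size=3, max_size=20),
        scale=st.floats(0.01, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, isis, scale):
        times = np.cumsum([0.0] + isis)
        assert intr.cv_isi(times * scale) == pytest.approx(
            intr.cv_isi(times), rel=1e-9, abs=1e-12
        )


def sag_trace(peak_defl, ss_defl, rate=10.0, baseline=-65.0):
    return piecewise_trace(
        [0, 200, 230, 260, 800, 1000, 1001, 1500],
        [
            baseline,
            baseline,
            baseline - peak_defl,
            baseline - ss_defl,
            baseline - ss_defl,
            baseline - ss_defl,
            baseline,
            baseline,
        ],
        rate,
        1500,
    )


class TestSagAndRebound:
    def test_constructed_sag_ratio(self):
        stim = StimulusDescriptor(-150.0, 200, 800)
        fam = make_family([(stim, sag_trace(20.0, 15.0))], 10.0, 1500)
        assert intr.sag_ratio(fam).summary == pytest.approx(20.0 / 15.0, abs=1e-3)

    def test_passive_cell_sag_ratio_is_one(self, passive_params):
        fam = simulate_family(passive_params, sag_protocol(), 50.0, 0)
        res = intr.sag_ratio(fam)
        for _, ratio in res.per_sweep:
            assert ratio == pytest.approx(1.0, abs=0.02)

    def test_h_current_raises_sag_ratio(self, vip_params, passive_params):
        stim = [StimulusDescriptor(-150.0, 200, 800)]
        on = simulate_family(vip_params, stim, 50.0, 0)
        off = simulate_family(passive_params, stim, 50.0, 0)
        assert intr.sag_ratio(on).summary > intr.sag_ratio(off).summary

    def test_sag_ratio_at_least_one_for_simulated_sweeps(self, wt_families):
        *_, sag_fam = wt_families
        for _, ratio in intr.sag_ratio(sag_fam).per_sweep:
            assert ratio >= 1.0

    def test_depolarizing_response_rejected(self):
        stim = StimulusDescriptor(-150.0, 200, 800)
        tr = piecewise_trace([0, 200, 210, 1000, 1010, 1500], [-65, -65, -55, -55, -65, -65], 10.0, 1500)
        fam = make_family([(stim, tr)], 10.0, 1500)
        with pytest.raises(ValueError, match="non-hyperpolarizing"):
            intr.sag_ratio(fam)

    def test_passive_cell_rebound_slope_zero(self, passive_params):
        fam = simulate_family(passive_params, sag_protocol(), 50.0, 0)
        assert abs(intr.rebound_slope(fam)) < 0.02

    def test_constructed_linear_rebound_slope(self):
        sweeps = []
        for v_ss, reb in [(-10.0, 2.5), (-20.0, 7.5), (-30.0, 12.5)]:
            tr = piecewise_trace(
                [0, 200, 201, 999, 1000, 1050, 1100, 1500],
                [0, 0, v_ss, v_ss, 0, reb, 0, 0],
                10.0,
                1500,
            )
            sweeps.append((StimulusDescriptor(v_ss * 5.0, 200, 800), tr))
        fam = make_family(sweeps, 10.0, 1500)
        assert intr.rebound_slope(fam) == pytest.approx(-0.5, abs=0.01)

    def test_simulated_slope_close_to_dense_protocol_fit(self, vip_params):
        coarse = simulate_family(vip_params, sag_protocol(), 50.0, 0)
        dense_protocol = [
            StimulusDescriptor(float(a), 200.0, 800.0)
            for a in range(-50, -251, -10)
        ]
        dense = simulate_family(vip_params, dense_protocol, 50.0, 0)
        s_coarse = intr.rebound_slope(coarse)
        s_dense = intr.rebound_slope(dense)
        assert s_coarse == pytest.approx(s_dense, rel=0.05)

    def test_single_sweep_rejected_for_slope(self):
        stim = StimulusDescriptor(-150.0, 200, 800)
        fam = make_family([(stim, sag_trace(20.0, 15.0))], 10.0, 1500)
        with pytest.raises(ValueError, match=">= 2"):
            intr.rebound_slope(fam)


class TestExtractFeatures:
    def test_full_vector_from_simulated_cell(self, wt_families):
        fs = intr.extract_features(list(wt_families))
        assert fs.rmp_mv is not None and -70 < fs.rmp_mv < -55
        assert fs.rin_mohm is not None and fs.rin_mohm > 0
        assert fs.rheobase_pa == 75.0
        assert fs.ap_half_width_ms is not None and fs.ap_half_width_ms > 0
        assert fs.cv_isi is not None and fs.cv_isi >= 0
        assert fs.sag_ratio is not None and fs.sag_ratio >= 1.0
        assert fs.rebound_slope is not None
        assert len(fs.firing_curve) == 13

    def test_spike_counts_monotone_in_current(self, wt_families):
        fs = intr.extract_features(list(wt_families))
        counts = [c for _, c in fs.firing_curve]
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_extraction_is_deterministic(self, wt_families):
        a = intr.extract_features(list(wt_families)).to_dict()
        b = intr.extract_features(list(wt_families)).to_dict()
        assert a == b

    def test_rin_recovery_grid(self):
        # passive cells spanning 100-500 MOhm with recording noise
        errors = []
        for k, g_leak in enumerate(np.linspace(2.0, 10.0, 10)):
            p = NeuronModelParams(
                leak_conductance=g_leak, noise_sd=0.2
            ).passive()
            fam = simulate_family(p, rin_protocol(), 50.0, 100 + k)
            rin = intr.measure_rin(fam)
            errors.append(abs(rin - 1000.0 / g_leak) / (1000.0 / g_leak))
        assert np.median(errors) < 0.02
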