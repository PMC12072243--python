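"""Feature extraction on constructed traces plus simulator properties."""

import numpy as np
import pytest
from scipy import stats as sstats

from habephys import StepProtocol, VoltageTrace, simulate_cell
from habephys import phenotypes
from habephys.features import (FeatureUndefined, SpikeTrain,
                               amplitude_adaptation_index,
                               classify_spontaneous,
                               count_rebound_oscillations, detect_spikes,
                               extract_features, frequency_adaptation_index,
                               lowpass_10Hz, max_spikes,
                               measure_rdp_duration, passive_properties,
                               sag_ratio)

from conftest import synthetic_trace

FS = 20_000.0
PROTO = StepProtocol(t_total=7.0)  # -100 pA, 0.5..1.5 s


def flat(level_mV, seconds, fs=FS):
    return np.full(int(seconds * fs), float(level_mV))


def add_spike(v, t_s, peak_mV, width_ms=1.0, fs=FS):
    i = int(t_s * fs)
    n = int(width_ms / 1000.0 * fs)
    half = np.linspace(v[i], peak_mV, n // 2)
    v[i:i + n // 2] = half
    v[i + n // 2:i + n] = half[::-1][: n - n // 2]
    return v


class TestSpikeTrain:
    def test_strictly_increasing_enforced(self):
        with pytest.raises(ValueError):
            SpikeTrain([0.2, 0.1], [60.0, 60.0])

    def test_refractory_floor_enforced(self):
        with pytest.raises(ValueError):
            SpikeTrain([0.1, 0.1005], [60.0, 60.0])


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        assert len(detect_spikes(synthetic_trace(flat(-60, 2.0)))) == 0

    def test_constructed_train_counted_at_peaks(self):
        v = flat(-60, 2.0)
        times = [0.2 + 0.25 * k for k in range(7)]
        for t in times:
            add_spike(v, t, 10.0)
        st = detect_spikes(synthetic_trace(v))
        assert len(st) == 7
        # peak sits at the top of the 0.5 ms rising ramp
        assert np.allclose(st.spike_times, np.array(times) + 9 / FS,
                           atol=2.5 / FS)
        assert np.allclose(st.peak_amplitudes, 70.0, atol=0.5)

    def test_amplitudes_referenced_to_minus_60(self):
        v = flat(-60, 1.0)
        add_spike(v, 0.5, 0.0)
        st = detect_spikes(synthetic_trace(v))
        assert st.peak_amplitudes[0] == pytest.approx(60.0, abs=0.5)


class TestLowpass:
    def test_dc_gain_unity(self):
        tr = synthetic_trace(flat(-55, 2.0))
        assert np.allclose(lowpass_10Hz(tr).v_mV, -55.0, atol=1e-9)

    def test_frequency_response(self):
        t = np.arange(int(5 * FS)) / FS
        slow = synthetic_trace(np.sin(2 * np.pi * 1.0 * t))
        fast = synthetic_trace(np.sin(2 * np.pi * 100.0 * t))
        mid = slice(int(1 * FS), int(4 * FS))
        assert lowpass_10Hz(slow).v_mV[mid].max() > 0.95
        assert np.abs(lowpass_10Hz(fast).v_mV[mid]).max() < 0.05

    def test_plateau_preserved_spikes_removed(self, long_trace,
                                              hyper_protocol_10s):
        # compare the filtered spiking trace against the TTX condition
        # (same cell, no spikes)
        p = phenotypes.long_rdp()
        ttx = simulate_cell(p, hyper_protocol_10s, "ttx")
        filt = lowpass_10Hz(long_trace).v_mV
        fs = long_trace.fs
        window = slice(int(2.5 * fs), int(6.0 * fs))  # mid-plateau
        # spikes (which cross -20 mV) are removed entirely
        assert filt[window].max() < -20.0
        # the plateau itself survives filtering: both the filtered
        # spiking trace and the spike-free TTX trace sit well above the
        # -60 mV baseline and track each other (the residual offset is
        # the spikes' average depolarizing area, < 10 mV)
        assert filt[window].min() > -50.0
        assert ttx.v_mV[window].min() > -55.0
        assert np.abs(filt[window] - ttx.v_mV[window]).max() < 10.0


class TestRdpDuration:
    def test_quiet_trace_zero(self):
        m = measure_rdp_duration(synthetic_trace(flat(-60, 7.0)), PROTO)
        assert m.duration_ms == 0.0 and not m.censored

    def test_constructed_trapezoid_500ms(self):
        v = flat(-60, 7.0)
        fs = FS
        t0 = PROTO.t_off + 0.1
        t1 = PROTO.t_off + 0.6
        ramp = int(0.01 * fs)
        i0, i1 = int(t0 * fs), int(t1 * fs)
        v[i0 - ramp:i0] = np.linspace(-60, -45, ramp)
        v[i0:i1] = -45.0
        v[i1:i1 + ramp] = np.linspace(-45, -60, ramp)
        m = measure_rdp_duration(synthetic_trace(v), PROTO)
        assert m.duration_ms == pytest.approx(500.0, rel=0.05)
        assert not m.censored

    def test_censored_when_trace_ends_high(self):
        v = flat(-60, 7.0)
        i0 = int((PROTO.t_off + 0.5) * FS)
        v[i0:] = -40.0
        v[i0 - int(0.01 * FS):i0] = np.linspace(-60, -40, int(0.01 * FS))
        m = measure_rdp_duration(synthetic_trace(v), PROTO)
        assert m.censored

    def test_depolarizing_step_rejected(self):
        with pytest.raises(ValueError):
            measure_rdp_duration(synthetic_trace(flat(-60, 7.0)),
                                 StepProtocol(amp_pA=100.0, t_total=7.0))

    def test_short_vs_long_phenotypes(self, short_trace, long_trace,
                                      hyper_protocol, hyper_protocol_10s):
        assert measure_rdp_duration(short_trace,
                                    hyper_protocol).duration_ms < 400.0
        assert measure_rdp_duration(long_trace,
                                    hyper_protocol_10s).duration_ms > 400.0


class TestAdaptationIndices:
    def test_regular_train_fai_zero(self):
        times = PROTO.t_on + np.arange(0.05, 1.0, 0.1)
        st = SpikeTrain(times, np.full(times.size, 60.0))
        fai, f_init, f_final = frequency_adaptation_index(st, PROTO)
        assert f_init == pytest.approx(10.0)
        assert f_final == pytest.approx(10.0)
        assert fai == pytest.approx(0.0)

    def test_early_only_train_fai_one(self):
        times = PROTO.t_on + np.array([0.05, 0.1, 0.15, 0.2, 0.25])
        st = SpikeTrain(times, np.full(5, 60.0))
        fai, _, f_final = frequency_adaptation_index(st, PROTO)
        assert f_final == 0.0 and fai == 1.0

    def test_hand_computed_example(self):
        rel = np.array([0.01, 0.03, 0.07, 0.15, 0.31, 0.63, 0.95])
        st = SpikeTrain(PROTO.t_on + rel, np.full(rel.size, 60.0))
        fai, f_init, f_final = frequency_adaptation_index(st, PROTO)
        assert f_init == pytest.approx(50.0)
        assert f_final == pytest.approx(5.0)
        assert fai == pytest.approx(0.9)

    def test_fai_invariant_to_time_translation(self):
        rel = np.array([0.02, 0.08, 0.2, 0.5, 0.9])
        st = SpikeTrain(PROTO.t_on + rel, np.full(5, 60.0))
        shifted_proto = StepProtocol(t_on=1.0, t_off=2.0, t_total=7.0)
        st2 = SpikeTrain(shifted_proto.t_on + rel, np.full(5, 60.0))
        assert frequency_adaptation_index(st, PROTO)[0] == pytest.approx(
            frequency_adaptation_index(st2, shifted_proto)[0])

    def test_too_few_spikes_flagged(self):
        st = SpikeTrain([PROTO.t_on + 0.1], [60.0])
        with pytest.raises(FeatureUndefined):
            frequency_adaptation_index(st, PROTO)

    def test_aai_ratio(self):
        st = SpikeTrain(PROTO.t_on + np.array([0.1, 0.2]), [60.0, 30.0])
        assert amplitude_adaptation_index(st, PROTO) == pytest.approx(0.5)
        st2 = SpikeTrain(PROTO.t_on + np.array([0.1, 0.2]), [60.0, 60.0])
        assert amplitude_adaptation_index(st2, PROTO) == pytest.approx(1.0)


class TestFiringPhenotypes:
    def test_hf_low_fai_lf_high_fai(self, hf_depol_trace, lf_depol_trace,
                                    depol_protocol):
        fai_hf, _, _ = frequency_adaptation_index(
            detect_spikes(hf_depol_trace), depol_protocol)
        fai_lf, _, _ = frequency_adaptation_index(
            detect_spikes(lf_depol_trace), depol_protocol)
        assert fai_hf <= 0.8
        assert fai_lf > 0.8

    def test_lf_amplitude_adaptation_below_one(self, lf_depol_trace,
                                               depol_protocol):
        aai = amplitude_adaptation_index(detect_spikes(lf_depol_trace),
                                         depol_protocol)
        assert 0.0 < aai < 1.0


class TestMaxSpikes:
    def test_all_silent(self):
        traces = {a: synthetic_trace(flat(-60, 2.5))
                  for a in (20, 40, 60, 80, 100)}
        proto = StepProtocol(amp_pA=20.0, t_total=2.5)
        assert max_spikes(traces, proto) == 0

    def test_missing_step_listed(self):
        traces = {a: synthetic_trace(flat(-60, 2.5)) for a in (20, 40)}
        proto = StepProtocol(amp_pA=20.0, t_total=2.5)
        with pytest.raises(ValueError, match="60"):
            max_spikes(traces, proto)

    def test_constructed_counts(self):
        proto = StepProtocol(amp_pA=20.0, t_total=2.5)
        counts = {20: 2, 40: 5, 60: 9, 80: 7, 100: 4}
        traces = {}
        for amp, n in counts.items():
            v = flat(-60, 2.5)
            for k in range(n):
                add_spike(v, proto.t_on + 0.05 + 0.09 * k, 10.0)
            traces[amp] = synthetic_trace(v)
        assert max_spikes(traces, proto) == 9


class TestSagRatio:
    def test_constructed_quarter(self):
        v = flat(-60, 7.0)
        fs = FS
        i_on, i_off = int(PROTO.t_on * fs), int(PROTO.t_off * fs)
        v[i_on:i_off] = -90.0                       # steady -30 mV
        v[i_on:i_on + int(0.1 * fs)] = -100.0       # peak -40 mV
        assert sag_ratio(synthetic_trace(v), PROTO) == pytest.approx(
            0.25, abs=1e-3)

    def test_no_sag_zero(self):
        v = flat(-60, 7.0)
        v[int(PROTO.t_on * FS):int(PROTO.t_off * FS)] = -90.0
        assert sag_ratio(synthetic_trace(v), PROTO) == 0.0

    def test_offset_invariance(self):
        v = flat(-60, 7.0)
        fs = FS
        i_on, i_off = int(PROTO.t_on * fs), int(PROTO.t_off * fs)
        v[i_on:i_off] = -90.0
        v[i_on:i_on + int(0.1 * fs)] = -100.0
        a = sag_ratio(synthetic_trace(v), PROTO)
        b = sag_ratio(synthetic_trace(v + 7.3), PROTO)
        assert a == pytest.approx(b)

    def test_simulated_sag_requires_g_h(self, hyper_protocol):
        with_h = simulate_cell(phenotypes.short_rdp(), hyper_protocol)
        without = simulate_cell(phenotypes.short_rdp(g_H=0.0),
                                hyper_protocol)
        assert sag_ratio(with_h, hyper_protocol) > sag_ratio(
            without, hyper_protocol)
        assert sag_ratio(without, hyper_protocol) < 0.02


class TestPassiveProperties:
    def test_leak_only_500_mohm(self):
        from habephys.model import ModelParams

        p = ModelParams(g_Na=0, g_K=0, g_T=0, g_SK=0, g_H=0, g_adapt=0,
                        g_T_glia=0, g_CNG=0, g_gap=0)
        proto = StepProtocol(hold_mV=None, amp_pA=-10.0, t_total=4.0)
        tr = simulate_cell(p, proto)
        rmp, r_in = passive_properties(tr, proto)
        assert rmp == pytest.approx(p.E_leak_n, abs=0.01)
        assert r_in == pytest.approx(500.0, rel=0.01)

    def test_zero_step_rejected(self):
        proto = StepProtocol(hold_mV=None, amp_pA=0.0, t_total=4.0)
        with pytest.raises(FeatureUndefined):
            passive_properties(synthetic_trace(flat(-60, 4.0)), proto)

    def test_glial_resistance_much_lower(self, coupled_pair):
        # glial leak 18 nS vs neuronal 2 nS: input resistance far lower
        from habephys import phenotypes as ph

        p = ph.long_rdp()
        assert 1000.0 / p.g_leak_g < 0.2 * (1000.0 / p.g_leak_n)


class TestSpontaneous:
    def test_low_rate_is_silent(self):
        v = flat(-60, 20.0)
        for t in (3.0, 9.0, 15.0):  # 0.15 Hz
            add_spike(v, t, 10.0)
        cls, rate, _ = classify_spontaneous(synthetic_trace(v))
        assert cls == "silent" and rate == pytest.approx(0.15)

    def test_regular_firing_is_tonic(self):
        v = flat(-60, 20.0)
        for t in np.arange(0.1, 20.0, 0.2):  # 5 Hz regular
            add_spike(v, t, 10.0)
        cls, rate, _ = classify_spontaneous(synthetic_trace(v))
        assert cls == "tonic" and rate == pytest.approx(5.0, rel=0.02)

    def test_clustered_spikes_on_wave_is_burst(self):
        fs = FS
        v = flat(-60, 20.0)
        for start in (2.0, 8.0, 14.0):
            i0, i1 = int(start * fs), int((start + 1.0) * fs)
            v[i0:i1] = -48.0  # slow wave 12 mV above baseline
            for k in range(5):
                add_spike(v, start + 0.1 + 0.15 * k, 10.0)
        cls, _, _ = classify_spontaneous(synthetic_trace(v))
        assert cls == "burst"

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            classify_spontaneous(synthetic_trace(flat(-60, 5.0)))

    @pytest.mark.parametrize("spont", ["silent", "tonic", "burst"])
    def test_simulated_spontaneous_classes(self, spont):
        proto = StepProtocol(hold_mV=None, amp_pA=0.0, t_on=0.1, t_off=0.2,
                             t_total=21.0)
        p = phenotypes.cell_params("short_rdp", "hf", spont)
        tr = simulate_cell(p, proto, seed=0)
        cls, _, _ = classify_spontaneous(tr)
        assert cls == spont


class TestOscillations:
    def test_no_excursions_zero(self):
        proto = StepProtocol(t_total=21.5)
        assert count_rebound_oscillations(
            synthetic_trace(flat(-60, 21.5)), proto) == 0

    def test_constructed_hump_train(self):
        proto = StepProtocol(t_total=21.5)
        fs = FS
        v = flat(-60, 21.5)
        for k in range(12):
            start = proto.t_off + 0.5 + 1.5 * k
            i0, i1 = int(start * fs), int((start + 0.5) * fs)
            v[i0:i1] = -45.0
        assert count_rebound_oscillations(synthetic_trace(v), proto) == 12

    def test_insufficient_window_rejected(self):
        with pytest.raises(ValueError):
            count_rebound_oscillations(synthetic_trace(flat(-60, 7.0)),
                                       PROTO)


class TestExtractFeatures:
    def test_assembled_vector(self, short_trace, hyper_protocol,
                              hf_depol_trace, depol_protocol):
        traces = {a: hf_depol_trace for a in (20, 40, 60, 80, 100)}
        cf = extract_features(short_trace, hyper_protocol, traces,
                              depol_protocol)
        assert 0.0 < cf.rdp_ms < 400.0
        assert cf.max_spikes > 0
        assert np.isfinite(cf.fai) and cf.fai <= 0.8
        assert cf.flags == {}

    def test_deterministic(self, short_trace, hyper_protocol):
        a = extract_features(short_trace, hyper_protocol)
        b = extract_features(short_trace, hyper_protocol)
        assert a == b


class TestDurationCorrelation:
    def test_spont_depol_vs_rdp_positive_r(self, hyper_protocol_10s):
        """Cohorts mixing short/long phenotypes: spontaneous
        depolarization duration correlates with RDP duration."""
        psp = StepProtocol(hold_mV=None, amp_pA=0.0, t_on=0.1, t_off=0.2,
                           t_total=21.0)
        rdps, deps = [], []
        for kind in ("short_rdp", "long_rdp"):
            for fk in ("hf", "lf"):
                for seed in range(3):
                    p = phenotypes.cell_params(kind, fk)
                    pb = phenotypes.cell_params(kind, fk, "burst")
                    d = measure_rdp_duration(
                        simulate_cell(p, hyper_protocol_10s),
                        hyper_protocol_10s).duration_ms
                    _, _, dep = classify_spontaneous(
                        simulate_cell(pb, psp, seed=seed))
                    rdps.append(d)
                    deps.append(dep)
        r = sstats.pearsonr(rdps, deps).statistic
        assert r > 0.5
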