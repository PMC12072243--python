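"""Per-cell feature extraction from current-clamp voltage traces.

Implements the measurements used to characterize lateral habenula
neurons: rebound depolarizing potential (RDP) duration from the 10 Hz
low-pass filtered trace via +10 mV threshold crossings, frequency and
amplitude adaptation indices, maximum evoked spike count, sag ratio,
passive properties, and spontaneous-activity classification.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .model import StepProtocol, VoltageTrace


class FeatureUndefined(ValueError):
    """A feature's preconditions are not met (e.g. too few spikes)."""


@dataclass
class SpikeTrain:
    """Detected action potentials: times (s) and peak amplitudes (mV)
    measured from the -60 mV holding level."""

    spike_times: np.ndarray
    peak_amplitudes: np.ndarray

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        self.peak_amplitudes = np.asarray(self.peak_amplitudes, dtype=float)
        if self.spike_times.size != self.peak_amplitudes.size:
            raise ValueError("times and amplitudes must match")
        if self.spike_times.size > 1:
            dts = np.diff(self.spike_times)
            if not (dts > 0).all():
                raise ValueError("spike times must be strictly increasing")
            if (dts < 1e-3).any():
                raise ValueError("spike train violates 1 ms refractory floor")
        if not np.isfinite(self.peak_amplitudes).all():
            raise ValueError("amplitudes must be finite")

    def __len__(self) -> int:
        return int(self.spike_times.size)


@dataclass
class RdpMeasurement:
    duration_ms: float
    censored: bool
    peak_mV: float


@dataclass
class CellFeatures:
    """The per-neuron feature vector."""

    rmp_mV: float = np.nan
    r_in_MOhm: float = np.nan
    sag_ratio: float = np.nan
    max_spikes: int = -1
    fai: float = np.nan
    f_initial_Hz: float = np.nan
    f_final_Hz: float = np.nan
    aai: float = np.nan
    rdp_ms: float = np.nan
    rdp_censored: bool = False
    n_oscillations: int = -1
    spont_class: str = ""
    spont_rate_Hz: float = np.nan
    spont_depol_ms: float = np.nan
    flags: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def lowpass_10Hz(trace: VoltageTrace, cutoff_Hz: float = 10.0,
                 order: int = 4) -> VoltageTrace:
    """Zero-phase Bessel low-pass used to remove spikes before duration
    measurements.  DC gain is 1; forward-backward application preserves
    the crossing times that define durations."""
    if trace.fs <= 2.0 * cutoff_Hz:
        raise ValueError("sampling rate too low for the requested cutoff")
    b, a = signal.bessel(order, cutoff_Hz, btype="low", fs=trace.fs,
                         norm="mag")
    padlen = 3 * (max(len(a), len(b)) - 1)
    if trace.v_mV.size <= padlen:
        raise ValueError("trace shorter than filter warm-up")
    v = signal.filtfilt(b, a, trace.v_mV)
    return VoltageTrace(fs=trace.fs, v_mV=v, i_pA=trace.i_pA,
                        meta={**trace.meta, "filtered": f"bessel{order}@{cutoff_Hz}Hz"})


# ---------------------------------------------------------------------------
# spikes
# ---------------------------------------------------------------------------

def detect_spikes(trace: VoltageTrace, threshold_mV: float = -20.0,
                  refractory_ms: float = 2.0,
                  reference_mV: float = -60.0) -> SpikeTrain:
    """One event per suprathreshold excursion.

    An event begins at an upward crossing of ``threshold_mV``; its time
    and amplitude are taken at the excursion's voltage peak, amplitudes
    measured from ``reference_mV`` (the -60 mV holding level by
    default).  Events closer than ``refractory_ms`` to the previous
    event's crossing are merged.
    """
    v = trace.v_mV
    above = v >= threshold_mV
    ups = np.flatnonzero(~above[:-1] & above[1:]) + 1
    times, amps = [], []
    refr = refractory_ms / 1000.0
    last_t = -np.inf
    for k, i0 in enumerate(ups):
        t_cross = i0 / trace.fs
        if t_cross - last_t < refr:
            continue
        last_t = t_cross
        i1 = ups[k + 1] if k + 1 < len(ups) else v.size
        # end of this excursion (first sample back below threshold)
        below = np.flatnonzero(~above[i0:i1])
        i_end = i0 + (below[0] if below.size else i1 - i0)
        seg = v[i0:max(i_end, i0 + 1)]
        i_peak = i0 + int(np.argmax(seg))
        times.append(i_peak / trace.fs)
        amps.append(v[i_peak] - reference_mV)
    return SpikeTrain(np.array(times), np.array(amps))


def count_spikes_oracle(trace: VoltageTrace, threshold_mV: float = -20.0,
                        min_separation_ms: float = 2.0) -> int:
    """Independent spike counter: local-maxima scan above threshold."""
    peaks, _ = signal.find_peaks(
        trace.v_mV, height=threshold_mV,
        distance=max(1, int(round(min_separation_ms * trace.fs / 1000.0))))
    return int(peaks.size)


# ---------------------------------------------------------------------------
# RDP duration
# ---------------------------------------------------------------------------

def _baseline(filtered_v: np.ndarray, fs: float, t_on: float,
              window_s: float = 0.5) -> float:
    i_on = int(round(t_on * fs))
    i0 = max(0, i_on - int(round(window_s * fs)))
    if i_on <= i0:
        raise ValueError("no pre-stimulus window for baseline")
    return float(np.mean(filtered_v[i0:i_on]))


def measure_rdp_duration(trace: VoltageTrace, protocol: StepProtocol,
                         threshold_up_mV: float = 10.0,
                         prefiltered: bool = False) -> RdpMeasurement:
    """RDP duration from threshold crossings of the filtered trace.

    The baseline is the mean filtered voltage over the 500 ms before the
    step onset; the duration runs from the first upward crossing of
    baseline + 10 mV after the step offset to the next downward
    crossing.  Returns 0 if the threshold is never crossed, and a
    censored duration (to trace end) if the trace ends above threshold.
    """
    if protocol.amp_pA >= 0:
        raise ValueError("RDP measurement requires a hyperpolarizing step")
    filt = trace if prefiltered else lowpass_10Hz(trace)
    v = filt.v_mV
    fs = trace.fs
    base = _baseline(v, fs, protocol.t_on)
    thr = base + threshold_up_mV
    i_off = int(round(protocol.t_off * fs))
    seg = v[i_off:]
    above = seg >= thr
    if above[0]:
        i_up = 0  # already above threshold at the offset sample
    else:
        ups = np.flatnonzero(~above[:-1] & above[1:]) + 1
        if ups.size == 0:
            return RdpMeasurement(0.0, False, float(seg.max() - base))
        i_up = int(ups[0])
    downs = np.flatnonzero(above[i_up:-1] & ~above[i_up + 1:]) + 1
    peak = float(seg[i_up:].max() - base)
    if downs.size == 0:
        dur = (seg.size - 1 - i_up) / fs * 1000.0
        return RdpMeasurement(dur, True, peak)
    i_down = i_up + int(downs[0])
    return RdpMeasurement((i_down - i_up) / fs * 1000.0, False, peak)


def rdp_duration_oracle(trace: VoltageTrace, protocol: StepProtocol,
                        threshold_up_mV: float = 10.0) -> float:
    """Brute-force sample-by-sample crossing scan (independent check)."""
    v = lowpass_10Hz(trace).v_mV
    fs = trace.fs
    base = _baseline(v, fs, protocol.t_on)
    thr = base + threshold_up_mV
    i_off = int(round(protocol.t_off * fs))
    i = i_off
    n = v.size
    while i < n and v[i] < thr:
        i += 1
    if i == n:
        return 0.0
    j = i
    while j < n and v[j] >= thr:
        j += 1
    if j == n:
        return (n - 1 - i) / fs * 1000.0
    return (j - i) / fs * 1000.0


def count_rebound_oscillations(trace: VoltageTrace, protocol: StepProtocol,
                               window_s: float = 20.0,
                               threshold_up_mV: float = 10.0) -> int:
    """Number of distinct filtered-trace excursions above baseline+10 mV
    within ``window_s`` after the step offset."""
    if trace.duration_s < protocol.t_off + window_s - 1e-9:
        raise ValueError("insufficient post-offset window")
    v = lowpass_10Hz(trace).v_mV
    fs = trace.fs
    base = _baseline(v, fs, protocol.t_on)
    thr = base + threshold_up_mV
    i0 = int(round(protocol.t_off * fs))
    i1 = min(v.size, int(round((protocol.t_off + window_s) * fs)))
    above = v[i0:i1] >= thr
    ups = int(above[0]) + int(np.sum(~above[:-1] & above[1:]))
    return ups


# ---------------------------------------------------------------------------
# depolarization-evoked firing
# ---------------------------------------------------------------------------

def frequency_adaptation_index(spikes: SpikeTrain, protocol: StepProtocol):
    """(f_initial - f_final) / f_initial for the +100 pA step.

    ``f_initial`` is the inverse of the first interspike interval;
    ``f_final`` is the firing frequency over the 200 ms immediately
    before the step offset (count / 0.2 s).
    """
    t = spikes.spike_times
    in_step = t[(t >= protocol.t_on) & (t < protocol.t_off)]
    if in_step.size < 2:
        raise FeatureUndefined("frequency adaptation needs >= 2 spikes")
    f_init = 1.0 / (in_step[1] - in_step[0])
    n_final = int(np.sum((in_step >= protocol.t_off - 0.2)
                         & (in_step < protocol.t_off)))
    f_final = n_final / 0.2
    return (f_init - f_final) / f_init, f_init, f_final


def amplitude_adaptation_index(spikes: SpikeTrain,
                               protocol: Optional[StepProtocol] = None) -> float:
    """Second spike amplitude divided by the first (amplitudes from -60 mV)."""
    t = spikes.spike_times
    a = spikes.peak_amplitudes
    if protocol is not None:
        keep = (t >= protocol.t_on) & (t < protocol.t_off)
        t, a = t[keep], a[keep]
    if t.size < 2:
        raise FeatureUndefined("amplitude adaptation needs >= 2 spikes")
    if a[0] <= 0:
        raise FeatureUndefined("first spike amplitude is non-positive")
    return float(a[1] / a[0])


def max_spikes(traces_by_amp: dict, protocol: StepProtocol,
               threshold_mV: float = -20.0) -> int:
    """Maximum spike count over the 1 s depolarizing steps 20..100 pA."""
    required = [20, 40, 60, 80, 100]
    missing = [a for a in required if a not in traces_by_amp]
    if missing:
        raise ValueError(f"missing step amplitudes: {missing}")
    best = 0
    for amp in required:
        st = detect_spikes(traces_by_amp[amp], threshold_mV=threshold_mV)
        t = st.spike_times
        n = int(np.sum((t >= protocol.t_on) & (t < protocol.t_off)))
        best = max(best, n)
    return best


# ---------------------------------------------------------------------------
# subthreshold properties
# ---------------------------------------------------------------------------

def sag_ratio(trace: VoltageTrace, protocol: StepProtocol,
              steady_window_s: float = 0.1) -> float:
    """(V_peak - V_steady) / V_peak on the hyperpolarizing deflection.

    V_peak is the maximal deflection magnitude during the step; V_steady
    is the mean deflection over the last 100 ms of the step.
    """
    if protocol.amp_pA >= 0:
        raise ValueError("sag ratio requires a hyperpolarizing step")
    v = trace.v_mV
    fs = trace.fs
    base = _baseline(v, fs, protocol.t_on)
    i_on = int(round(protocol.t_on * fs))
    i_off = int(round(protocol.t_off * fs))
    seg = v[i_on:i_off]
    v_peak = float(base - seg.min())
    i_st = i_off - int(round(steady_window_s * fs))
    v_steady = float(base - np.mean(v[i_st:i_off]))
    if v_peak <= v_steady or v_peak <= 0:
        return 0.0
    return (v_peak - v_steady) / v_peak


def passive_properties(trace: VoltageTrace, protocol: StepProtocol,
                       spike_threshold_mV: float = -20.0):
    """Resting membrane potential (mV) and input resistance (MOhm).

    RMP is the mean pre-stimulus voltage; R_in is the steady-state
    deflection over the last 100 ms of a small step divided by the step
    current.
    """
    if protocol.amp_pA == 0:
        raise FeatureUndefined("input resistance needs a non-zero step")
    v = trace.v_mV
    fs = trace.fs
    i_on = int(round(protocol.t_on * fs))
    i_off = int(round(protocol.t_off * fs))
    if (v[: i_off] >= spike_threshold_mV).any():
        raise ValueError("spikes during the passive measurement window")
    rmp = float(np.mean(v[max(0, i_on - int(0.5 * fs)):i_on]))
    steady = float(np.mean(v[i_off - int(0.1 * fs):i_off]))
    r_in = (steady - rmp) / protocol.amp_pA * 1000.0  # mV/pA -> MOhm
    return rmp, r_in


# ---------------------------------------------------------------------------
# spontaneous activity
# ---------------------------------------------------------------------------

def classify_spontaneous(trace: VoltageTrace, rate_silent_Hz: float = 0.2,
                         burst_gap_s: float = 0.3,
                         burst_span_s: float = 3.0,
                         burst_min_spikes: int = 3,
                         burst_depol_mV: float = 5.0,
                         window_s: float = 20.0):
    """Classify a >= 20 s unstimulated recording as silent/tonic/burst.

    Rate < 0.2 Hz -> silent.  Otherwise the spike train is split into
    clusters at silent gaps >= 300 ms; a cluster counts as a burst when
    it has >= 3 spikes, spans under 3 s (a discrete event, not a
    continuous train) and rides a filtered depolarization >= 5 mV above
    baseline.  Any burst -> burst, otherwise tonic.  Also returns the
    overall rate (spikes / 20 s) and the mean duration of filtered
    depolarizations crossing baseline + 10 mV.
    """
    if trace.duration_s < window_s - 1e-9:
        raise ValueError(f"need >= {window_s} s of recording")
    n = int(round(window_s * trace.fs))
    sub = VoltageTrace(fs=trace.fs, v_mV=trace.v_mV[:n], i_pA=trace.i_pA[:n],
                       meta=trace.meta)
    spikes = detect_spikes(sub)
    rate = len(spikes) / window_s
    filt = lowpass_10Hz(sub).v_mV
    # 20th percentile rather than the median: in cells where plateau
    # events occupy much of the record the median sits on the events
    # themselves and would clip them
    base = float(np.percentile(filt, 20.0))

    spont_depol_ms = _mean_excursion_ms(filt, sub.fs, base + 10.0)

    if rate < rate_silent_Hz:
        return "silent", rate, spont_depol_ms
    # burst detection: discrete spike clusters on a depolarized wave
    t = spikes.spike_times
    idx = (t * sub.fs).astype(int)
    is_burst = False
    k = 0
    while k < len(t):
        j = k
        while j + 1 < len(t) and t[j + 1] - t[j] < burst_gap_s:
            j += 1
        if j - k + 1 >= burst_min_spikes and t[j] - t[k] < burst_span_s:
            wave = filt[idx[k]:idx[j] + 1]
            if wave.size and wave.max() >= base + burst_depol_mV:
                is_burst = True
                break
        k = j + 1
    return ("burst" if is_burst else "tonic"), rate, spont_depol_ms


def _mean_excursion_ms(filtered_v: np.ndarray, fs: float,
                       threshold: float) -> float:
    above = filtered_v >= threshold
    if not above.any():
        return 0.0
    edges = np.diff(above.astype(int))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(above.size)
    durs = [(e - s) / fs * 1000.0 for s, e in zip(starts, ends)]
    return float(np.mean(durs)) if durs else 0.0


# ---------------------------------------------------------------------------
# assembled extraction
# ---------------------------------------------------------------------------

def extract_features(hyper_trace: VoltageTrace, hyper_protocol: StepProtocol,
                     depol_traces: Optional[dict] = None,
                     depol_protocol: Optional[StepProtocol] = None,
                     spont_trace: Optional[VoltageTrace] = None) -> CellFeatures:
    """Compute the full feature vector from the standard protocol set.

    ``depol_traces`` maps step amplitude (pA) to traces; the +100 pA
    trace provides the adaptation indices.  Undefined features are
    recorded in ``flags`` rather than raising.
    """
    out = CellFeatures()
    m = measure_rdp_duration(hyper_trace, hyper_protocol)
    out.rdp_ms, out.rdp_censored = m.duration_ms, m.censored
    out.sag_ratio = sag_ratio(hyper_trace, hyper_protocol)
    if hyper_trace.duration_s >= hyper_protocol.t_off + 20.0:
        out.n_oscillations = count_rebound_oscillations(
            hyper_trace, hyper_protocol)
    if depol_traces is not None:
        proto = depol_protocol or hyper_protocol
        try:
            out.max_spikes = max_spikes(depol_traces, proto)
        except ValueError as e:
            out.flags["max_spikes"] = str(e)
        if 100 in depol_traces:
            spikes = detect_spikes(depol_traces[100])
            try:
                out.fai, out.f_initial_Hz, out.f_final_Hz = \
                    frequency_adaptation_index(spikes, proto)
            except FeatureUndefined as e:
                out.flags["fai"] = str(e)
            try:
                out.aai = amplitude_adaptation_index(spikes, proto)
            except FeatureUndefined as e:
                out.flags["aai"] = str(e)
    if spont_trace is not None:
        out.spont_class, out.spont_rate_Hz, out.spont_depol_ms = \
            classify_spontaneous(spont_trace)
    return out
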