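"""Intrinsic membrane and firing feature extraction from current-clamp sweeps.

Implements the per-cell feature vector of a whole-cell patch-clamp
characterization of VIP+ cortical interneurons:

* resting membrane potential (RMP): mean of the pre-stimulus baseline;
* input resistance (Rin): OLS slope of the steady-state voltage-current
  relation over the -50..+20 pA family, spiking sweeps excluded;
* firing curve, maximum firing frequency and rheobase from 800 ms
  depolarizing steps;
* single-AP threshold / amplitude / half-width from the sweep 50 pA above
  rheobase, with the threshold defined as the voltage at which the third
  derivative of voltage with time is maximal;
* coefficient of variation of inter-spike intervals (CV ISI);
* sag ratio and rebound slope from hyperpolarizing steps (HCN signature).

Deflection sign convention: sag and rebound deflections are positive
magnitudes relative to the pre-stimulus baseline.  All window parameters
(steady-state window = last 20% of the step, threshold search window = 2 ms
before the spike peak, rebound window = 200 ms after step offset, smoothing
window = 0.1 ms) are keyword arguments with those defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .synth.neuron import SPIKE_CUTOFF_MV, StimulusDescriptor, SweepFamily


class InsufficientSpikesError(ValueError):
    """Raised when a spike-train statistic needs more spikes than present."""


@dataclass(frozen=True)
class SpikeTrain:
    """Detected spikes in one sweep; threshold data filled by AP analysis."""

    peak_times_ms: np.ndarray
    peak_voltages_mv: np.ndarray
    threshold_times_ms: np.ndarray | None = None
    threshold_voltages_mv: np.ndarray | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.peak_times_ms) <= 0):
            raise ValueError("spike peak times must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return len(self.peak_times_ms)


@dataclass
class FiringOutput:
    firing_curve: list[tuple[float, int]]  # (current pA, spike count)
    max_firing_frequency_hz: float
    rheobase_pa: float | None


@dataclass
class IntrinsicFeatureSet:
    """The per-cell intrinsic feature vector; missing features are None."""

    rmp_mv: float | None = None
    rin_mohm: float | None = None
    rheobase_pa: float | None = None
    firing_curve: list[tuple[float, int]] = field(default_factory=list)
    max_firing_frequency_hz: float | None = None
    ap_threshold_mv: float | None = None
    ap_amplitude_mv: float | None = None
    ap_half_width_ms: float | None = None
    cv_isi: float | None = None
    sag_ratio: float | None = None
    rebound_slope: float | None = None

    def to_dict(self) -> dict:
        d = {
            "rmp_mv": self.rmp_mv,
            "rin_mohm": self.rin_mohm,
            "rheobase_pa": self.rheobase_pa,
            "max_firing_frequency_hz": self.max_firing_frequency_hz,
            "ap_threshold_mv": self.ap_threshold_mv,
            "ap_amplitude_mv": self.ap_amplitude_mv,
            "ap_half_width_ms": self.ap_half_width_ms,
            "cv_isi": self.cv_isi,
            "sag_ratio": self.sag_ratio,
            "rebound_slope": self.rebound_slope,
        }
        for amp, count in self.firing_curve:
            d[f"spikes_at_{amp:g}pA"] = count
        return d


FEATURE_COLUMNS = [
    "rmp_mv",
    "rin_mohm",
    "rheobase_pa",
    "max_firing_frequency_hz",
    "ap_threshold_mv",
    "ap_amplitude_mv",
    "ap_half_width_ms",
    "cv_isi",
    "sag_ratio",
    "rebound_slope",
]


def _baseline_mean(trace: np.ndarray, stim: StimulusDescriptor, rate_khz: float) -> float:
    n0 = int(round(stim.onset * rate_khz))
    if n0 < 1:
        raise ValueError("sweep has no pre-stimulus baseline")
    return float(np.mean(trace[:n0]))


def _steady_state_mean(
    trace: np.ndarray, stim: StimulusDescriptor, rate_khz: float, window_frac: float = 0.2
) -> float:
    i0 = int(round((stim.offset - window_frac * stim.duration) * rate_khz))
    i1 = int(round(stim.offset * rate_khz))
    return float(np.mean(trace[i0:i1]))


def measure_rmp(segment: np.ndarray, rate_khz: float, min_length_ms: float = 100.0) -> float:
    """Mean of a designated baseline voltage segment (>= 100 ms)."""
    segment = np.asarray(segment, dtype=np.float64)
    if len(segment) < min_length_ms * rate_khz:
        raise ValueError(
            f"baseline segment shorter than {min_length_ms} ms at {rate_khz} kHz"
        )
    return float(np.mean(segment))


def detect_spikes(
    sweep: np.ndarray,
    rate_khz: float,
    cutoff_mv: float = SPIKE_CUTOFF_MV,
    merge_window_ms: float = 1.0,
) -> SpikeTrain:
    """Detect spikes as upward crossings of the cutoff voltage.

    The spike peak is the local maximum before the next downward crossing;
    crossings closer than the merge window collapse into one spike.  Zero
    spikes is a valid result.
    """
    v = np.asarray(sweep, dtype=np.float64)
    above = v >= cutoff_mv
    up = np.flatnonzero(~above[:-1] & above[1:]) + 1
    peaks = []
    peak_vs = []
    last_peak_t = -np.inf
    dt = 1.0 / rate_khz
    for i in up:
        j = i
        while j < len(v) and above[j]:
            j += 1
        seg = v[i:j]
        k = i + int(np.argmax(seg))
        t = k * dt
        if t - last_peak_t < merge_window_ms:
            continue
        peaks.append(t)
        peak_vs.append(v[k])
        last_peak_t = t
    return SpikeTrain(np.asarray(peaks), np.asarray(peak_vs))


def measure_rin(
    family: SweepFamily,
    amp_range_pa: tuple[float, float] = (-50.0, 20.0),
    steady_window_frac: float = 0.2,
) -> float:
    """Input resistance (MOhm): OLS slope of steady-state dV (mV) vs I (pA).

    Sweeps outside the amplitude range or containing spikes are excluded;
    at least three usable sweeps with nonzero current spread are required.
    """
    rate = family.sampling_rate_khz
    pts = []
    for stim, trace in family.sweeps:
        if not (amp_range_pa[0] - 1e-9 <= stim.amplitude <= amp_range_pa[1] + 1e-9):
            continue
        if detect_spikes(trace, rate).n_spikes > 0:
            continue
        dv = _steady_state_mean(trace, stim, rate, steady_window_frac) - _baseline_mean(
            trace, stim, rate
        )
        pts.append((stim.amplitude, dv))
    if len(pts) < 3:
        raise ValueError(f"need >= 3 usable subthreshold sweeps, got {len(pts)}")
    currents = np.array([p[0] for p in pts])
    if np.ptp(currents) == 0:
        raise ValueError("zero current spread in Rin family")
    dvs = np.array([p[1] for p in pts])
    slope_mv_per_pa = np.polyfit(currents, dvs, 1)[0]
    return float(slope_mv_per_pa * 1000.0)  # mV/pA = GOhm -> MOhm


def firing_output(
    family: SweepFamily,
    min_amp_pa: float = 25.0,
) -> FiringOutput:
    """Firing curve, maximum firing frequency and rheobase.

    Considers depolarizing sweeps with amplitude >= ``min_amp_pa``; they
    must share a common step duration.  Frequency = spike count during the
    step divided by the step duration.  Rheobase is the smallest amplitude
    eliciting at least one spike; if no sweep spikes it is reported missing.
    """
    rate = family.sampling_rate_khz
    selected = [(s, tr) for s, tr in family.sweeps if s.amplitude >= min_amp_pa]
    if len(selected) < 2:
        raise ValueError("need >= 2 depolarizing sweeps")
    durations = {s.duration for s, _ in selected}
    if len(durations) > 1:
        raise ValueError(f"mixed step durations in firing family: {sorted(durations)}")
    duration_s = durations.pop() / 1000.0
    curve = []
    for stim, trace in sorted(selected, key=lambda p: p[0].amplitude):
        train = detect_spikes(trace, rate)
        in_step = np.sum(
            (train.peak_times_ms >= stim.onset) & (train.peak_times_ms < stim.offset)
        )
        curve.append((stim.amplitude, int(in_step)))
    max_freq = max(c for _, c in curve) / duration_s
    rheobase = next((a for a, c in curve if c >= 1), None)
    return FiringOutput(curve, float(max_freq), rheobase)


def _smooth(v: np.ndarray, window_samples: int) -> np.ndarray:
    if window_samples <= 1:
        return v
    kernel = np.ones(window_samples) / window_samples
    pad = window_samples // 2
    padded = np.pad(v, pad, mode="edge")
    out = np.convolve(padded, kernel, mode="same")[pad : pad + len(v)]
    return out


def third_derivative(v: np.ndarray, dt_ms: float) -> np.ndarray:
    """d3V/dt3 by three successive central differences (mV/ms^3)."""
    d = v
    for _ in range(3):
        d = np.gradient(d, dt_ms)
    return d


def ap_waveform_features(
    family: SweepFamily,
    rheobase_pa: float,
    above_rheobase_pa: float = 50.0,
    smooth_window_ms: float = 0.1,
    search_window_ms: float = 2.0,
) -> tuple[float, float, float]:
    """AP threshold, amplitude and half-width from the rheobase + 50 pA sweep.

    The voltage is smoothed with a centered moving average before
    differentiation (third differences amplify noise).  The threshold is the
    smoothed voltage at the maximum of d3V/dt3 within the window preceding
    the first spike peak; amplitude is peak minus threshold; half-width is
    the time between the two crossings of threshold + amplitude/2, linearly
    interpolated between samples.
    """
    target = rheobase_pa + above_rheobase_pa
    match = [
        (s, tr) for s, tr in family.sweeps if abs(s.amplitude - target) < 1e-6
    ]
    if not match:
        raise ValueError(f"no sweep at rheobase + {above_rheobase_pa:g} pA = {target:g} pA")
    stim, trace = match[0]
    rate = family.sampling_rate_khz
    dt = 1.0 / rate
    train = detect_spikes(trace, rate)
    if train.n_spikes == 0:
        raise ValueError("no spike in the AP-analysis sweep")
    peak_idx = int(round(train.peak_times_ms[0] / dt))
    v = np.asarray(trace, dtype=np.float64)
    win = max(1, int(round(smooth_window_ms * rate)))
    vs = _smooth(v, win)
    d3 = third_derivative(vs, dt)
    i0 = max(0, peak_idx - int(round(search_window_ms * rate)))
    if peak_idx <= i0:
        raise ValueError("spike peak too close to sweep start for threshold search")
    thr_idx = i0 + int(np.argmax(d3[i0:peak_idx]))
    threshold = float(vs[thr_idx])
    peak_v = float(v[peak_idx])
    amplitude = peak_v - threshold
    if amplitude <= 0:
        raise ValueError("non-positive AP amplitude; threshold search failed")
    level = threshold + amplitude / 2.0

    t_up = None
    for i in range(thr_idx, peak_idx):
        if v[i] < level <= v[i + 1]:
            frac = (level - v[i]) / (v[i + 1] - v[i])
            t_up = (i + frac) * dt
            break
    if t_up is None:
        raise ValueError("half-amplitude rising crossing not found")
    # falling crossing: walk forward from the peak
    t_down = None
    for i in range(peak_idx, len(v) - 1):
        if v[i] >= level > v[i + 1]:
            frac = (v[i] - level) / (v[i] - v[i + 1])
            t_down = (i + frac) * dt
            break
    if t_down is None:
        raise ValueError("half-amplitude falling crossing not found")
    half_width = t_down - t_up
    return threshold, amplitude, float(half_width)


def cv_isi(spike_train: SpikeTrain | Sequence[float]) -> float:
    """Coefficient of variation of inter-spike intervals (sd/mean).

    Uses successive spike peak-time differences and the population (divisor
    n) standard deviation.  Requires at least 4 spikes (3 ISIs).
    """
    times = (
        spike_train.peak_times_ms
        if isinstance(spike_train, SpikeTrain)
        else np.asarray(spike_train, dtype=np.float64)
    )
    if len(times) < 4:
        raise InsufficientSpikesError(
            f"CV ISI needs >= 4 spikes, got {len(times)}"
        )
    isis = np.diff(times)
    return float(np.std(isis) / np.mean(isis))


@dataclass
class SagResult:
    per_sweep: list[tuple[float, float]]  # (current pA, sag ratio)

    @property
    def summary(self) -> float:
        """Sag ratio at the largest hyperpolarizing step."""
        return min(self.per_sweep, key=lambda p: p[0])[1]


def sag_ratio(
    family: SweepFamily,
    max_amp_pa: float = -50.0,
    steady_window_frac: float = 0.2,
) -> SagResult:
    """Sag ratio per hyperpolarizing sweep: peak over steady-state deflection.

    Deflections are positive magnitudes relative to the pre-stimulus
    baseline.  Sweeps containing spikes are excluded; a non-hyperpolarizing
    steady-state response raises.
    """
    rate = family.sampling_rate_khz
    out = []
    for stim, trace in family.sweeps:
        if stim.amplitude > max_amp_pa + 1e-9:
            continue
        if detect_spikes(trace, rate).n_spikes > 0:
            continue
        base = _baseline_mean(trace, stim, rate)
        i_on = int(round(stim.onset * rate))
        i_off = int(round(stim.offset * rate))
        peak_defl = base - float(np.min(trace[i_on:i_off]))
        ss_defl = base - _steady_state_mean(trace, stim, rate, steady_window_frac)
        if ss_defl <= 0:
            raise ValueError(
                f"non-hyperpolarizing steady state at {stim.amplitude:g} pA"
            )
        out.append((stim.amplitude, peak_defl / ss_defl))
    if not out:
        raise ValueError("no usable hyperpolarizing sweeps for sag ratio")
    return SagResult(sorted(out, key=lambda p: p[0]))


def rebound_slope(
    family: SweepFamily,
    max_amp_pa: float = -50.0,
    rebound_window_ms: float = 200.0,
    steady_window_frac: float = 0.2,
) -> float:
    """OLS slope of rebound amplitude vs steady-state voltage.

    Per hyperpolarizing sweep: rebound amplitude = (max V within the window
    after step offset) - baseline (mV); steady-state voltage = mean V over
    the last 20% of the step (mV).  Requires >= 2 sweeps.
    """
    rate = family.sampling_rate_khz
    xs, ys = [], []
    for stim, trace in family.sweeps:
        if stim.amplitude > max_amp_pa + 1e-9:
            continue
        base = _baseline_mean(trace, stim, rate)
        i_off = int(round(stim.offset * rate))
        i_end = min(len(trace), i_off + int(round(rebound_window_ms * rate)))
        rebound = float(np.max(trace[i_off:i_end])) - base
        ss_v = _steady_state_mean(trace, stim, rate, steady_window_frac)
        xs.append(ss_v)
        ys.append(rebound)
    if len(xs) < 2:
        raise ValueError("rebound slope needs >= 2 hyperpolarizing sweeps")
    return float(np.polyfit(np.asarray(xs), np.asarray(ys), 1)[0])


def extract_features(
    families: SweepFamily | Iterable[SweepFamily],
    firing_min_amp_pa: float = 25.0,
    **kwargs,
) -> IntrinsicFeatureSet:
    """Extract the full per-cell feature vector from one or more families.

    Sweeps are pooled and classified by their stimulus descriptors: the
    -50..+20 pA subset feeds Rin, amplitudes >= ``firing_min_amp_pa`` feed
    the firing analysis, and amplitudes <= -50 pA feed sag and rebound.  CV
    ISI is computed on the rheobase + 50 pA sweep.  Features whose inputs
    are unavailable (e.g. rheobase when nothing spikes) are left missing
    rather than failing the whole extraction.
    """
    fams = [families] if isinstance(families, SweepFamily) else list(families)
    if not fams:
        raise ValueError("no sweep families given")
    rate = fams[0].sampling_rate_khz
    for f in fams:
        if f.sampling_rate_khz != rate:
            raise ValueError("families must share a sampling rate")

    fs = IntrinsicFeatureSet()
    # RMP from the pre-stimulus baseline of the first sweep
    stim0, trace0 = fams[0].sweeps[0]
    n0 = int(round(stim0.onset * rate))
    try:
        fs.rmp_mv = measure_rmp(trace0[:n0], rate)
    except ValueError:
        fs.rmp_mv = None

    def family_subset(pred) -> list[SweepFamily]:
        subs = []
        for f in fams:
            picked = [(s, tr) for s, tr in f.sweeps if pred(s)]
            if picked:
                subs.append(
                    SweepFamily(f.sampling_rate_khz, f.sweep_length_ms, picked, f.clamp_mode)
                )
        return subs

    rin_fams = family_subset(lambda s: -50.0 - 1e-9 <= s.amplitude <= 20.0 + 1e-9)
    if rin_fams:
        rin_fam = max(rin_fams, key=len)
        try:
            fs.rin_mohm = measure_rin(
                rin_fam,
                **{k: v for k, v in kwargs.items() if k in ("steady_window_frac",)},
            )
        except ValueError:
            fs.rin_mohm = None

    firing_fams = family_subset(lambda s: s.amplitude >= firing_min_amp_pa)
    firing_fam = firing_fams[0] if firing_fams else None
    if firing_fam is not None:
        try:
            fo = firing_output(firing_fam, firing_min_amp_pa)
            fs.firing_curve = fo.firing_curve
            fs.max_firing_frequency_hz = fo.max_firing_frequency_hz
            fs.rheobase_pa = fo.rheobase_pa
        except ValueError:
            pass
    if fs.rheobase_pa is not None and firing_fam is not None:
        try:
            thr, amp, hw = ap_waveform_features(firing_fam, fs.rheobase_pa)
            fs.ap_threshold_mv, fs.ap_amplitude_mv, fs.ap_half_width_ms = thr, amp, hw
        except ValueError:
            pass
        try:
            target = fs.rheobase_pa + 50.0
            match = [
                tr for s, tr in firing_fam.sweeps if abs(s.amplitude - target) < 1e-6
            ]
            if match:
                fs.cv_isi = cv_isi(detect_spikes(match[0], rate))
        except InsufficientSpikesError:
            pass

    sag_fams = family_subset(lambda s: s.amplitude <= -50.0 + 1e-9 and s.duration >= 500.0)
    if sag_fams:
        sag_fam = max(sag_fams, key=lambda f: max(s.duration for s, _ in f.sweeps))
        try:
            fs.sag_ratio = sag_ratio(sag_fam).summary
        except ValueError:
            pass
        try:
            fs.rebound_slope = rebound_slope(sag_fam)
        except ValueError:
            pass
    return fs
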