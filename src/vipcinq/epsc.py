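"""Spontaneous EPSC detection and kinetics in voltage-clamp traces.

The detector replaces a proprietary event-detection tool with a transparent
threshold/prominence procedure:

1. baseline = running median of the raw trace (window 500 ms), which makes
   detection exactly invariant to a constant holding-current offset;
2. the trace is low-pass filtered (4th-order zero-phase Butterworth, 1 kHz)
   and the inward deviation ``baseline - filtered`` computed;
3. the robust noise SD is the median absolute deviation of the inward
   deviation times 1.4826, and the threshold is ``k * sd`` (default k = 4);
4. event peaks are local maxima of the inward deviation with both height and
   topographic prominence at least the threshold, a minimum width of 1 ms at
   half prominence (suppressing single-sample noise excursions), and at
   least 5 ms separation.  Prominence rather than a plain crossing-and-
   disarm scheme means an event riding on the decay tail of its predecessor
   is still counted, so event frequencies stay unbiased at high rates;
5. the event onset is the last upward threshold crossing before the peak
   (measured relative to the local pre-event level for overlapping events);
6. the amplitude is the mean inward deviation in a +/-0.5 ms window around
   the peak, minus the median local baseline just before onset — averaging
   rather than taking the raw extremum keeps the estimator nearly unbiased
   in noise, and the local baseline implements tail subtraction for
   overlapping events (no deconvolution).

Reported amplitudes and areas are positive magnitudes of the inward
(negative-going) current, matching the sign convention of published sEPSC
summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import butter, find_peaks, sosfiltfilt


@dataclass(frozen=True)
class EpscDetectionConfig:
    baseline_window_ms: float = 500.0
    lowpass_hz: float = 1000.0
    threshold_sds: float = 4.0
    merge_window_ms: float = 5.0
    peak_search_ms: float = 20.0
    min_dwell_ms: float = 1.0
    peak_avg_window_ms: float = 1.0
    local_baseline_ms: float = 4.0
    kinetics_cap_ms: float = 100.0


@dataclass
class EpscEvent:
    """One detected event; amplitude and AUC are positive magnitudes."""

    onset_time_ms: float
    peak_time_ms: float
    amplitude_pa: float
    half_width_ms: float | None = None
    auc_pa_ms: float | None = None
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.amplitude_pa <= 0:
            raise ValueError("event amplitude must be > 0")
        if self.onset_time_ms >= self.peak_time_ms:
            raise ValueError("event onset must precede its peak")


@dataclass
class EpscEventList:
    events: list[EpscEvent]
    trace_duration_s: float

    @property
    def frequency_hz(self) -> float:
        return len(self.events) / self.trace_duration_s

    def __len__(self) -> int:
        return len(self.events)


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    return (
        pd.Series(x)
        .rolling(window, center=True, min_periods=1)
        .median()
        .to_numpy()
    )


def event_kinetics(
    segment: np.ndarray,
    sampling_rate_khz: float,
    amplitude: float | None = None,
) -> tuple[float | None, float | None, bool]:
    """Half-width and AUC of one baseline-subtracted inward-positive segment.

    The segment starts at the event onset.  Half-width is the time between
    the two crossings of 50% of the amplitude (linear interpolation); AUC is
    the trapezoidal integral from onset to the return to baseline (first
    non-positive sample after the peak) or the end of the segment.  Returns
    ``(half_width_ms, auc_pa_ms, truncated)`` — ``truncated`` is True when
    the event does not return to baseline within the segment.
    """
    seg = np.asarray(segment, dtype=np.float64)
    if len(seg) < 2:
        return None, None, True
    dt = 1.0 / sampling_rate_khz
    peak_idx = int(np.argmax(seg))
    if amplitude is None:
        amplitude = float(seg[peak_idx])
    if amplitude <= 0:
        return None, None, True
    level = amplitude / 2.0

    t_up = None
    if seg[0] >= level:
        t_up = 0.0
    else:
        for i in range(peak_idx):
            if seg[i] < level <= seg[i + 1]:
                t_up = (i + (level - seg[i]) / (seg[i + 1] - seg[i])) * dt
                break
    t_down = None
    for i in range(peak_idx, len(seg) - 1):
        if seg[i] >= level > seg[i + 1]:
            t_down = (i + (seg[i] - level) / (seg[i] - seg[i + 1])) * dt
            break
    half_width = (t_down - t_up) if (t_up is not None and t_down is not None) else None

    # return to baseline: first non-positive sample after the peak
    end_idx = None
    for i in range(peak_idx, len(seg)):
        if seg[i] <= 0:
            end_idx = i
            break
    truncated = end_idx is None
    stop = len(seg) if truncated else end_idx + 1
    auc = float(np.trapezoid(seg[:stop], dx=dt))
    return half_width, auc, truncated


def detect_events(
    trace: np.ndarray,
    sampling_rate_khz: float = 10.0,
    config: EpscDetectionConfig = EpscDetectionConfig(),
) -> EpscEventList:
    """Detect spontaneous inward events in a voltage-clamp current trace.

    ``trace`` is the raw current in pA (inward events negative).  Returns
    events ordered by onset with per-event amplitude, half-width and AUC;
    events truncated by the trace end are flagged.
    """
    x = np.asarray(trace, dtype=np.float64)
    rate = sampling_rate_khz
    dt = 1.0 / rate
    w = int(round(config.baseline_window_ms * rate))
    if len(x) <= w:
        raise ValueError(
            f"trace ({len(x)} samples) shorter than baseline window ({w} samples)"
        )
    baseline = _running_median(x, w)
    nyquist_hz = rate * 1000.0 / 2.0
    if 0 < config.lowpass_hz < nyquist_hz:
        sos = butter(4, config.lowpass_hz / nyquist_hz, output="sos")
        filtered = sosfiltfilt(sos, x)
    else:
        filtered = x
    dev = baseline - filtered  # inward deviation, positive magnitudes

    sigma = 1.4826 * float(np.median(np.abs(dev - np.median(dev))))
    if sigma == 0:
        sigma = np.finfo(float).tiny  # noise-free traces: any deviation counts
    thr = config.threshold_sds * sigma

    peaks, _props = find_peaks(
        dev,
        height=thr,
        prominence=thr,
        distance=max(1, int(round(config.merge_window_ms * rate))),
        width=max(1, int(round(config.min_dwell_ms * rate))),
        rel_height=0.5,
    )
    back_w = int(round(config.peak_search_ms * rate))
    avg_half = max(1, int(round(config.peak_avg_window_ms * rate / 2)))
    base_w = max(1, int(round(config.local_baseline_ms * rate)))
    cap = int(round(config.kinetics_cap_ms * rate))
    events: list[EpscEvent] = []
    for p in peaks:
        lo = max(0, p - back_w)
        # onset: last upward threshold crossing before the peak; for events
        # riding on a predecessor's tail the crossing is taken relative to
        # the local minimum (valley) between the two events
        seg_pre = dev[lo:p]
        below = np.flatnonzero(seg_pre < thr)
        if len(below):
            i = lo + int(below[-1]) + 1
        else:
            valley = lo + int(np.argmin(seg_pre)) if len(seg_pre) else lo
            level = dev[valley] + thr
            risen = np.flatnonzero(dev[valley:p] < level)
            i = valley + (int(risen[-1]) + 1 if len(risen) else 1)
        i = min(i, p - 1) if p > 0 else 0
        base_lo = max(0, i - base_w)
        local_base = float(np.median(dev[base_lo:i])) if i > base_lo else 0.0
        a0, a1 = max(0, p - avg_half), min(len(dev), p + avg_half + 1)
        amplitude = float(np.mean(dev[a0:a1])) - local_base
        if amplitude <= 0:
            continue
        seg = dev[i : min(len(dev), i + cap)] - local_base
        hw, auc, truncated = event_kinetics(seg, rate, amplitude)
        events.append(
            EpscEvent(
                onset_time_ms=i * dt,
                peak_time_ms=p * dt,
                amplitude_pa=amplitude,
                half_width_ms=hw,
                auc_pa_ms=auc,
                truncated=truncated or (i + cap >= len(dev)),
            )
        )
    events.sort(key=lambda e: e.onset_time_ms)
    return EpscEventList(events=events, trace_duration_s=len(x) * dt / 1000.0)


def summarize_epsc(event_list: EpscEventList) -> dict:
    """Per-cell summary: frequency plus arithmetic means of event measures.

    Frequency is defined even with zero events; kinetics means require at
    least one (non-truncated, for half-width/AUC) event and are reported as
    NaN otherwise.
    """
    events = event_list.events
    clean = [e for e in events if not e.truncated]
    return {
        "n_events": len(events),
        "frequency_hz": event_list.frequency_hz,
        "mean_amplitude_pa": float(np.mean([e.amplitude_pa for e in events]))
        if events
        else float("nan"),
        "mean_half_width_ms": float(
            np.mean([e.half_width_ms for e in clean if e.half_width_ms is not None])
        )
        if any(e.half_width_ms is not None for e in clean)
        else float("nan"),
        "mean_auc_pa_ms": float(
            np.mean([e.auc_pa_ms for e in clean if e.auc_pa_ms is not None])
        )
        if any(e.auc_pa_ms is not None for e in clean)
        else float("nan"),
    }
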