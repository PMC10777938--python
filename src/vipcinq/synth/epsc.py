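"""Synthetic spontaneous EPSC traces with known ground truth.

Events arrive as a homogeneous Poisson process.  Each event adds an inward
(negative-going) biexponential current transient, normalized to unit peak and
scaled by its amplitude, onto the holding baseline.  Recording noise is
additive Gaussian on the current.  The generator emulates 5 min voltage-clamp
recordings at -70 mV holding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class BiexpKernel:
    """Biexponential synaptic kernel ``A (exp(-t/tau_d) - exp(-t/tau_r))``.

    ``amplitude_pa`` is the positive peak magnitude of the inward current;
    the kernel is normalized so its peak equals exactly that value.
    """

    amplitude_pa: float = 20.0
    rise_tau_ms: float = 1.0
    decay_tau_ms: float = 10.0

    def __post_init__(self) -> None:
        if not (self.decay_tau_ms > self.rise_tau_ms > 0):
            raise ValueError("kernel requires decay tau > rise tau > 0")
        if self.amplitude_pa <= 0:
            raise ValueError("kernel amplitude must be > 0")

    @property
    def peak_time_ms(self) -> float:
        r, d = self.rise_tau_ms, self.decay_tau_ms
        return r * d / (d - r) * math.log(d / r)

    @property
    def peak_norm(self) -> float:
        """Peak value of the un-normalized difference of exponentials."""
        tp = self.peak_time_ms
        return math.exp(-tp / self.decay_tau_ms) - math.exp(-tp / self.rise_tau_ms)

    def analytic_auc_pa_ms(self) -> float:
        """Closed-form area of one unit-amplitude-scaled event (pA*ms)."""
        return self.amplitude_pa * (self.decay_tau_ms - self.rise_tau_ms) / self.peak_norm

    def render(self, t_ms: np.ndarray) -> np.ndarray:
        """Unit-peak kernel evaluated at times >= 0 (zero before onset)."""
        y = np.where(
            t_ms >= 0,
            np.exp(-np.maximum(t_ms, 0) / self.decay_tau_ms)
            - np.exp(-np.maximum(t_ms, 0) / self.rise_tau_ms),
            0.0,
        )
        return y / self.peak_norm


@dataclass(frozen=True)
class EpscGroundTruth:
    onset_times_ms: np.ndarray
    amplitudes_pa: np.ndarray


def simulate_epsc_trace(
    rate_hz: float,
    kernel: BiexpKernel,
    duration_s: float,
    noise_sd_pa: float,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    sampling_rate_khz: float = 10.0,
    baseline_pa: float = 0.0,
    amplitude_cv: float = 0.0,
) -> tuple[np.ndarray, EpscGroundTruth]:
    """Simulate a voltage-clamp current trace with planted sEPSC events.

    Returns the current trace (pA; inward events are negative deflections)
    and the planted event onsets/amplitudes for recall, precision and bias
    oracles.  ``amplitude_cv`` > 0 draws per-event amplitudes from a
    lognormal with that coefficient of variation around the kernel amplitude.
    """
    if duration_s <= 0:
        raise ValueError("duration must be > 0")
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    if noise_sd_pa < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    duration_ms = duration_s * 1000.0
    n = int(round(duration_ms * sampling_rate_khz))
    dt = 1.0 / sampling_rate_khz
    n_events = rng.poisson(rate_hz * duration_s)
    onsets = np.sort(rng.uniform(0.0, duration_ms, n_events))
    if amplitude_cv > 0:
        sigma = math.sqrt(math.log(1.0 + amplitude_cv**2))
        amps = kernel.amplitude_pa * rng.lognormal(-0.5 * sigma**2, sigma, n_events)
    else:
        amps = np.full(n_events, kernel.amplitude_pa)

    trace = np.full(n, baseline_pa, dtype=np.float64)
    # render each event over a finite support (12 decay constants)
    support = int(round(12.0 * kernel.decay_tau_ms * sampling_rate_khz))
    t_rel = np.arange(support) * dt
    for onset, amp in zip(onsets, amps):
        i0 = int(math.ceil(onset * sampling_rate_khz))
        if i0 >= n:
            continue
        seg = slice(i0, min(i0 + support, n))
        t = (np.arange(seg.start, seg.stop) * dt) - onset
        trace[seg] -= amp * kernel.render(t)
    if noise_sd_pa > 0:
        trace += rng.normal(0.0, noise_sd_pa, n)
    return trace, EpscGroundTruth(onset_times_ms=onsets, amplitudes_pa=amps)
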