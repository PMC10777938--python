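"""Single-compartment membrane model used to generate current-clamp sweeps.

The model is an adaptive exponential integrate-and-fire (AdEx) neuron with an
additional hyperpolarization-activated cation current (H-current, carried by
HCN channels in real VIP+ interneurons).  State variables:

``V``   membrane voltage (mV)
``w``   spike-triggered adaptation current (pA), decaying with ``tau_w``
``m``   first-order H-current activation in [0, 1]

Membrane equation (units: pF, nS, mV, pA, ms — note pA/pF = mV/ms)::

    C dV/dt = -gL (V - EL) + gL * dT * exp((V - VT)/dT)
              - w - gh * m * (V - Eh) + I(t)

A spike initiates when ``V`` crosses the committed-initiation voltage
``VT + dT`` (one slope factor above the intrinsic threshold, where the
exponential term dominates the membrane current).  The recorded waveform then
follows a stereotyped spike: a linear rise to the peak :data:`SPIKE_PEAK_MV`
over ``0.1 * dT`` ms and a linear fall to the reset voltage over ``0.2 * dT``
ms.  Because the pasted shape is defined in time units, spike amplitude,
timing and width are stable under refinement of the integration step; the
slope factor both sets the initiation voltage offset and scales the
action-potential width, and the slope discontinuity at the waveform foot
makes the third-derivative threshold criterion land at ``~VT + dT``.  The
recorded spikes still cross :data:`SPIKE_CUTOFF_MV` upward on their way to
the peak, which is what the spike detector operating on recorded sweeps
looks for.
With ``gh > 0`` a hyperpolarizing step produces a voltage sag (transient
minimum below the late steady state) and a depolarizing rebound at step
offset, the HCN signature measured in the sag-ratio and rebound-slope
features.

Recording noise is modelled as additive Gaussian noise on the returned
voltage trace (measurement noise); the underlying dynamics are deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import brentq

try:  # pragma: no cover - exercised implicitly on import
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore[misc]
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


#: Voltage (mV) whose upward crossing defines a spike, both in the simulator
#: and in the spike detector operating on recorded sweeps.
SPIKE_CUTOFF_MV = 0.0
#: Stylized spike-peak sample (mV) written at each registered spike.
SPIKE_PEAK_MV = 20.0


class IntegrationError(RuntimeError):
    """Raised when the membrane integration produces a non-finite state."""


@dataclass(frozen=True)
class NeuronModelParams:
    """Parameters of the AdEx + H-current membrane model.

    All conductances in nS, capacitance in pF, voltages in mV, currents in
    pA, time constants in ms.
    """

    capacitance: float = 30.0
    leak_conductance: float = 4.0
    leak_reversal: float = -65.0
    spike_threshold_slope_factor: float = 2.0
    intrinsic_threshold: float = -45.0
    reset_voltage: float = -55.0
    adaptation_increment: float = 40.0
    adaptation_time_constant: float = 120.0
    h_current_max_conductance: float = 2.0
    h_current_reversal: float = -30.0
    h_current_activation_midpoint: float = -85.0
    h_current_time_constant: float = 50.0
    h_current_activation_slope: float = 8.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.capacitance <= 0:
            raise ValueError("capacitance must be > 0")
        if self.leak_conductance <= 0:
            raise ValueError("leak_conductance must be > 0")
        if self.h_current_max_conductance < 0:
            raise ValueError("h_current_max_conductance must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.h_current_activation_slope <= 0:
            raise ValueError("h_current_activation_slope must be > 0")

    @property
    def membrane_time_constant_ms(self) -> float:
        return self.capacitance / self.leak_conductance

    def passive(self) -> "NeuronModelParams":
        """Copy with spiking, adaptation and H-current disabled.

        The intrinsic threshold is moved far above physiological range so the
        exponential term underflows to zero; the membrane is then a pure RC
        circuit with closed-form step responses.
        """
        return replace(
            self,
            intrinsic_threshold=1e6,
            adaptation_increment=0.0,
            h_current_max_conductance=0.0,
        )


@dataclass(frozen=True)
class StimulusDescriptor:
    """One rectangular current step riding on a holding current."""

    amplitude: float  # pA
    onset: float = 200.0  # ms
    duration: float = 800.0  # ms
    baseline_current: float = 0.0  # pA

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("stimulus duration must be > 0")
        if self.onset < 0:
            raise ValueError("stimulus onset must be >= 0")

    @property
    def offset(self) -> float:
        return self.onset + self.duration

    def validate_for_length(self, sweep_length_ms: float) -> None:
        if self.offset > sweep_length_ms + 1e-9:
            raise ValueError(
                f"stimulus extends to {self.offset} ms, beyond sweep length "
                f"{sweep_length_ms} ms"
            )

    def waveform(self, n_samples: int, dt_ms: float) -> np.ndarray:
        t = np.arange(n_samples) * dt_ms
        i = np.full(n_samples, self.baseline_current, dtype=np.float64)
        i[(t >= self.onset) & (t < self.offset)] += self.amplitude
        return i


@dataclass
class SweepFamily:
    """A family of equal-length sweeps sharing a sampling rate.

    ``sweeps`` pairs each stimulus descriptor with its recorded sample
    vector: voltage (mV) in current clamp, current (pA) in voltage clamp.
    ``spike_truth`` optionally carries the simulator's reset log (ground-truth
    spike times, ms) for oracle-based tests; file round-trips drop it.
    """

    sampling_rate_khz: float
    sweep_length_ms: float
    sweeps: list[tuple[StimulusDescriptor, np.ndarray]]
    clamp_mode: Literal["current", "voltage"] = "current"
    spike_truth: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        n = self.n_samples
        for k, (stim, trace) in enumerate(self.sweeps):
            if len(trace) != n:
                raise ValueError(
                    f"sweep {k} has {len(trace)} samples, expected {n}"
                )
            stim.validate_for_length(self.sweep_length_ms)

    @property
    def dt_ms(self) -> float:
        return 1.0 / self.sampling_rate_khz

    @property
    def n_samples(self) -> int:
        return int(round(self.sweep_length_ms * self.sampling_rate_khz))

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt_ms

    def __len__(self) -> int:
        return len(self.sweeps)


@dataclass(frozen=True)
class SimulatedSweep:
    """A simulated voltage sweep plus the model's ground-truth spike log."""

    voltage_mv: np.ndarray
    spike_times_ms: np.ndarray
    dt_ms: float

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.voltage_mv)) * self.dt_ms


@njit(cache=False)
def _integrate(
    stim: np.ndarray,
    dt: float,
    c: float,
    g_l: float,
    e_l: float,
    d_t: float,
    v_t: float,
    v_reset: float,
    b: float,
    tau_w: float,
    g_h: float,
    e_h: float,
    v_half: float,
    tau_h: float,
    k_h: float,
    v0: float,
    m0: float,
    spike_init: float,
    spike_peak: float,
    rise_ms: float,
    fall_ms: float,
):  # pragma: no cover - numba-compiled
    n = stim.shape[0]
    out = np.empty(n)
    spikes = np.empty(n, dtype=np.int64)
    n_spikes = 0
    v = v0
    w = 0.0
    m = m0
    out[0] = v
    n_rise = max(1, int(round(rise_ms / dt)))
    n_fall = max(1, int(round(fall_ms / dt)))
    i = 1
    while i < n:
        arg = (v - v_t) / d_t
        if arg > 30.0:
            arg = 30.0
        exp_term = g_l * d_t * math.exp(arg)
        i_h = g_h * m * (v - e_h)
        dv = (-g_l * (v - e_l) + exp_term - w - i_h + stim[i - 1]) * dt / c
        m_inf = 1.0 / (1.0 + math.exp((v - v_half) / k_h))
        if tau_h > 0.0:
            m += dt * (m_inf - m) / tau_h
        if tau_w > 0.0:
            w += dt * (-w / tau_w)
        v_new = v + dv
        if not math.isfinite(v_new):
            return out, spikes[:n_spikes], i
        if v_new >= spike_init:
            # paste the stereotyped spike waveform: linear rise from the
            # initiation voltage to the peak over rise_ms, linear fall to
            # reset over fall_ms; the state is refractory during the paste
            v_start = v_new if v_new < spike_peak else spike_init
            for j in range(n_rise):
                k = i + j
                if k >= n:
                    break
                out[k] = v_start + (spike_peak - v_start) * (j + 1.0) / n_rise
            peak_idx = i + n_rise - 1
            if peak_idx < n:
                spikes[n_spikes] = peak_idx
                n_spikes += 1
            for j in range(n_fall):
                k = i + n_rise + j
                if k >= n:
                    break
                out[k] = spike_peak + (v_reset - spike_peak) * (j + 1.0) / n_fall
            v = v_reset
            w += b
            i = i + n_rise + n_fall
        else:
            out[i] = v_new
            v = v_new
            i += 1
    return out, spikes[:n_spikes], -1


def _resting_state(params: NeuronModelParams, holding_pa: float) -> tuple[float, float]:
    """Solve the subthreshold steady state (V, m) for a holding current."""
    p = params

    def m_inf(v: float) -> float:
        return 1.0 / (
            1.0 + math.exp((v - p.h_current_activation_midpoint) / p.h_current_activation_slope)
        )

    def balance(v: float) -> float:
        arg = min((v - p.intrinsic_threshold) / p.spike_threshold_slope_factor, 30.0)
        exp_term = p.leak_conductance * p.spike_threshold_slope_factor * math.exp(arg)
        return (
            -p.leak_conductance * (v - p.leak_reversal)
            + exp_term
            - p.h_current_max_conductance * m_inf(v) * (v - p.h_current_reversal)
            + holding_pa
        )

    lo = -150.0
    hi = min(p.intrinsic_threshold + p.spike_threshold_slope_factor, SPIKE_CUTOFF_MV) - 1e-6
    try:
        if balance(lo) * balance(hi) < 0:
            v0 = brentq(balance, lo, hi, xtol=1e-10)
        else:
            v0 = p.leak_reversal + holding_pa / p.leak_conductance
    except ValueError:  # pathological parameters; fall back to ohmic rest
        v0 = p.leak_reversal + holding_pa / p.leak_conductance
    return float(v0), m_inf(float(v0))


def simulate_sweep(
    params: NeuronModelParams,
    stim: StimulusDescriptor,
    rate_khz: float = 50.0,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    sweep_length_ms: float | None = None,
) -> SimulatedSweep:
    """Integrate one current-clamp sweep.

    Fixed-step explicit (forward-Euler) integration with ``dt = 1/rate``;
    spike-and-reset at the initiation voltage ``VT + dT``.  The membrane
    starts at its
    subthreshold steady state for the stimulus baseline current, so a zero
    stimulus with the H-current off yields a flat trace at the leak reversal.

    Raises
    ------
    IntegrationError
        If the state becomes non-finite; the message names the time step.
    """
    if rate_khz < 10.0:
        raise ValueError("sampling rate must be >= 10 kHz for spike-shape analysis")
    if sweep_length_ms is None:
        sweep_length_ms = stim.offset + 400.0
    stim.validate_for_length(sweep_length_ms)
    dt = 1.0 / rate_khz
    n = int(round(sweep_length_ms * rate_khz))
    waveform = stim.waveform(n, dt)
    v0, m0 = _resting_state(params, stim.baseline_current)
    p = params
    out, spikes, fail = _integrate(
        waveform,
        dt,
        p.capacitance,
        p.leak_conductance,
        p.leak_reversal,
        p.spike_threshold_slope_factor,
        p.intrinsic_threshold,
        p.reset_voltage,
        p.adaptation_increment,
        p.adaptation_time_constant,
        p.h_current_max_conductance,
        p.h_current_reversal,
        p.h_current_activation_midpoint,
        p.h_current_time_constant,
        p.h_current_activation_slope,
        v0,
        m0,
        p.intrinsic_threshold + p.spike_threshold_slope_factor,
        SPIKE_PEAK_MV,
        0.1 * p.spike_threshold_slope_factor,
        0.2 * p.spike_threshold_slope_factor,
    )
    if fail >= 0:
        raise IntegrationError(
            f"non-finite membrane state at time step {fail} (t = {fail * dt:.4f} ms)"
        )
    if params.noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, params.noise_sd, n)
    return SimulatedSweep(voltage_mv=out, spike_times_ms=spikes * dt, dt_ms=dt)


def simulate_family(
    params: NeuronModelParams,
    protocol: Sequence[StimulusDescriptor],
    rate_khz: float = 50.0,
    seed: int | np.random.SeedSequence | None = None,
    sweep_length_ms: float | None = None,
) -> SweepFamily:
    """Simulate one sweep per stimulus descriptor, preserving order.

    All sweeps share a common length (the longest stimulus plus a 400 ms
    tail unless given) and a common settling baseline before onset.  The
    returned family carries the simulator's spike-time log in
    ``spike_truth``.
    """
    if len(protocol) == 0:
        raise ValueError("protocol must contain at least one stimulus")
    if sweep_length_ms is None:
        sweep_length_ms = max(s.offset for s in protocol) + 400.0
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = ss.spawn(len(protocol))
    sweeps = []
    truth = []
    for stim, child in zip(protocol, children):
        sim = simulate_sweep(params, stim, rate_khz, child, sweep_length_ms)
        sweeps.append((stim, sim.voltage_mv))
        truth.append(sim.spike_times_ms)
    return SweepFamily(
        sampling_rate_khz=rate_khz,
        sweep_length_ms=sweep_length_ms,
        sweeps=sweeps,
        clamp_mode="current",
        spike_truth=truth,
    )
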