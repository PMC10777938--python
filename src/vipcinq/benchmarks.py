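"""From-scratch validation benchmarks for every pipeline stage.

Each function regenerates its inputs with the synthetic generators, runs the
measurement path under test, and returns a scalar quality metric together
with the problem size used.  They are consumed by the acceptance script and
the acceptance test suite; nothing here caches or reuses previous results.
"""

from __future__ import annotations

import itertools
from dataclasses import replace

import numpy as np
from scipy import stats as sps

from . import intrinsic as intr
from .counts import trajectory_contrast
from .epsc import EpscDetectionConfig, detect_events, event_kinetics
from .puncta import Punctum, colocalize
from .stats import one_way_anova, two_way_anova
from .synth import (
    BiexpKernel,
    CohortSpec,
    NeuronModelParams,
    StimulusDescriptor,
    simulate_cohort,
    simulate_epsc_trace,
    simulate_family,
    simulate_sweep,
)
from .synth.protocols import firing_protocol, rin_protocol, sag_protocol


def _spawn(seed: int, n: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(seed).spawn(n)


# --------------------------------------------------------------------------
# closed-form limits


def rc_supnorm_error_pct(seed: int = 0) -> tuple[float, int]:
    """Worst-case deviation of a passive simulated step response from the
    analytic RC solution, as % of the step amplitude (whole sweep)."""
    params = NeuronModelParams().passive()
    worst = 0.0
    n = 0
    for amp in (-150.0, -50.0, 30.0):
        stim = StimulusDescriptor(amp, 200, 500)
        sw = simulate_sweep(params, stim, 50.0, seed, 1000.0)
        t = sw.time_ms
        tau = params.membrane_time_constant_ms
        el = params.leak_reversal
        dv = amp / params.leak_conductance
        expected = np.full_like(t, el)
        during = (t >= stim.onset) & (t < stim.offset)
        expected[during] = el + dv * (1 - np.exp(-(t[during] - stim.onset) / tau))
        after = t >= stim.offset
        v_off = el + dv * (1 - np.exp(-stim.duration / tau))
        expected[after] = el + (v_off - el) * np.exp(-(t[after] - stim.offset) / tau)
        worst = max(worst, float(np.max(np.abs(sw.voltage_mv - expected)) / abs(dv)))
        n += len(t)
    return 100.0 * worst, n


def biexp_auc_error_pct(seed: int = 0) -> tuple[float, int]:
    """Relative error of the measured AUC of one noise-free biexponential
    event against its closed-form integral."""
    kernel = BiexpKernel(20.0, 1.0, 10.0)
    rate = 10.0
    t = np.arange(int(300 * rate)) / rate
    seg = 20.0 * kernel.render(t)
    _, auc, _ = event_kinetics(seg, rate)
    return 100.0 * abs(auc - kernel.analytic_auc_pa_ms()) / kernel.analytic_auc_pa_ms(), len(t)


def passive_sag_and_rebound(seed: int = 0) -> tuple[float, float, int]:
    """Sag ratio and rebound slope of a passive cell (expected 1 and 0)."""
    params = NeuronModelParams().passive()
    fam = simulate_family(params, sag_protocol(), 50.0, seed)
    sag = intr.sag_ratio(fam).summary
    slope = intr.rebound_slope(fam)
    return float(sag), float(slope), len(fam)


# --------------------------------------------------------------------------
# oracle equivalence


def ap_threshold_error_mv(seed: int = 0) -> tuple[float, int]:
    """|pipeline threshold at 50 kHz - brute-force d3V/dt3 maximization on a
    500 kHz simulation of the same cell| (mV)."""
    params = NeuronModelParams()
    fam = simulate_family(params, firing_protocol(), 50.0, seed)
    rheo = intr.firing_output(fam).rheobase_pa
    thr50, _, _ = intr.ap_waveform_features(fam, rheo)

    rate = 500.0
    sw = simulate_sweep(params, StimulusDescriptor(rheo + 50.0, 200, 800), rate, seed, 1200.0)
    dt = 1.0 / rate
    win = int(round(0.1 * rate))
    kernel = np.ones(win) / win
    v = sw.voltage_mv
    vs = np.convolve(np.pad(v, win // 2, mode="edge"), kernel, mode="same")[
        win // 2 : win // 2 + len(v)
    ]
    d3 = vs.copy()
    for _ in range(3):
        d3 = np.gradient(d3, dt)
    peak_idx = int(round(sw.spike_times_ms[0] / dt))
    lo = peak_idx - int(round(2.0 * rate))
    thr_oracle = float(vs[lo + int(np.argmax(d3[lo:peak_idx]))])
    return abs(thr50 - thr_oracle), len(v)


def rin_grid_max_error_pct(seed: int = 0, n_cells: int = 20) -> tuple[float, int]:
    """Worst-case Rin recovery error over a grid of passive cells spanning
    100-500 MOhm with 0.2 mV recording noise, vs the analytic 1/gL."""
    worst = 0.0
    seeds = _spawn(seed, n_cells)
    for ss, g_leak in zip(seeds, np.linspace(2.0, 10.0, n_cells)):
        p = replace(NeuronModelParams(noise_sd=0.2).passive(), leak_conductance=float(g_leak))
        fam = simulate_family(p, rin_protocol(), 50.0, ss)
        rin = intr.measure_rin(fam)
        truth = 1000.0 / g_leak
        worst = max(worst, abs(rin - truth) / truth)
    return 100.0 * worst, n_cells


def _exhaustive_match_count(pre, post, d_max):
    best = 0
    n = min(len(pre), len(post))
    for k in range(n, 0, -1):
        for pre_idx in itertools.combinations(range(len(pre)), k):
            for post_perm in itertools.permutations(range(len(post)), k):
                ok = all(
                    np.hypot(pre[i].x_um - post[j].x_um, pre[i].y_um - post[j].y_um)
                    <= d_max
                    for i, j in zip(pre_idx, post_perm)
                )
                if ok:
                    return k
    return best


def coloc_oracle_agreement(seed: int = 0, n_scenes: int = 30) -> tuple[float, int]:
    """Fraction of planted pair/singleton scenes (<= 10 puncta) where greedy
    colocalization equals the exhaustive maximum matching."""
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_scenes):
        centers: list[tuple[float, float]] = []
        while len(centers) < 5:
            c = tuple(rng.uniform(0, 12, 2))
            if all(np.hypot(c[0] - a, c[1] - b) > 1.5 for a, b in centers):
                centers.append(c)
        pre, post = [], []
        for i, (x, y) in enumerate(centers):
            kind = rng.integers(0, 3)
            if kind == 0:  # colocalized pair
                pre.append(Punctum(x, y, 0, 0.1, 100.0))
                theta = rng.uniform(0, 2 * np.pi)
                r = rng.uniform(0.05, 0.3)
                post.append(Punctum(x + r * np.cos(theta), y + r * np.sin(theta), 0, 0.1, 100.0))
            elif kind == 1:  # presynaptic singleton
                pre.append(Punctum(x, y, 0, 0.1, 100.0))
            else:  # postsynaptic singleton
                post.append(Punctum(x, y, 0, 0.1, 100.0))
        greedy = len(colocalize(pre, post, 0.5)) if pre and post else 0
        oracle = _exhaustive_match_count(pre, post, 0.5) if pre and post else 0
        agree += greedy == oracle
    return agree / n_scenes, n_scenes


def t2_f_identity_max_diff(seed: int = 0, n_reps: int = 50) -> tuple[float, int]:
    """Max |F - t^2| over random two-group datasets."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_reps):
        a = rng.normal(0, 1, int(rng.integers(3, 12)))
        b = rng.normal(rng.uniform(0, 2), 1.3, int(rng.integers(3, 12)))
        f = one_way_anova({"a": a, "b": b}).f_statistic
        t, _ = sps.ttest_ind(a, b)
        worst = max(worst, abs(f - t**2))
    return worst, n_reps


def ss_decomposition_max_residual(seed: int = 0, n_reps: int = 50) -> tuple[float, int]:
    """Max relative |SS_total - (SS_between + SS_within)| over random data."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_reps):
        groups = {
            k: rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), int(rng.integers(3, 15)))
            for k in "abcd"
        }
        res = one_way_anova(groups)
        allv = np.concatenate(list(groups.values()))
        ss_total = float(np.sum((allv - allv.mean()) ** 2))
        worst = max(worst, abs(ss_total - res.ss_between - res.ss_within) / ss_total)
    return worst, n_reps


# --------------------------------------------------------------------------
# parameter recovery


def epsc_recall_and_bias(
    seed: int = 0, n_seeds: int = 100, duration_s: float = 30.0
) -> tuple[float, float, int]:
    """Detector recall and relative amplitude bias at SNR 5 against the
    generator's planted truth (onset matching window 5 ms)."""
    kernel = BiexpKernel(20.0, 1.0, 10.0)  # amplitude / noise sd = 5
    hits = planted = 0
    ratios: list[float] = []
    for ss in _spawn(seed, n_seeds):
        trace, truth = simulate_epsc_trace(2.0, kernel, duration_s, 4.0, ss)
        det = detect_events(trace, 10.0)
        det_on = np.array([e.onset_time_ms for e in det.events])
        for t, a in zip(truth.onset_times_ms, truth.amplitudes_pa):
            planted += 1
            if len(det_on):
                j = int(np.argmin(np.abs(det_on - t)))
                if abs(det_on[j] - t) <= 5.0:
                    hits += 1
                    ratios.append(det.events[j].amplitude_pa / a)
    recall = hits / planted
    bias_pct = 100.0 * (float(np.mean(ratios)) - 1.0)
    return recall, bias_pct, planted


def epsc_frequency_coverage(
    seed: int = 0,
    rates_hz: tuple[float, ...] = (0.5, 2.0, 5.0, 10.0),
    reps_per_rate: int = 25,
    duration_s: float = 30.0,
) -> tuple[float, int]:
    """Fraction of replicates whose detected event count falls inside the
    central Poisson 95% interval of the planted rate."""
    kernel = BiexpKernel(20.0, 1.0, 10.0)
    inside = total = 0
    seeds = iter(_spawn(seed, len(rates_hz) * reps_per_rate))
    for rate in rates_hz:
        mean = rate * duration_s
        lo, hi = sps.poisson.ppf(0.025, mean), sps.poisson.ppf(0.975, mean)
        for _ in range(reps_per_rate):
            trace, _ = simulate_epsc_trace(rate, kernel, duration_s, 4.0, next(seeds))
            n = len(detect_events(trace, 10.0))
            inside += lo <= n <= hi
            total += 1
    return inside / total, total


def cohort_divergence_power(
    seed: int = 0, n_reps: int = 100, n_animals: int = 8
) -> tuple[float, int]:
    """Power to flag the planted P15->P25 divergence between the flat-cKO
    and declining-WT trajectories (planted effect ~2 pooled sd at P25)."""
    spec = CohortSpec(density_sd=29.0, n_animals=n_animals)
    hits = 0
    for ss in _spawn(seed, n_reps):
        res = trajectory_contrast(simulate_cohort(spec, ss))
        hits += res.earliest_divergence_age == 25
    return hits / n_reps, n_reps


# --------------------------------------------------------------------------
# statistical calibration


def anova_type1_error(seed: int = 0, n_reps: int = 10_000) -> tuple[float, int]:
    """One-way ANOVA rejection rate at alpha = 0.05 under the null
    (three Normal(0,1) groups, n = 12 each)."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_reps):
        g = {k: rng.normal(0.0, 1.0, 12) for k in "abc"}
        rejections += one_way_anova(g).p_value < 0.05
    return rejections / n_reps, n_reps


def interaction_df_for_firing_design(seed: int = 0) -> tuple[int, int]:
    """Interaction df of the genotype x current two-way ANOVA with 3
    genotypes and the 13-level firing protocol."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    levels = [s.amplitude for s in firing_protocol()]
    rows = [
        {"genotype": g, "current": lev, "spikes": rng.normal(gi + 0.02 * lev, 1.0)}
        for gi, g in enumerate(("WT", "cHet", "cKO"))
        for lev in levels
        for _ in range(2)
    ]
    res = two_way_anova(pd.DataFrame(rows), "spikes", "genotype", "current")
    return res.interaction_df, len(rows)


# --------------------------------------------------------------------------
# exact toy identities


def toy_identities() -> dict[str, float]:
    """The instant closed-form checks, each computed by the pipeline code."""
    from .counts import CountBox, density_in_box
    from .puncta import dendrite_length as dlen
    from .puncta import soma_geometry
    import pandas as pd

    cv_periodic = intr.cv_isi(np.arange(10) * 50.0)
    cv_known = intr.cv_isi(np.cumsum([0.0, 10.0, 20.0, 30.0]))
    rng = np.random.default_rng(0)
    cells = pd.DataFrame(
        {
            "animal_id": "m1",
            "section_id": 0,
            "x_um": rng.uniform(0, 1000, 50),
            "y_um": rng.uniform(0, 500, 50),
            "markers": "VIP",
        }
    )
    density = density_in_box(cells, CountBox(0, 0, 1000, 500))
    circ, area = soma_geometry([(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)])
    length = dlen([(0.0, 0.0), (3.0, 4.0)])
    return {
        "cv_isi_periodic": float(cv_periodic),
        "cv_isi_10_20_30": float(cv_known),
        "density_50_cells_half_mm2": float(density),
        "soma_circumference_10um_square": float(circ),
        "soma_area_10um_square": float(area),
        "dendrite_length_3_4": float(length),
    }
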