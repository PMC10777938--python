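# Methods

`vipcinq` re-implements, as a tested pipeline, the quantification machinery
used in studies of *Tsc1* deletion in VIP+ cortical interneurons: intrinsic
electrophysiology feature extraction, spontaneous EPSC (sEPSC) analysis,
synaptic puncta colocalization densities, developmental cell-density and
apoptosis counting, and the group-comparison statistics. Because no
recordings or images are deposited for such studies, every stage is driven
by a synthetic-data generator with known ground truth, and every measurement
is validated against closed forms, brute-force oracles, or that ground
truth. This note documents the models, the defaults and why, the numerical
choices, and what passing the tests does and does not establish.

## Membrane model and sweep generator

Current-clamp sweeps come from an adaptive exponential integrate-and-fire
(AdEx) neuron extended with a hyperpolarization-activated cation current
(H-current, the HCN conductance of real VIP+ cells):

    C dV/dt = -gL (V - EL) + gL·ΔT·exp((V - VT)/ΔT) - w - gh·m·(V - Eh) + I(t)
    dw/dt   = -w/τw                (w += b at each spike)
    dm/dt   = (m∞(V) - m)/τh,      m∞(V) = 1 / (1 + exp((V - V½)/k))

Units are pF, nS, mV, pA, ms (so pA/pF = mV/ms). Integration is fixed-step
forward Euler with dt = 1/sampling-rate. This is deliberately the simplest
mechanism that produces every measured feature — an ohmic subthreshold
regime (input resistance), a rheobase, adapting spike trains (CV of
inter-spike intervals), and HCN-dependent sag and rebound — with every
feature controllable through one parameter.

A spike initiates when V crosses VT + ΔT, one slope factor above the
intrinsic threshold, where the exponential term dominates the membrane
current and the trajectory is committed. The recorded waveform then follows
a stereotyped spike — linear rise to +20 mV over 0.1·ΔT ms, linear fall to
the reset voltage over 0.2·ΔT ms — defined in *time* units, so spike
amplitude, timing and width converge under dt refinement (a raw EIF
upstroke diverges and makes all three dt-dependent). Two consequences are
intentional: the slope discontinuity at the waveform foot places the
maximum of d³V/dt³ at ≈ VT + ΔT, giving the third-derivative threshold
criterion a well-defined target; and ΔT becomes the single knob controlling
spike width (≈ 0.27 ms at ΔT = 2 mV — narrower than real VIP+ spikes, but
the comparisons the pipeline makes are relative, not absolute).

Recording noise is additive Gaussian on the returned voltage trace
(measurement noise, default SD 0.2 mV in the pipeline); the dynamics are
deterministic, and the integrator's reset log is returned as ground truth
for spike detection. Sweeps start at the numerically solved subthreshold
steady state, so baselines are flat from t = 0.

Default cell (VIP-like): C = 30 pF, gL = 4 nS (τm = 7.5 ms, Rin ≈ 250 MΩ
passive), EL = -65 mV, ΔT = 2 mV, VT = -45 mV, Vreset = -55 mV, b = 40 pA,
τw = 120 ms, gh = 2 nS, Eh = -30 mV, V½ = -85 mV, k = 8 mV, τh = 50 ms.
These give rheobase ≈ 75 pA, max firing ≈ 90 Hz at 500 pA, sag ratio ≈ 1.45
and CV ISI ≈ 0.26 — plausible for the cell class, chosen once, not fitted.

Stimulus families follow the standard characterization protocols: -50 to
+20 pA in 10 pA steps (input resistance), 800 ms depolarizing steps for the
firing curve, and -50 to -250 pA in 50 pA steps (sag/rebound). The firing
protocol uses 13 levels — 25–300 pA in 25 pA steps plus a 500 pA top step —
so the genotype × current factorial has an interaction with
(3−1)(13−1) = 24 degrees of freedom, matching the reported df structure of
this design; the 25 pA spacing at the bottom guarantees a sweep exactly
50 pA above rheobase for single-spike analysis. Sampling defaults: 50 kHz
for current clamp (third-derivative threshold detection needs dense
sampling), 10 kHz for voltage clamp; the acquisition rate of the original
recordings is not stated anywhere, so these are package choices.

Genotype effects (WT / cHet / cKO) are parameter multipliers chosen to
reproduce reported effect *directions* only — e.g. cKO: leak × 1.75 (lower
Rin), gh × 1.5 (larger rebound), ΔT × 1.5 (broader spikes), threshold × 1.05
(more excitable), sEPSC amplitude × 1.4. They are illustrative and
documented as such; nothing in the package fits them to data.

## Intrinsic feature extraction

All windows are config keys with these defaults, each ≫ the membrane time
constant where relevant; none is specified by the protocols the package
emulates, so they are package choices:

- RMP: mean of the pre-stimulus baseline (≥ 100 ms).
- Input resistance: OLS slope of steady-state ΔV (mean over the last 20%
  of the step, minus baseline) against injected current, × 1000 → MΩ;
  spike-containing sweeps are excluded from the fit; ≥ 3 usable sweeps
  required.
- Spike detection: upward crossing of 0 mV; peak = local maximum before
  the next downward crossing; 1 ms merge window.
- Firing: per-sweep spike count during the step; frequency = count/0.8 s;
  rheobase = smallest amplitude with ≥ 1 spike (missing, not an error,
  when nothing spikes).
- AP shape (first spike of the rheobase + 50 pA sweep): voltage smoothed
  with a 0.1 ms centered moving average (third differences amplify noise),
  d³V/dt³ by three successive central differences, threshold = smoothed V
  at the d³V/dt³ maximum within 2 ms before the peak; amplitude =
  peak − threshold; half-width at threshold + amplitude/2 with linear
  interpolation between samples.
- CV ISI: population (divisor-n) SD over mean of successive peak-time
  differences, on the rheobase + 50 pA sweep; ≥ 4 spikes required.
- Sag: deflections are positive magnitudes relative to baseline; ratio =
  peak deflection / steady-state deflection, reported per sweep and
  summarized at the largest step; ≥ 1 by construction for this model
  family (the membrane relaxes monotonically without HCN).
- Rebound slope: OLS slope of rebound amplitude (max V in the 200 ms after
  step offset, minus baseline) against steady-state voltage.

## sEPSC generator and detector

The generator plants a homogeneous Poisson process of biexponential inward
events, A·(e^(−t/τd) − e^(−t/τr)) normalized to unit peak (defaults
A = 20 pA, τr = 1 ms, τd = 10 ms, 5-min-style traces at −70 mV emulated as
30 s segments in the pipeline), with Gaussian current noise (default 4 pA →
SNR 5) and optional lognormal amplitude scatter. Planted onsets and
amplitudes are returned for oracle tests.

The detector is a transparent replacement for proprietary event detection:
running-median baseline (500 ms window; exactly removes any holding
offset), 1 kHz zero-phase Butterworth low-pass, robust noise SD from the
MAD × 1.4826, and event peaks as local maxima of the inward deviation with
height *and* topographic prominence ≥ k·SD (k = 4), width ≥ 1 ms at half
prominence, and ≥ 5 ms separation. The onset is the last threshold crossing
before the peak; amplitude is the mean deviation in a ±0.5 ms window around
the peak minus the median local baseline just before onset (averaging
instead of taking the extremum is what keeps the amplitude bias ≈ +3% at
SNR 5, below 5%; the local baseline measures overlapping events from the
tail of their predecessor, without deconvolution). Half-width is measured
between the 50%-amplitude crossings, AUC by trapezoidal integration from
onset to return-to-baseline or a 100 ms cap; truncated events are flagged
and excluded from kinetics summaries.

Known limitation (measured, and deliberately not patched): two events
closer than ≈ 4.5 ms produce a single local maximum in the 1 kHz-filtered
trace, and the leading peak of pairs 5–8 ms apart has prominence below the
4-SD noise floor at SNR 5, so such pairs count once. At 10 Hz this loses
≈ 8% of events and pushes detected counts below the Poisson 95% band in
many replicates; below ≈ 5 Hz frequency recovery is essentially exact.
Resolving closer pairs requires template deconvolution, which is outside
this package's scope. Absolute frequencies are therefore comparable only
within a fixed detector configuration.

## Puncta stacks and colocalization

The stack generator renders each punctum as a Gaussian blob (in-plane
σ = radius/2; default radius 0.3 µm, 0.1 µm pixels, 0.25 µm z-step) into a
two-channel volume with constant background and optional Gaussian noise.
The axial profile is confined to one focal plane (σ = 0.2 planes) so that
per-plane counting — the convention the analysis follows — has a
one-to-one correspondence with planted truth.

Analysis: per-plane rolling-ball-style background subtraction (grey opening
with a 1 µm disk, clipped at 0); puncta by thresholding at plane
mean + 3·SD (scale-invariant) with 8-connected components filtered to
0.05–3 µm² and intensity-weighted centroids. A channel-wide floor (3D
channel mean + 3·SD) guards the per-plane threshold: on a near-empty plane
of a low-noise stack the plane's own statistics are arbitrarily small and
would otherwise detect numerically negligible structure. A synapse is a
pre/post pair with centroid distance ≤ 0.5 µm in the same focal plane,
matched greedily by ascending distance, one-to-one; greedy matching was
chosen over assignment optimization for testability — on scenes of ≤ 10
well-separated puncta it equals the exhaustive maximum matching, which the
tests verify (crafted near-degenerate geometries can make greedy drop a
pair; planted scenes do not produce them). Counts are summed across planes,
then normalized: soma density per µm of polygon circumference (sum of edge
lengths; area by the shoelace formula), dendrite density per µm of polyline
length. Compartment assignment uses the presynaptic centroid, inside the
soma polygon or within a 1 µm band of either ROI; a synapse matching both
goes to the nearer boundary, ties to the soma. Punctum "size" is the
in-plane component area; coordinates are microns at pixel centers, 0-based.

## Cell counts and developmental trajectories

Boxes and laminar bins are half-open [lo, hi), making boundary assignment
deterministic and counts exactly additive under splitting; a boundary cell
belongs to the deeper bin. Densities are counts divided by box area in mm².
Co-label fractions (|a∧b|/|a|) are computed per animal — the animal, not
the section, is the statistical unit, and sections average within animal
first. "Every 5th section" sampling is a section-id filter, with no
stereological correction.

The cohort generator draws per-animal densities from Normal(trajectory
mean, SD 20 cells/mm²; truncated at 0 by redraw) and apoptosis-marker
co-label counts from Binomial(3000 cells, rate). Default trajectories rise
to a plateau between P7 and P15 and then decline through P35 in WT/cHet
(170 → 110 → 85 cells/mm²) while staying flat in cKO, with co-label rates
0.002 (WT/cHet) vs 0.0008 (cKO) — free generator parameters emulating the
qualitative developmental pattern, not measured values.

`trajectory_contrast` reports group means ± SEM, per-age one-way ANOVA with
Tukey pairs, and within-genotype age-to-age changes. An age is flagged
divergent when the omnibus ANOVA survives a Bonferroni correction across
the ages tested *and* at least one Tukey pair is below α: without the
cross-age correction, testing six ages at α = 0.05 would flag ~26% of null
cohorts, which no useful screen should do. With the default trajectories
and n = 8 animals/group the earliest flagged age is P25, with power ≈ 0.9
when the planted P25 effect is 2 pooled SD.

## Statistics

The protocol is Shapiro–Wilk per group and Levene (center = mean) across
groups at α = 0.05 (groups with n < 3 or zero variance are flagged
untestable, not failed), one-way ANOVA with Tukey's post-test for all group
comparisons, and a two-way fixed-effects ANOVA with interaction for the
genotype × current firing curves. The one-way F is assembled from the
explicit SS decomposition and Tukey–Kramer p-values from the
studentized-range distribution (scipy supplies the distributions; scipy's
own `f_oneway` and `tukey_hsd` serve as independent cross-checks in the
tests, not as the implementation). Identical groups report F = 0, p = 1;
zero within-group variance with distinct means reports F = ∞, p = 0. The
two-way table comes from a statsmodels OLS fit (type-II SS); treating every
observation as independent ignores the repeated-measures structure of
per-cell current series — a documented simplification matching the df
structure this design reports. No multiplicity correction is applied beyond
Tukey (and the Bonferroni across ages inside the trajectory screen).

Calibration is verified by simulation: the one-way type-I error rate over
10 000 null datasets falls in [0.045, 0.055], and the planted-interaction
power of the two-way design matches its noncentral-F closed form.

## What the synthetic tests do and do not show

The generators emulate the *structure* of the study's data — stimulus
families, Poisson synaptic bombardment, diffraction-limited puncta,
per-animal cohort tables — with known truth, so the tests establish that
the measurement code is correct: features match closed forms and
brute-force oracles, detectors recover planted events and objects, and the
statistics are calibrated. They do not establish anything about real
recordings: real cells have channel noise, electrode drift and
series-resistance artifacts; real sEPSCs have heterogeneous kinetics; real
confocal stacks have axially elongated PSFs, misalignment and uneven
background; and the genotype effect sizes here are illustrative parameter
multipliers. Absolute numbers produced by the pipeline (frequencies,
densities, thresholds) depend on the stated configuration defaults and are
comparable only within a fixed configuration.

## Problem sizes used by the validation suite

The acceptance benchmarks use 30 s sEPSC traces (100 seeds for
recall/bias; 25 replicates per rate at 0.5–10 Hz for frequency coverage),
a 20-cell passive grid for Rin recovery, 100 cohort replicates at
8 animals/group for divergence power, 10 000 null datasets for type-I
calibration, and a 500 kHz dense-grid simulation as the AP-threshold
oracle. These sizes were chosen so the whole validation runs in minutes on
one CPU while keeping Monte-Carlo error well below each criterion's margin.
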