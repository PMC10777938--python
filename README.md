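# vipcinq

Quantification pipeline for studies of VIP+ (vasoactive intestinal
peptide-expressing) cortical interneurons — the disinhibitory, CGE-derived
interneuron class — under genetic perturbations such as conditional *Tsc1*
deletion, which hyperactivates mTOR signaling. Such studies rest on four
quantitative pillars, all of which this package implements as tested,
reusable code:

1. **Intrinsic electrophysiology** from whole-cell current-clamp step
   families: resting membrane potential, input resistance
   (R_in, the OLS slope of the steady-state V–I relation), rheobase, firing
   curves and maximum firing frequency, single-AP threshold (the voltage at
   the maximum of d³V/dt³), amplitude and half-width, the coefficient of
   variation of inter-spike intervals (CV ISI = σ_ISI/μ_ISI), and the
   HCN-channel signatures — sag ratio (peak over steady-state deflection)
   and rebound slope.
2. **Spontaneous EPSCs** from voltage-clamp traces at −70 mV: event
   detection with a transparent threshold/prominence detector, per-event
   amplitude, half-width and area under the curve, and per-cell frequency.
3. **Synaptic puncta** in two-channel confocal z-stacks (e.g.
   vGlut1/PSD95): background subtraction, per-plane puncta detection,
   pre/post colocalization (centroid distance ≤ 0.5 µm), and densities
   normalized to soma circumference or dendrite length.
4. **Developmental cell counting**: densities in half-open counting boxes,
   laminar distributions, per-animal apoptosis-marker co-label fractions,
   and trajectory contrasts that flag the earliest age at which genotypes
   diverge.

Group comparisons follow the field's standard protocol — Shapiro–Wilk and
Levene checks, one-way ANOVA with Tukey's post-test, and a two-way
genotype × current ANOVA with interaction for firing curves.

Because raw recordings and images for such studies are typically
unavailable, the package includes first-class synthetic generators with
known ground truth for every stage: an adaptive exponential
integrate-and-fire neuron with an H-current (sag, rebound, adapting trains),
Poisson biexponential sEPSC traces, planted two-channel puncta stacks, and
per-animal developmental cohorts. Every measurement path is validated
against closed forms, brute-force oracles, or the planted truth — see
`docs/methods.md` for the models, defaults and known limitations.

## Worked example

Run the full synthetic study (simulate → features → stats → report) with
the default three-genotype design, four cells per genotype and eight
animals per cohort group:

```bash
vipcinq run --out out/
```

`out/report.md` then contains, per feature, group means ± SEM and the
ANOVA p-value. With the default seed (0) the intrinsic section reads, in
part:

```
- rin_mohm — WT: 201.111 ± 11.380; cHet: 213.463 ± 3.059; cKO: 110.609 ± 2.704 (ANOVA p = 4.553e-06)
- max_firing_frequency_hz — WT: 94.062 ± 4.158; cHet: 115.000 ± 5.751; cKO: 147.500 ± 4.868 (ANOVA p = 0.0001136)
- ap_half_width_ms — WT: 0.268 ± 0.001; cHet: 0.330 ± 0.000; cKO: 0.409 ± 0.000 (ANOVA p = 2.182e-17)
- mean_amplitude_pa — WT: 19.747 ± 0.624; cHet: 22.468 ± 0.665; cKO: 28.425 ± 0.674 (ANOVA p = 1.898e-05)

Two-way ANOVA genotype x current interaction: F(24, 117) = 17.191, p = 5.862e-28
Earliest developmental divergence between genotypes: P25
```

Read: the simulated *Tsc1*-null (cKO) cells have roughly half the input
resistance of wildtype (110.6 vs 201.1 MΩ), fire faster (147.5 vs 94.1 Hz),
have broader spikes (0.409 vs 0.268 ms) and receive larger sEPSCs (28.4 vs
19.7 pA), while the cohort stage flags P25 as the first age at which cell
densities diverge — the qualitative effect structure the generator's
genotype multipliers encode (illustrative directions, not fitted effect
sizes). The two-way interaction df of 24 reflects the 3-genotype ×
13-current-level factorial design. Alongside the report the run writes
`features.csv` (one row per cell), `epsc_summary.csv`, `cohort.csv`,
`anova.json` and a reproducibility manifest; re-running with the same seed
reproduces every output byte-identically.

Individual stages are available as subcommands (`vipcinq simulate
ephys|epsc|stack|cohort`, `vipcinq features intrinsic|epsc`, `vipcinq
puncta`, `vipcinq counts density|laminar|colabel|trajectory`, `vipcinq
stats anova`) and as plain library functions (`vipcinq.intrinsic`,
`vipcinq.epsc`, `vipcinq.puncta`, `vipcinq.counts`, `vipcinq.stats`,
`vipcinq.synth`).

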