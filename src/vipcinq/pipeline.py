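"""End-to-end synthetic study: simulate -> features -> stats -> report.

Mirrors the analysis flow of the source experiments: per-genotype cohorts of
simulated VIP+ interneurons are characterized (intrinsic features, sEPSCs),
a developmental cohort is generated and its trajectory contrasted, and every
feature is compared across genotypes with the one-way ANOVA + Tukey
protocol, plus the two-way genotype x current ANOVA on the firing curves.
All randomness derives from the single config seed; re-running with the same
config and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .counts import trajectory_contrast
from .epsc import EpscDetectionConfig, detect_events, summarize_epsc
from .intrinsic import FEATURE_COLUMNS, extract_features
from .io import write_cohort
from .stats import one_way_anova_tukey, two_way_anova
from .synth import (
    BiexpKernel,
    CohortSpec,
    DEFAULT_COLABEL_RATES,
    DEFAULT_TRAJECTORIES,
    simulate_cohort,
    simulate_epsc_trace,
    simulate_family,
)
from .synth.protocols import firing_protocol, rin_protocol, sag_protocol

EPSC_SUMMARY_COLUMNS = ["frequency_hz", "mean_amplitude_pa", "mean_half_width_ms", "mean_auc_pa_ms"]

_JITTERED_PARAMS = (
    "capacitance",
    "leak_conductance",
    "h_current_max_conductance",
    "adaptation_increment",
)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _jitter_params(params, cv: float, rng: np.random.Generator):
    if cv <= 0:
        return params
    sigma = np.sqrt(np.log(1.0 + cv**2))
    updates = {
        name: getattr(params, name) * rng.lognormal(-0.5 * sigma**2, sigma)
        for name in _JITTERED_PARAMS
    }
    return replace(params, **updates)


def _simulate_cell(params, rate_khz: float, ss: np.random.SeedSequence):
    kids = ss.spawn(3)
    fams = [
        simulate_family(params, rin_protocol(), rate_khz, kids[0]),
        simulate_family(params, firing_protocol(), rate_khz, kids[1]),
        simulate_family(params, sag_protocol(), rate_khz, kids[2]),
    ]
    return fams


def run_pipeline(config: PipelineConfig, outdir: str | Path, seed: int | None = None) -> dict:
    """Run every stage and write outputs + a run manifest under ``outdir``.

    Returns the manifest dict.  Raises :class:`PipelineError` naming the
    failing stage (e.g. the stats stage with fewer than two genotypes).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = config.seed if seed is None else seed
    root = np.random.SeedSequence(seed)
    ss_ephys, ss_epsc, ss_cohort = root.spawn(3)
    effects = config.effects()
    files: dict[str, list[str]] = {}

    # --- stage: ephys (intrinsic features per simulated cell) -------------
    try:
        rows = []
        firing_long = []
        base = config.ephys.neuron.to_params()
        cell_seeds = ss_ephys.spawn(len(config.genotypes))
        for g, g_ss in zip(config.genotypes, cell_seeds):
            per_cell = g_ss.spawn(config.ephys.n_cells_per_genotype)
            for i, c_ss in enumerate(per_cell):
                jit_rng = np.random.default_rng(c_ss.spawn(1)[0])
                params = effects[g].apply_to_params(
                    _jitter_params(base, config.ephys.cell_param_cv, jit_rng)
                )
                fams = _simulate_cell(params, config.ephys.sampling_rate_khz, c_ss)
                fs = extract_features(fams)
                row = {"genotype": g, "cell_id": f"{g}_{i:02d}", **fs.to_dict()}
                rows.append(row)
                for amp, count in fs.firing_curve:
                    firing_long.append(
                        {"genotype": g, "current_pa": amp, "spike_count": count}
                    )
        features = pd.DataFrame(rows)
        features.to_csv(outdir / "features.csv", index=False)
        firing_df = pd.DataFrame(firing_long)
        firing_df.to_csv(outdir / "firing_curves.csv", index=False)
        files["ephys"] = ["features.csv", "firing_curves.csv"]
    except PipelineError:
        raise
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineError("ephys", str(e)) from e

    # --- stage: epsc ------------------------------------------------------
    try:
        epsc_rows = []
        det_cfg = EpscDetectionConfig(threshold_sds=config.epsc.threshold_sds)
        g_seeds = ss_epsc.spawn(len(config.genotypes))
        for g, g_ss in zip(config.genotypes, g_seeds):
            amp = config.epsc.amplitude_pa * effects[g].factor("epsc_amplitude")
            kernel = BiexpKernel(amp, config.epsc.rise_tau_ms, config.epsc.decay_tau_ms)
            for i, c_ss in enumerate(g_ss.spawn(config.ephys.n_cells_per_genotype)):
                trace, _truth = simulate_epsc_trace(
                    config.epsc.rate_hz,
                    kernel,
                    config.epsc.duration_s,
                    config.epsc.noise_sd_pa,
                    c_ss,
                    config.epsc.sampling_rate_khz,
                    amplitude_cv=config.epsc.amplitude_cv,
                )
                det = detect_events(trace, config.epsc.sampling_rate_khz, det_cfg)
                epsc_rows.append(
                    {"genotype": g, "cell_id": f"{g}_{i:02d}", **summarize_epsc(det)}
                )
        epsc_df = pd.DataFrame(epsc_rows)
        epsc_df.to_csv(outdir / "epsc_summary.csv", index=False)
        files["epsc"] = ["epsc_summary.csv"]
    except Exception as e:  # noqa: BLE001
        raise PipelineError("epsc", str(e)) from e

    # --- stage: cohort ----------------------------------------------------
    try:
        spec = CohortSpec(
            genotypes=tuple(config.genotypes),
            n_animals=config.cohort.n_animals,
            density_sd=config.cohort.density_sd,
            cells_per_animal=config.cohort.cells_per_animal,
            trajectories={
                g: dict(DEFAULT_TRAJECTORIES.get(g, DEFAULT_TRAJECTORIES["WT"]))
                for g in config.genotypes
            },
            colabel_rates={
                g: DEFAULT_COLABEL_RATES.get(g, DEFAULT_COLABEL_RATES["WT"])
                for g in config.genotypes
            },
        )
        cohort = simulate_cohort(spec, ss_cohort)
        write_cohort(cohort, outdir / "cohort.csv")
        files["cohort"] = ["cohort.csv"]
        trajectory = None
        if len(config.genotypes) >= 2:
            trajectory = trajectory_contrast(cohort, alpha=config.stats.alpha)
            trajectory.group_summary.to_csv(outdir / "cohort_trajectory.csv", index=False)
            files["cohort"].append("cohort_trajectory.csv")
    except Exception as e:  # noqa: BLE001
        raise PipelineError("cohort", str(e)) from e

    # --- stage: stats -----------------------------------------------------
    usable = [
        g for g in config.genotypes if (features["genotype"] == g).sum() >= 2
    ]
    if len(usable) < 2:
        raise PipelineError("stats", "insufficient groups for between-genotype statistics")
    anova_out: dict[str, dict] = {}
    for col_source, cols in ((features, FEATURE_COLUMNS), (epsc_df, EPSC_SUMMARY_COLUMNS)):
        for col in cols:
            groups = {}
            for g in usable:
                vals = col_source.loc[col_source["genotype"] == g, col].dropna().to_numpy()
                if len(vals) >= 2:
                    groups[g] = vals
            if len(groups) < 2:
                continue
            try:
                anova_out[col] = one_way_anova_tukey(groups, config.stats.alpha).to_dict()
            except ValueError:
                continue
    try:
        tw = two_way_anova(firing_df, "spike_count", "genotype", "current_pa")
        anova_out["firing_curve_interaction"] = {
            "F": tw.interaction_f,
            "df_interaction": tw.interaction_df,
            "df_residual": tw.residual_df,
            "p": tw.interaction_p,
        }
    except ValueError:
        pass
    if trajectory is not None:
        anova_out["cohort_earliest_divergence_age"] = {
            "age": trajectory.earliest_divergence_age
        }
    (outdir / "anova.json").write_text(json.dumps(anova_out, indent=1, default=float))
    files["stats"] = ["anova.json"]

    # --- stage: report ----------------------------------------------------
    lines = ["# Synthetic VIP+ interneuron study report", ""]
    lines.append(f"Genotypes: {', '.join(config.genotypes)}; seed {seed}.")
    lines.append("")
    lines.append("## Intrinsic and synaptic features (mean ± sem)")
    lines.append("")
    for source, cols in ((features, FEATURE_COLUMNS), (epsc_df, EPSC_SUMMARY_COLUMNS)):
        for col in cols:
            parts = []
            for g in config.genotypes:
                vals = source.loc[source["genotype"] == g, col].dropna()
                if len(vals) == 0:
                    parts.append(f"{g}: n/a")
                else:
                    sem = vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else 0.0
                    parts.append(f"{g}: {vals.mean():.3f} ± {sem:.3f}")
            p = anova_out.get(col, {}).get("p")
            suffix = f" (ANOVA p = {p:.4g})" if p is not None else ""
            lines.append(f"- **{col}** — " + "; ".join(parts) + suffix)
    if "firing_curve_interaction" in anova_out:
        tw_d = anova_out["firing_curve_interaction"]
        lines.append("")
        lines.append(
            f"Two-way ANOVA genotype x current interaction: "
            f"F({tw_d['df_interaction']}, {tw_d['df_residual']}) = {tw_d['F']:.3f}, "
            f"p = {tw_d['p']:.4g}"
        )
    if trajectory is not None:
        lines.append("")
        lines.append(
            "Earliest developmental divergence between genotypes: "
            f"P{trajectory.earliest_divergence_age}"
            if trajectory.earliest_divergence_age is not None
            else "No developmental divergence detected."
        )
    (outdir / "report.md").write_text("\n".join(lines) + "\n")
    files["report"] = ["report.md"]

    manifest = {
        "config_hash": hashlib.sha256(
            config.model_dump_json().encode()
        ).hexdigest(),
        "seed": seed,
        "version": __version__,
        "stages": files,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
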