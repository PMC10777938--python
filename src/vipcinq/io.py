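"""File formats: sweep CSV + stimulus sidecar JSON, stack TIFF + sidecar,
cohort and cell tables as CSV.

Sweep families are interchange-format agnostic of acquisition hardware: a
CSV whose first column is time in ms and remaining columns are sweeps (unit
suffix in the header, ``_mV`` for current clamp, ``_pA`` for voltage clamp),
plus a sidecar JSON carrying the per-sweep stimulus descriptors and the
clamp mode.  Values written with full precision round-trip bit-identically.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .puncta import PunctaStack
from .synth.neuron import StimulusDescriptor, SweepFamily

COHORT_COLUMNS = [
    "animal_id",
    "genotype",
    "age",
    "density_per_mm2",
    "cells_counted",
    "colabel_count",
]

CELL_COLUMNS = ["animal_id", "section_id", "x_um", "y_um", "markers"]


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_sweeps(family: SweepFamily, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    csv_path = Path(csv_path)
    json_path = Path(json_path) if json_path else _sidecar_path(csv_path)
    unit = "mV" if family.clamp_mode == "current" else "pA"
    data = {"time_ms": family.time_ms}
    for k, (_, trace) in enumerate(family.sweeps):
        data[f"sweep_{k:03d}_{unit}"] = trace
    # %.17g guarantees float64 round-trips bit-identically through text
    pd.DataFrame(data).to_csv(csv_path, index=False, float_format="%.17g")
    sidecar = {
        "clamp_mode": family.clamp_mode,
        "sampling_rate_khz": family.sampling_rate_khz,
        "sweep_length_ms": family.sweep_length_ms,
        "stimuli": [
            {
                "amplitude_pa": s.amplitude,
                "onset_ms": s.onset,
                "duration_ms": s.duration,
                "baseline_current_pa": s.baseline_current,
            }
            for s, _ in family.sweeps
        ],
    }
    json_path.write_text(json.dumps(sidecar, indent=1))


def read_sweeps(csv_path: str | Path, json_path: str | Path | None = None) -> SweepFamily:
    """Read a sweep family; validates sidecar agreement and units.

    Columns whose unit suffix is ``_V`` (or ``_nA``) are rescaled to mV (pA)
    with a warning.  Ragged columns (missing values) and a sweep-count
    mismatch with the sidecar raise parse errors naming the problem.
    """
    csv_path = Path(csv_path)
    json_path = Path(json_path) if json_path else _sidecar_path(csv_path)
    if not json_path.exists():
        raise FileNotFoundError(f"missing stimulus sidecar {json_path}")
    sidecar = json.loads(json_path.read_text())
    df = pd.read_csv(csv_path, float_precision="round_trip")
    if df.isna().any().any():
        bad = int(df[df.isna().any(axis=1)].index[0]) + 2  # header + 1-based
        raise ValueError(f"ragged/missing values in {csv_path} at line {bad}")
    sweep_cols = [c for c in df.columns if c != "time_ms"]
    stimuli = sidecar["stimuli"]
    if len(sweep_cols) != len(stimuli):
        raise ValueError(
            f"{csv_path} has {len(sweep_cols)} sweep columns but sidecar lists "
            f"{len(stimuli)} stimuli"
        )
    clamp_mode = sidecar["clamp_mode"]
    expected_unit = "mV" if clamp_mode == "current" else "pA"
    sweeps = []
    for col, s in zip(sweep_cols, stimuli):
        unit = col.rsplit("_", 1)[-1]
        values = df[col].to_numpy(dtype=np.float64)
        if unit != expected_unit:
            if (unit, expected_unit) in {("V", "mV"), ("nA", "pA")}:
                warnings.warn(f"column {col}: converting {unit} to {expected_unit} (x1000)")
                values = values * 1000.0
            else:
                raise ValueError(
                    f"column {col}: unit {unit!r} incompatible with clamp mode {clamp_mode!r}"
                )
        stim = StimulusDescriptor(
            amplitude=s["amplitude_pa"],
            onset=s["onset_ms"],
            duration=s["duration_ms"],
            baseline_current=s.get("baseline_current_pa", 0.0),
        )
        sweeps.append((stim, values))
    return SweepFamily(
        sampling_rate_khz=sidecar["sampling_rate_khz"],
        sweep_length_ms=sidecar["sweep_length_ms"],
        sweeps=sweeps,
        clamp_mode=clamp_mode,
    )


def write_stack(stack: PunctaStack, tiff_path: str | Path, json_path: str | Path | None = None) -> None:
    """Write a two-channel stack as multi-page TIFF, z-major then channel.

    Page order: for each z-plane, the presynaptic then postsynaptic page.
    Pixel geometry and channel roles go to the sidecar JSON.
    """
    tiff_path = Path(tiff_path)
    json_path = Path(json_path) if json_path else tiff_path.with_suffix(".json")
    pages = [
        stack.data[c, z]
        for z in range(stack.n_planes)
        for c in range(2)
    ]
    tifffile.imwrite(tiff_path, np.stack(pages))
    json_path.write_text(
        json.dumps(
            {
                "pixel_size_um": stack.pixel_size_um,
                "z_step_um": stack.z_step_um,
                "channel_roles": list(stack.channel_roles),
                "n_planes": stack.n_planes,
            },
            indent=1,
        )
    )


def read_stack(tiff_path: str | Path, json_path: str | Path | None = None) -> PunctaStack:
    tiff_path = Path(tiff_path)
    json_path = Path(json_path) if json_path else tiff_path.with_suffix(".json")
    if not json_path.exists():
        raise FileNotFoundError(f"missing stack sidecar {json_path}")
    meta = json.loads(json_path.read_text())
    pages = tifffile.imread(tiff_path)
    nz = meta["n_planes"]
    if pages.shape[0] != 2 * nz:
        raise ValueError(f"expected {2 * nz} pages, found {pages.shape[0]}")
    data = np.empty((2, nz, pages.shape[1], pages.shape[2]), dtype=np.float64)
    for z in range(nz):
        for c in range(2):
            data[c, z] = pages[2 * z + c]
    return PunctaStack(
        data,
        meta["pixel_size_um"],
        meta["z_step_um"],
        tuple(meta["channel_roles"]),
    )


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    cohort[COHORT_COLUMNS].to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns {missing}")
    if (df["density_per_mm2"] < 0).any():
        raise ValueError("negative densities in cohort table")
    if (df["colabel_count"] > df["cells_counted"]).any():
        raise ValueError("colabel_count exceeds cells_counted")
    return df


def read_cells(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CELL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table missing columns {missing}")
    if not np.isfinite(df[["x_um", "y_um"]].to_numpy()).all():
        raise ValueError("non-finite cell coordinates")
    return df


def write_cells(cells: pd.DataFrame, path: str | Path) -> None:
    cells[CELL_COLUMNS].to_csv(path, index=False)
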