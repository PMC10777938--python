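"""Synthetic two-channel puncta stacks with planted ground truth.

Each punctum is rendered as a 3D Gaussian blob (in-plane sigma = radius/2)
into the presynaptic or postsynaptic channel.  The axial profile is kept
narrow (default sigma 0.2 planes) so each planted punctum crosses the
detection threshold in exactly one focal plane: downstream counting is
per-plane, and a one-to-one correspondence between planted and countable
objects is what makes recall/precision oracles exact.  Planted pre/post
pairs are the ground-truth synapses; singletons exercise the
non-colocalized background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..puncta import PunctaStack


@dataclass(frozen=True)
class PlantedPunctum:
    x_um: float
    y_um: float
    plane: int
    radius_um: float = 0.3
    intensity: float = 200.0

    def __post_init__(self) -> None:
        if self.radius_um <= 0:
            raise ValueError("punctum radius must be > 0")


@dataclass(frozen=True)
class PlantedPair:
    pre: PlantedPunctum
    post: PlantedPunctum


@dataclass
class SynthStackSpec:
    """Specification of a synthetic stack; default z-step 0.25 um."""

    shape_xyz: tuple[int, int, int] = (128, 128, 8)
    pixel_size_um: float = 0.1
    z_step_um: float = 0.25
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    planted_singletons: dict[int, list[PlantedPunctum]] = field(default_factory=dict)
    background_level: float = 10.0
    noise_sd: float = 0.0
    axial_sigma_planes: float = 0.2
    soma_polygon: tuple[tuple[float, float], ...] | None = None
    dendrite_polyline: tuple[tuple[float, float], ...] | None = None

    def all_puncta(self) -> list[tuple[int, PlantedPunctum]]:
        out = [(0, p.pre) for p in self.planted_pairs]
        out += [(1, p.post) for p in self.planted_pairs]
        for ch, lst in self.planted_singletons.items():
            out += [(ch, p) for p in lst]
        return out


def _render_blob(
    volume: np.ndarray, p: PlantedPunctum, pixel_size: float, sigma_z: float
) -> None:
    nz, ny, nx = volume.shape
    sigma_px = (p.radius_um / 2.0) / pixel_size
    cx = p.x_um / pixel_size
    cy = p.y_um / pixel_size
    half = int(np.ceil(4 * sigma_px)) + 1
    half_z = int(np.ceil(4 * sigma_z)) + 1
    x0, x1 = max(0, int(cx) - half), min(nx, int(cx) + half + 1)
    y0, y1 = max(0, int(cy) - half), min(ny, int(cy) + half + 1)
    z0, z1 = max(0, p.plane - half_z), min(nz, p.plane + half_z + 1)
    zz, yy, xx = np.meshgrid(
        np.arange(z0, z1), np.arange(y0, y1), np.arange(x0, x1), indexing="ij"
    )
    g = p.intensity * np.exp(
        -(
            (xx - cx) ** 2 / (2 * sigma_px**2)
            + (yy - cy) ** 2 / (2 * sigma_px**2)
            + (zz - p.plane) ** 2 / (2 * max(sigma_z, 1e-6) ** 2)
        )
    )
    volume[z0:z1, y0:y1, x0:x1] += g


def simulate_stack(
    spec: SynthStackSpec,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> tuple[PunctaStack, SynthStackSpec]:
    """Render the specified scene; returns the stack and the spec as truth.

    Raises if any planted punctum lies outside the volume, listing the
    offending index.
    """
    nx, ny, nz = spec.shape_xyz
    bad = [
        i
        for i, (_, p) in enumerate(spec.all_puncta())
        if not (
            0 <= p.x_um <= (nx - 1) * spec.pixel_size_um
            and 0 <= p.y_um <= (ny - 1) * spec.pixel_size_um
            and 0 <= p.plane < nz
        )
    ]
    if bad:
        raise ValueError(f"planted puncta outside volume at indices {bad}")
    data = np.full((2, nz, ny, nx), float(spec.background_level))
    for ch, p in spec.all_puncta():
        _render_blob(data[ch], p, spec.pixel_size_um, spec.axial_sigma_planes)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(seed)
        data = np.clip(data + rng.normal(0.0, spec.noise_sd, data.shape), 0.0, None)
    stack = PunctaStack(data, spec.pixel_size_um, spec.z_step_um)
    return stack, spec
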