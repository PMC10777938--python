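"""Synaptic puncta counting and pre/post colocalization in two-channel stacks.

A putative synapse is a presynaptic punctum (e.g. vGlut1 or vAChT) whose
centroid lies within ``d_max`` of a postsynaptic punctum (e.g. PSD95 or
nAChRa4) in the same focal plane.  Counts are accumulated across planes and
normalized to the soma circumference or the dendrite length drawn by the
user, exactly as densities are reported per micron of membrane.

Coordinates: pixel indices are 0-based; physical coordinates are microns at
pixel centers (pixel ``i`` center at ``i * pixel_size``).  ROI polygons and
polylines are given in physical microns in the imaging plane.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.ndimage import grey_opening
from scipy.spatial.distance import cdist
from shapely.geometry import LineString, Point, Polygon
from skimage.measure import label, regionprops
from skimage.morphology import disk


@dataclass
class PunctaStack:
    """Two-channel 3D image: ``data`` has shape (2, z, y, x)."""

    data: np.ndarray
    pixel_size_um: float
    z_step_um: float = 0.25
    channel_roles: tuple[str, str] = ("presynaptic", "postsynaptic")

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 4 or self.data.shape[0] != 2:
            raise ValueError("stack data must have shape (2, z, y, x)")
        if self.pixel_size_um <= 0 or self.z_step_um <= 0:
            raise ValueError("pixel_size and z_step must be > 0")

    @property
    def n_planes(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class RoiSet:
    """Soma polygon and dendrite polyline (microns) with an assignment band.

    A synapse whose presynaptic centroid falls inside the soma polygon, or
    within ``band_half_width_um`` of its boundary or of the dendrite
    polyline, is assigned to that compartment.
    """

    soma_polygon: tuple[tuple[float, float], ...]
    dendrite_polyline: tuple[tuple[float, float], ...]
    band_half_width_um: float = 1.0

    def __post_init__(self) -> None:
        if len(self.soma_polygon) < 3:
            raise ValueError("soma polygon needs >= 3 vertices")
        if len(self.dendrite_polyline) < 2:
            raise ValueError("dendrite polyline needs >= 2 vertices")
        if not Polygon(self.soma_polygon).is_valid:
            raise ValueError("soma polygon is self-intersecting")


@dataclass(frozen=True)
class Punctum:
    """One fluorescent spot in one focal plane."""

    x_um: float
    y_um: float
    plane: int
    area_um2: float
    peak_intensity: float

    def __post_init__(self) -> None:
        if self.area_um2 <= 0:
            raise ValueError("punctum area must be > 0")


@dataclass(frozen=True)
class SynapseSite:
    pre: Punctum
    post: Punctum
    distance_um: float
    plane: int


@dataclass
class SynapseDensityReport:
    soma_count: int
    soma_circumference_um: float
    soma_area_um2: float
    dendrite_count: int
    dendrite_length_um: float
    mean_punctum_area_um2: dict[str, float] = field(default_factory=dict)

    @property
    def soma_density_per_um(self) -> float:
        return self.soma_count / self.soma_circumference_um

    @property
    def dendrite_density_per_um(self) -> float:
        return self.dendrite_count / self.dendrite_length_um

    def to_dict(self) -> dict:
        return {
            "soma_count": self.soma_count,
            "soma_circumference_um": self.soma_circumference_um,
            "soma_area_um2": self.soma_area_um2,
            "soma_density_per_um": self.soma_density_per_um,
            "dendrite_count": self.dendrite_count,
            "dendrite_length_um": self.dendrite_length_um,
            "dendrite_density_per_um": self.dendrite_density_per_um,
            **{
                f"mean_punctum_area_um2_{k}": v
                for k, v in self.mean_punctum_area_um2.items()
            },
        }


def subtract_background(stack: PunctaStack, radius_um: float = 1.0) -> PunctaStack:
    """Rolling-ball style background subtraction (grey opening) per plane.

    The background of each plane of each channel is its morphological grey
    opening with a disk of the stated radius; the opening is subtracted and
    the result clipped at zero.  A constant plane maps to zeros; an
    already-zero plane is unchanged.
    """
    if radius_um <= 0:
        raise ValueError("background radius must be > 0")
    r_px = max(1, int(round(radius_um / stack.pixel_size_um)))
    footprint = disk(r_px)
    out = np.empty_like(stack.data)
    for c in range(2):
        for z in range(stack.n_planes):
            plane = stack.data[c, z]
            bg = grey_opening(plane, footprint=footprint)
            out[c, z] = np.clip(plane - bg, 0.0, None)
    return PunctaStack(out, stack.pixel_size_um, stack.z_step_um, stack.channel_roles)


def detect_puncta(
    plane: np.ndarray,
    pixel_size_um: float,
    plane_index: int = 0,
    threshold_sds: float = 3.0,
    min_area_um2: float = 0.05,
    max_area_um2: float = 3.0,
    floor: float | None = None,
) -> list[Punctum]:
    """Threshold + connected components puncta detection in one plane.

    The threshold is ``mean + threshold_sds * sd`` of the plane, which makes
    counts invariant under global intensity scaling.  8-connected components
    with in-plane area inside the stated bounds become puncta; centroids are
    intensity-weighted.  A degenerate (constant) plane yields no puncta.

    ``floor`` is an optional absolute peak-intensity requirement; stack-level
    callers pass a channel-wide statistic (itself scale-covariant) so that
    near-empty planes, whose adaptive threshold is arbitrarily low, do not
    produce spurious detections.
    """
    plane = np.asarray(plane, dtype=np.float64)
    sd = plane.std()
    if sd == 0:
        return []
    thr = plane.mean() + threshold_sds * sd
    if floor is not None:
        thr = max(thr, floor)
    mask = plane > thr
    labels = label(mask, connectivity=2)
    px_area = pixel_size_um**2
    out: list[Punctum] = []
    for rp in regionprops(labels, intensity_image=plane):
        area = rp.area * px_area
        if not (min_area_um2 <= area <= max_area_um2):
            continue
        cy, cx = rp.centroid_weighted
        out.append(
            Punctum(
                x_um=cx * pixel_size_um,
                y_um=cy * pixel_size_um,
                plane=plane_index,
                area_um2=area,
                peak_intensity=float(rp.intensity_max),
            )
        )
    return out


def colocalize(
    pre: Sequence[Punctum],
    post: Sequence[Punctum],
    d_max_um: float = 0.5,
) -> list[SynapseSite]:
    """Greedy one-to-one pre/post matching by ascending centroid distance.

    Both lists must come from the same focal plane.  Pairs with centroid
    distance <= ``d_max_um`` are matched in ascending-distance order, each
    punctum used at most once; the procedure is symmetric in the two
    channels.
    """
    if not pre or not post:
        return []
    planes = {p.plane for p in pre} | {p.plane for p in post}
    if len(planes) > 1:
        raise ValueError("colocalize operates within a single focal plane")
    a = np.array([[p.x_um, p.y_um] for p in pre])
    b = np.array([[p.x_um, p.y_um] for p in post])
    d = cdist(a, b)
    order = np.argsort(d, axis=None, kind="stable")
    used_pre: set[int] = set()
    used_post: set[int] = set()
    sites: list[SynapseSite] = []
    for flat in order:
        i, j = divmod(int(flat), d.shape[1])
        if d[i, j] > d_max_um:
            break
        if i in used_pre or j in used_post:
            continue
        used_pre.add(i)
        used_post.add(j)
        sites.append(SynapseSite(pre[i], post[j], float(d[i, j]), pre[i].plane))
    return sites


def soma_geometry(polygon: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Circumference (sum of edge lengths) and shoelace area of a polygon.

    Accepts vertices in either orientation; the closing edge is implied.
    Raises on fewer than 3 vertices or a self-intersecting outline.
    """
    if len(polygon) < 3:
        raise ValueError("polygon needs >= 3 vertices")
    if not Polygon(polygon).is_valid:
        raise ValueError("polygon is self-intersecting")
    pts = np.asarray(polygon, dtype=np.float64)
    closed = np.vstack([pts, pts[:1]])
    circumference = float(np.sum(np.linalg.norm(np.diff(closed, axis=0), axis=1)))
    x, y = pts[:, 0], pts[:, 1]
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    return circumference, area


def dendrite_length(polyline: Sequence[tuple[float, float]]) -> float:
    """Sum of Euclidean segment lengths of the drawn dendrite polyline."""
    if len(polyline) < 2:
        raise ValueError("polyline needs >= 2 vertices")
    pts = np.asarray(polyline, dtype=np.float64)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def assign_and_normalize(
    synapses: Sequence[SynapseSite],
    rois: RoiSet,
    puncta_by_channel: dict[str, Sequence[Punctum]] | None = None,
) -> SynapseDensityReport:
    """Assign synapses to soma vs dendrite compartments and normalize.

    A synapse belongs to the soma if its presynaptic centroid is inside the
    soma polygon or within the assignment band of its boundary; to the
    dendrite if within the band of the polyline.  A synapse matching both is
    assigned to the nearer boundary, with ties going to the soma.  Counts are
    summed across focal planes before normalizing, so densities times
    lengths reproduce the integer counts exactly.
    """
    poly = Polygon(rois.soma_polygon)
    line = LineString(rois.dendrite_polyline)
    band = rois.band_half_width_um
    soma_count = 0
    dendrite_count = 0
    for s in synapses:
        p = Point(s.pre.x_um, s.pre.y_um)
        d_soma = poly.exterior.distance(p)
        in_soma = poly.contains(p) or d_soma <= band
        d_dend = line.distance(p)
        in_dend = d_dend <= band
        if in_soma and in_dend:
            if d_soma <= d_dend:
                soma_count += 1
            else:
                dendrite_count += 1
        elif in_soma:
            soma_count += 1
        elif in_dend:
            dendrite_count += 1
    circumference, area = soma_geometry(rois.soma_polygon)
    length = dendrite_length(rois.dendrite_polyline)
    mean_sizes = {}
    if puncta_by_channel:
        for role, plist in puncta_by_channel.items():
            if len(plist):
                mean_sizes[role] = float(np.mean([p.area_um2 for p in plist]))
    return SynapseDensityReport(
        soma_count=soma_count,
        soma_circumference_um=circumference,
        soma_area_um2=area,
        dendrite_count=dendrite_count,
        dendrite_length_um=length,
        mean_punctum_area_um2=mean_sizes,
    )


def count_stack(
    stack: PunctaStack,
    rois: RoiSet,
    background_radius_um: float = 1.0,
    threshold_sds: float = 3.0,
    min_area_um2: float = 0.05,
    max_area_um2: float = 3.0,
    d_max_um: float = 0.5,
) -> SynapseDensityReport:
    """Full per-cell pipeline: subtract background, detect per plane in both
    channels, colocalize per plane, assign to compartments and normalize."""
    clean = subtract_background(stack, background_radius_um)
    floors = [
        float(clean.data[c].mean() + threshold_sds * clean.data[c].std())
        for c in range(2)
    ]
    pre_all: list[Punctum] = []
    post_all: list[Punctum] = []
    sites: list[SynapseSite] = []
    for z in range(clean.n_planes):
        pre = detect_puncta(
            clean.data[0, z], clean.pixel_size_um, z, threshold_sds,
            min_area_um2, max_area_um2, floor=floors[0],
        )
        post = detect_puncta(
            clean.data[1, z], clean.pixel_size_um, z, threshold_sds,
            min_area_um2, max_area_um2, floor=floors[1],
        )
        pre_all.extend(pre)
        post_all.extend(post)
        sites.extend(colocalize(pre, post, d_max_um))
    return assign_and_normalize(
        sites,
        rois,
        {stack.channel_roles[0]: pre_all, stack.channel_roles[1]: post_all},
    )
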