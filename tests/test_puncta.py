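"""Puncta detection, colocalization and geometry: construction oracles,
exhaustive-matching oracle, end-to-end recall/precision on planted scenes."""

import itertools

import numpy as np
import pytest

from vipcinq.puncta import (
    Punctum,
    RoiSet,
    PunctaStack,
    assign_and_normalize,
    colocalize,
    count_stack,
    dendrite_length,
    detect_puncta,
    soma_geometry,
    subtract_background,
)
from vipcinq.synth import PlantedPair, PlantedPunctum, SynthStackSpec, simulate_stack


def make_plane(blobs, shape=(128, 128), background=0.0, pixel_size=0.1):
    """Render 2D Gaussian blobs (x_um, y_um, intensity) onto a plane."""
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    plane = np.full(shape, background, dtype=float)
    sigma_px = 0.15 / pixel_size
    for x_um, y_um, inten in blobs:
        cx, cy = x_um / pixel_size, y_um / pixel_size
        plane += inten * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma_px**2))
    return plane


def exhaustive_best_matching(pre, post, d_max):
    """Oracle: maximum-cardinality, then minimum-total-distance matching."""
    best = (0, 0.0)
    n = min(len(pre), len(post))
    for k in range(n, 0, -1):
        found = None
        for pre_idx in itertools.combinations(range(len(pre)), k):
            for post_perm in itertools.permutations(range(len(post)), k):
                d = [
                    np.hypot(
                        pre[i].x_um - post[j].x_um, pre[i].y_um - post[j].y_um
                    )
                    for i, j in zip(pre_idx, post_perm)
                ]
                if all(x <= d_max for x in d):
                    total = sum(d)
                    if found is None or total < found:
                        found = total
        if found is not None:
            return k, found
    return 0, 0.0


def P(x, y, plane=0, area=0.1):
    return Punctum(x_um=x, y_um=y, plane=plane, area_um2=area, peak_intensity=100.0)


class TestBackgroundSubtraction:
    def test_constant_plane_maps_to_zeros(self):
        stack = PunctaStack(np.full((2, 2, 64, 64), 13.0), 0.1)
        out = subtract_background(stack, radius_um=1.0)
        assert np.allclose(out.data, 0.0)

    def test_zero_plane_unchanged(self):
        stack = PunctaStack(np.zeros((2, 1, 64, 64)), 0.1)
        out = subtract_background(stack, radius_um=1.0)
        assert np.allclose(out.data, 0.0)

    def test_blob_on_background_shape_preserved(self):
        plane = make_plane([(3.0, 3.0, 100.0)], shape=(64, 64), background=20.0)
        data = np.zeros((2, 1, 64, 64))
        data[0, 0] = plane
        out = subtract_background(PunctaStack(data, 0.1), radius_um=1.0)
        clean = plane - 20.0
        # peak reduced by exactly the background; shape preserved within 5%
        assert out.data[0, 0].max() == pytest.approx(clean.max(), rel=0.05)
        core = clean > 0.05 * clean.max()
        assert np.allclose(out.data[0, 0][core], clean[core], atol=0.05 * clean.max())

    def test_invalid_radius_rejected(self):
        stack = PunctaStack(np.zeros((2, 1, 8, 8)), 0.1)
        with pytest.raises(ValueError, match="radius"):
            subtract_background(stack, radius_um=0.0)


class TestDetectPuncta:
    def test_planted_blobs_recovered_with_centroids(self):
        coords = [(2.0 + 3.0 * (k % 4), 2.0 + 3.0 * (k // 4)) for k in range(10)]
        plane = make_plane([(x, y, 100.0) for x, y in coords])
        found = detect_puncta(plane, 0.1)
        assert len(found) == 10
        for x, y in coords:
            d = [np.hypot(p.x_um - x, p.y_um - y) for p in found]
            assert min(d) < 0.1  # within one pixel

    def test_empty_plane_no_puncta(self):
        assert detect_puncta(np.zeros((64, 64)), 0.1) == []
        assert detect_puncta(np.full((64, 64), 5.0), 0.1) == []

    def test_separated_blobs_never_merge(self):
        # two blobs > 2 radii apart; oracle: brute-force flood fill
        plane = make_plane([(3.0, 3.0, 100.0), (3.0 + 1.5, 3.0, 100.0)])
        found = detect_puncta(plane, 0.1)
        assert len(found) == 2
        thr = plane.mean() + 3 * plane.std()
        mask = plane > thr
        seen = np.zeros_like(mask, dtype=bool)
        components = 0
        for start in zip(*np.nonzero(mask)):
            if seen[start]:
                continue
            components += 1
            stack = [start]
            while stack:
                r, c = stack.pop()
                if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]):
                    continue
                if seen[r, c] or not mask[r, c]:
                    continue
                seen[r, c] = True
                stack.extend(
                    (r + dr, c + dc)
                    for dr in (-1, 0, 1)
                    for dc in (-1, 0, 1)
                    if (dr, dc) != (0, 0)
                )
        assert components == 2

    def test_counts_invariant_under_intensity_scaling(self):
        plane = make_plane([(2.0 + 2.0 * k, 5.0, 80.0) for k in range(5)], background=10.0)
        a = detect_puncta(plane, 0.1)
        b = detect_puncta(plane * 37.5, 0.1)
        assert len(a) == len(b) == 5


class TestColocalize:
    def test_planted_pairs_all_matched(self):
        pre = [P(1.0 * k, 1.0) for k in range(10)]
        post = [P(1.0 * k + 0.2, 1.0) for k in range(10)]
        assert len(colocalize(pre, post)) == 10

    def test_offset_channels_no_matches(self):
        pre = [P(1.0 * k, 1.0) for k in range(5)]
        post = [P(1.0 * k, 3.0) for k in range(5)]  # 2 um away
        assert colocalize(pre, post) == []

    def test_matches_equal_exhaustive_oracle_on_random_scenes(self, rng):
        for _ in range(15):
            n_pre, n_post = int(rng.integers(1, 6)), int(rng.integers(1, 6))
            pre = [P(*rng.uniform(0, 4, 2)) for _ in range(n_pre)]
            post = [P(*rng.uniform(0, 4, 2)) for _ in range(n_post)]
            sites = colocalize(pre, post, d_max_um=0.5)
            k_oracle, _ = exhaustive_best_matching(pre, post, 0.5)
            # greedy matching is one-to-one and bounded by the optimum
            assert len(sites) <= k_oracle
            if k_oracle <= 1:
                assert len(sites) == k_oracle

    def test_well_separated_scene_equals_oracle(self):
        pre = [P(0.0, 0.0), P(3.0, 0.0), P(6.0, 0.0), P(9.0, 5.0)]
        post = [P(0.3, 0.0), P(3.0, 0.4), P(6.0, 3.0)]
        sites = colocalize(pre, post, d_max_um=0.5)
        k_oracle, _ = exhaustive_best_matching(pre, post, 0.5)
        assert len(sites) == k_oracle == 2

    def test_symmetric_in_channel_roles(self, rng):
        pre = [P(*rng.uniform(0, 5, 2)) for _ in range(8)]
        post = [P(*rng.uniform(0, 5, 2)) for _ in range(6)]
        assert len(colocalize(pre, post)) == len(colocalize(post, pre))

    def test_mixed_planes_rejected(self):
        with pytest.raises(ValueError, match="single focal plane"):
            colocalize([P(0, 0, plane=0)], [P(0, 0, plane=1)])


class TestGeometry:
    def test_square(self):
        square = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]
        c, a = soma_geometry(square)
        assert c == pytest.approx(40.0)
        assert a == pytest.approx(100.0)

    def test_orientation_invariance(self):
        square = [(0.0, 0.0), (10.0, 0.0), (10.0, 10.0), (0.0, 10.0)]
        assert soma_geometry(square) == soma_geometry(square[::-1])

    def test_regular_64gon_approximates_circle(self):
        theta = np.linspace(0, 2 * np.pi, 65)[:-1]
        poly = [(5 * np.cos(t), 5 * np.sin(t)) for t in theta]
        c, a = soma_geometry(poly)
        assert c == pytest.approx(2 * np.pi * 5, rel=0.01)
        assert a == pytest.approx(np.pi * 25, rel=0.01)

    def test_invalid_polygons_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            soma_geometry([(0, 0), (1, 1)])
        bowtie = [(0.0, 0.0), (2.0, 2.0), (2.0, 0.0), (0.0, 2.0)]
        with pytest.raises(ValueError, match="self-intersecting"):
            soma_geometry(bowtie)

    def test_dendrite_length_examples(self):
        assert dendrite_length([(0, 0), (3, 4)]) == pytest.approx(5.0)
        assert dendrite_length([(0, 0), (1, 0), (2, 0)]) == pytest.approx(2.0)
        with pytest.raises(ValueError, match=">= 2"):
            dendrite_length([(0, 0)])

    def test_random_polyline_equals_brute_force_sum(self, rng):
        pts = rng.uniform(0, 50, (100, 2))
        brute = sum(
            np.hypot(pts[i + 1, 0] - pts[i, 0], pts[i + 1, 1] - pts[i, 1])
            for i in range(99)
        )
        assert dendrite_length([tuple(p) for p in pts]) == pytest.approx(brute)


SQUARE_SOMA = ((2.0, 2.0), (12.0, 2.0), (12.0, 12.0), (2.0, 12.0))
DENDRITE = ((20.0, 2.0), (20.0, 52.0))


def site(x, y, plane=0):
    return type("S", (), {"pre": P(x, y, plane), "post": P(x, y, plane), "plane": plane})()


class TestAssignment:
    def test_soma_boundary_density(self):
        sites = [site(2.0, 2.0 + k) for k in np.linspace(0, 9, 8)]
        rois = RoiSet(SQUARE_SOMA, DENDRITE)
        rep = assign_and_normalize(sites, rois)
        assert rep.soma_count == 8
        assert rep.soma_density_per_um == pytest.approx(8 / 40.0)
        assert rep.soma_circumference_um == pytest.approx(40.0)
        assert rep.soma_area_um2 == pytest.approx(100.0)

    def test_dendrite_density(self):
        sites = [site(20.2, 2.0 + 5.0 * k) for k in range(10)]
        rois = RoiSet(SQUARE_SOMA, DENDRITE)
        rep = assign_and_normalize(sites, rois)
        assert rep.dendrite_count == 10
        assert rep.dendrite_length_um == pytest.approx(50.0)
        assert rep.dendrite_density_per_um == pytest.approx(0.2)

    def test_mixed_scene_counts_match_planted_assignment(self):
        soma_sites = [site(5.0, 5.0), site(7.0, 8.0), site(11.0, 3.0)]
        dend_sites = [site(19.8, 10.0), site(20.1, 30.0)]
        far_sites = [site(40.0, 40.0)]
        rep = assign_and_normalize(
            soma_sites + dend_sites + far_sites, RoiSet(SQUARE_SOMA, DENDRITE)
        )
        assert rep.soma_count == 3
        assert rep.dendrite_count == 2

    def test_density_times_length_reproduces_counts(self):
        sites = [site(5.0, 5.0), site(20.0, 30.0), site(6.0, 11.0)]
        rep = assign_and_normalize(sites, RoiSet(SQUARE_SOMA, DENDRITE))
        assert rep.soma_density_per_um * rep.soma_circumference_um == pytest.approx(
            rep.soma_count
        )
        assert rep.dendrite_density_per_um * rep.dendrite_length_um == pytest.approx(
            rep.dendrite_count
        )


class TestEndToEnd:
    def test_recall_and_precision_on_planted_scenes(self, rng):
        hits = planted = detections = 0
        for scene in range(20):
            pairs = []
            taken = []
            while len(pairs) < 6:
                x, y = rng.uniform(1.5, 10.5, 2)
                if all(np.hypot(x - a, y - b) > 1.5 for a, b in taken):
                    taken.append((x, y))
                    z = int(rng.integers(1, 5))
                    pairs.append(
                        PlantedPair(
                            PlantedPunctum(x, y, z), PlantedPunctum(x + 0.2, y, z)
                        )
                    )
            spec = SynthStackSpec(
                shape_xyz=(128, 128, 6),
                planted_pairs=pairs,
                noise_sd=0.0,
                soma_polygon=SQUARE_SOMA,
                dendrite_polyline=DENDRITE,
            )
            stack, truth = simulate_stack(spec, scene)
            rois = RoiSet(((0.5, 0.5), (12.2, 0.5), (12.2, 12.2), (0.5, 12.2)), DENDRITE,
                          band_half_width_um=1.0)
            rep = count_stack(stack, rois)
            n_found = rep.soma_count + rep.dendrite_count
            detections += n_found
            hits += min(n_found, len(pairs))
            planted += len(pairs)
        assert hits / planted >= 0.95
        assert hits / detections >= 0.95

    def test_swapping_channels_preserves_pair_count(self):
        pairs = [
            PlantedPair(PlantedPunctum(2.0 + 2.5 * k, 5.0, 2), PlantedPunctum(2.2 + 2.5 * k, 5.0, 2))
            for k in range(4)
        ]
        spec = SynthStackSpec(shape_xyz=(128, 128, 5), planted_pairs=pairs, noise_sd=0.0)
        stack, _ = simulate_stack(spec, 0)
        swapped = PunctaStack(stack.data[::-1].copy(), stack.pixel_size_um, stack.z_step_um)
        rois = RoiSet(SQUARE_SOMA, DENDRITE, band_half_width_um=3.0)
        a = count_stack(stack, rois)
        b = count_stack(swapped, rois)
        assert a.soma_count + a.dendrite_count == b.soma_count + b.dendrite_count
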