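"""Tests for nucleus segmentation, DoG filtering, and focus detection.

The detection rule is checked exactly against an independent brute-force
oracle (explicit per-pixel threshold test plus naive flood fill) on random
instances, and statistically against planted ground truth from the image
simulator.
"""

import numpy as np
import pandas as pd
import pytest

from recoverkit import (
    FociParams,
    ImageSimSpec,
    ImageStack,
    detect_foci,
    dog_subtract,
    max_project,
    run_irif_pipeline,
    segment_nuclei,
    simulate_images,
)
from recoverkit.foci_imaging import NucleusLabelMap


# ---------------------------------------------------------------------------
# brute-force oracle: per-pixel rule + naive flood fill, written independently
# ---------------------------------------------------------------------------

def oracle_detect(dog, labels, k_sd=3.0, abs_min=0.0, min_area=3, connectivity=8,
                  min_bg_pixels=10):
    """Naive reimplementation of the two-criterion focus rule."""
    nucleus_ids = sorted(int(v) for v in np.unique(labels) if v > 0)
    stats = {}
    for nid in nucleus_ids:
        vals = dog[labels == nid]
        if len(vals) < min_bg_pixels:
            continue
        med = float(np.median(vals))
        mad = float(np.median(np.abs(vals - med)))
        stats[nid] = (med, 1.4826 * mad)
    if not stats:
        return {}
    ref_sd = float(np.median([s for _, s in stats.values()]))
    if connectivity == 8:
        steps = [(dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    counts = {}
    for nid, (med, _) in stats.items():
        thr = med + k_sd * ref_sd
        passing = (labels == nid) & (dog > thr) & (dog > abs_min)
        seen = np.zeros_like(passing)
        n_foci = 0
        for r0 in range(passing.shape[0]):
            for c0 in range(passing.shape[1]):
                if passing[r0, c0] and not seen[r0, c0]:
                    stack_, comp = [(r0, c0)], []
                    seen[r0, c0] = True
                    while stack_:
                        r, c = stack_.pop()
                        comp.append((r, c))
                        for dr, dc in steps:
                            rr, cc = r + dr, c + dc
                            if (0 <= rr < passing.shape[0] and 0 <= cc < passing.shape[1]
                                    and passing[rr, cc] and not seen[rr, cc]):
                                seen[rr, cc] = True
                                stack_.append((rr, cc))
                    if len(comp) >= min_area:
                        n_foci += 1
        counts[nid] = n_foci
    return counts


def random_instance(rng, shape=(64, 64), n_nuclei=3):
    """Random rectangular 'nuclei' and a rough DoG-like field with spikes."""
    labels = np.zeros(shape, dtype=np.int32)
    for nid in range(1, n_nuclei + 1):
        h = rng.integers(8, 20)
        w = rng.integers(8, 20)
        r = rng.integers(0, shape[0] - h)
        c = rng.integers(0, shape[1] - w)
        labels[r : r + h, c : c + w] = nid
    dog = rng.normal(0, 1, size=shape)
    spikes = rng.integers(0, shape[0] * shape[1], size=30)
    dog.ravel()[spikes] += rng.uniform(2, 10, size=30)
    return dog, labels


class TestOracleEquivalence:
    @pytest.mark.parametrize("connectivity", [8, 4])
    def test_matches_bruteforce_on_random_instances(self, connectivity):
        rng = np.random.default_rng(2024)
        params = FociParams(k_sd=2.0, min_focus_area=2, connectivity=connectivity)
        for _ in range(25):
            dog, labels = random_instance(rng)
            expected = oracle_detect(dog, labels, k_sd=2.0, min_area=2,
                                     connectivity=connectivity)
            got = detect_foci(dog, NucleusLabelMap(labels=labels), params).counts()
            assert got == expected


class TestMaxProject:
    def test_single_plane_identity(self, rng):
        img = rng.uniform(0, 100, size=(16, 16))
        stack = ImageStack(channels={"dapi": img})
        assert np.array_equal(max_project(stack, "dapi"), img)

    def test_two_plane_pixel(self):
        a = np.zeros((2, 4, 4))
        a[0, 1, 1], a[1, 1, 1] = 3, 7
        assert max_project(ImageStack(channels={"c": a}), "c")[1, 1] == 7

    def test_equals_bruteforce_loop(self, rng):
        a = rng.uniform(0, 10, size=(5, 8, 8))
        out = max_project(ImageStack(channels={"c": a}), "c")
        for r in range(8):
            for c in range(8):
                assert out[r, c] == max(a[z, r, c] for z in range(5))

    def test_unknown_channel(self):
        stack = ImageStack(channels={"dapi": np.zeros((4, 4))})
        with pytest.raises(KeyError):
            max_project(stack, "gH2AX")


class TestDogSubtract:
    def test_constant_maps_to_zero(self):
        out = dog_subtract(np.full((32, 32), 500.0), 1, 3)
        assert np.abs(out).max() <= 1e-6 * 500

    def test_linearity(self, rng):
        img = rng.uniform(0, 100, size=(32, 32))
        np.testing.assert_allclose(dog_subtract(3 * img, 1, 4), 3 * dog_subtract(img, 1, 4),
                                   atol=1e-9)

    def test_response_peaks_at_planted_center(self):
        img = np.zeros((41, 41))
        rr, cc = np.mgrid[0:41, 0:41]
        img += 50 * np.exp(-((rr - 20) ** 2 + (cc - 20) ** 2) / (2 * 2.0**2))
        out = dog_subtract(img, 1, 4)
        assert np.unravel_index(out.argmax(), out.shape) == (20, 20)

    def test_sigma_order_enforced(self):
        with pytest.raises(ValueError):
            dog_subtract(np.zeros((8, 8)), 3, 1)


class TestSegmentNuclei:
    def test_all_zero_image(self):
        assert segment_nuclei(np.zeros((64, 64))).n_nuclei == 0

    def test_single_ellipse_area_within_5pct(self, rng):
        img = np.full((128, 128), 20.0)
        rr, cc = np.mgrid[0:128, 0:128]
        inside = ((rr - 64) / 30) ** 2 + ((cc - 64) / 40) ** 2 <= 1
        img[inside] = 150.0
        img += rng.normal(0, 2, size=img.shape)
        lab = segment_nuclei(np.clip(img, 0, None), FociParams(min_nucleus_area=100))
        assert lab.n_nuclei == 1
        planted = inside.sum()
        assert abs(lab.areas()[1] - planted) / planted < 0.05

    def test_touching_ellipses_split_by_watershed(self):
        img = np.full((128, 160), 20.0)
        rr, cc = np.mgrid[0:128, 0:160]
        # two circles r=25 whose centers are 44 px apart: overlap ~20% of radius
        for c0 in (55, 99):
            img[((rr - 64) ** 2 + (cc - c0) ** 2) <= 25**2] = 150.0
        lab = segment_nuclei(img, FociParams(min_nucleus_area=100, watershed_min_distance=15))
        assert lab.n_nuclei == 2

    def test_labels_renumbered_in_raster_order(self):
        img = np.full((100, 100), 10.0)
        img[10:30, 60:80] = 200.0  # first in raster order (top)
        img[60:85, 10:35] = 200.0
        lab = segment_nuclei(img, FociParams(min_nucleus_area=50))
        assert lab.n_nuclei == 2
        first_pixels = {nid: np.argwhere(lab.labels == nid)[0].tolist() for nid in (1, 2)}
        assert first_pixels[1][0] < first_pixels[2][0]


class TestDetectFoci:
    def _single_focus_scene(self, amplitude=10.0, noise_sd=1.0, seed=5):
        rng = np.random.default_rng(seed)
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[10:54, 10:54] = 1
        img = np.full((64, 64), 100.0)
        rr, cc = np.mgrid[0:64, 0:64]
        img += amplitude * noise_sd * np.exp(-((rr - 32) ** 2 + (cc - 30) ** 2) / (2 * 1.5**2))
        img += rng.normal(0, noise_sd, size=img.shape)
        dog = dog_subtract(img, 1, 3)
        return dog, NucleusLabelMap(labels=labels)

    def test_pure_noise_yields_no_foci(self, rng):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[8:56, 8:56] = 1
        dog = dog_subtract(np.full((64, 64), 100.0) + rng.normal(0, 1, (64, 64)), 1, 3)
        calls = detect_foci(dog, NucleusLabelMap(labels=labels), FociParams(k_sd=4.0))
        assert calls.counts()[1] == 0

    def test_single_planted_focus_recovered(self):
        dog, nuclei = self._single_focus_scene()
        calls = detect_foci(dog, nuclei, FociParams(k_sd=3.0))
        assert calls.counts()[1] == 1
        f = calls.foci.iloc[0]
        assert abs(f.centroid_row - 32) <= 1 and abs(f.centroid_col - 30) <= 1

    def test_foci_lie_within_their_nucleus(self):
        spec = ImageSimSpec(n_nuclei=4, foci_per_nucleus=6, seed=9, image_size=(384, 384))
        stack, _ = simulate_images(spec)
        params = FociParams()
        nuclei = segment_nuclei(max_project(stack, "dapi"), params)
        dog = dog_subtract(max_project(stack, "gH2AX"), 1, 3)
        calls = detect_foci(dog, nuclei, params)
        for f in calls.foci.itertuples():
            assert nuclei.labels[round(f.centroid_row), round(f.centroid_col)] == f.nucleus_id

    @pytest.mark.parametrize("param,values", [
        ("k_sd", [2.0, 3.0, 4.0, 6.0]),
        ("abs_min", [0.0, 1.0, 3.0, 8.0]),
        ("min_focus_area", [1, 3, 6, 12]),
    ])
    def test_counts_monotone_in_stringency(self, param, values):
        dog, nuclei = self._single_focus_scene(amplitude=6.0)
        prev = None
        for v in values:
            calls = detect_foci(dog, nuclei, FociParams(**{param: v}))
            n = sum(calls.counts().values())
            if prev is not None:
                assert n <= prev
            prev = n

    def test_per_nucleus_offset_invariance(self, rng):
        # constant per-nucleus background offsets are annihilated by the DoG
        # band-pass; the step edges sit outside the analysed nuclei, so only
        # the flat interior shift (which DoG removes) is in play
        labels = np.zeros((96, 200), dtype=np.int32)
        labels[28:68, 20:70] = 1
        labels[28:68, 130:180] = 2
        raw = np.full((96, 200), 100.0)
        rr, cc = np.mgrid[0:96, 0:200]
        for r0, c0 in [(40, 35), (55, 55), (40, 145), (55, 165), (33, 160)]:
            raw += 10.0 * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * 1.5**2))
        raw += rng.normal(0, 1.0, size=raw.shape)
        offset = raw.copy()
        offset[:, :100] += 40.0  # shifts nucleus 1 and its surround uniformly
        offset[:, 100:] += 90.0
        params = FociParams()
        nuclei = NucleusLabelMap(labels=labels)
        base = detect_foci(dog_subtract(raw, 1, 3), nuclei, params).counts()
        shifted = detect_foci(dog_subtract(offset, 1, 3), nuclei, params).counts()
        assert base == {1: 2, 2: 3}
        assert base == shifted

    def test_zero_nuclei_empty_callset(self):
        calls = detect_foci(np.zeros((32, 32)), NucleusLabelMap(labels=np.zeros((32, 32), dtype=np.int32)))
        assert calls.foci.empty and calls.nuclei.empty

    def test_tiny_nucleus_excluded_with_warning(self, caplog, rng):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[2:4, 2:4] = 1  # 4 px, below the background-estimation minimum
        labels[10:28, 10:28] = 2
        dog = rng.normal(0, 1, size=(32, 32))
        with caplog.at_level("WARNING"):
            calls = detect_foci(dog, NucleusLabelMap(labels=labels))
        assert set(calls.nuclei["nucleus_id"]) == {2}
        assert "too small" in caplog.text


class TestPipeline:
    def test_unirradiated_scene_median_zero(self):
        spec = ImageSimSpec(n_nuclei=5, foci_per_nucleus=0, seed=3, image_size=(384, 384))
        stack, _ = simulate_images(spec)
        table = run_irif_pipeline(stack, FociParams())
        assert table["focus_count"].median() == 0

    def test_post_ir_scene_mean_count_within_10pct(self):
        # Poisson mean 15 foci/nucleus at high SNR, as ~1 h after irradiation
        spec = ImageSimSpec(n_nuclei=5, foci_per_nucleus=("poisson", 15.0), seed=21,
                            image_size=(512, 512),
                            nucleus_semiaxes=((26.0, 32.0), (22.0, 28.0)),
                            min_focus_separation=6.0)
        stack, truth = simulate_images(spec)
        table = run_irif_pipeline(stack, FociParams())
        planted_mean = truth.foci.groupby("nucleus_id").size().reindex(
            truth.nuclei["nucleus_id"], fill_value=0).mean()
        assert table["focus_count"].mean() == pytest.approx(planted_mean, rel=0.10)

    def test_label_shuffle_leaves_counts_unchanged(self):
        spec = ImageSimSpec(n_nuclei=3, foci_per_nucleus=5, seed=17, image_size=(320, 320))
        stack, _ = simulate_images(spec)
        params = FociParams()
        nuclei = segment_nuclei(max_project(stack, "dapi"), params)
        dog = dog_subtract(max_project(stack, "gH2AX"), 1, 3)
        base = detect_foci(dog, nuclei, params)
        perm = {1: 3, 2: 1, 3: 2}
        shuffled = np.zeros_like(nuclei.labels)
        for old, new in perm.items():
            shuffled[nuclei.labels == old] = new
        remapped = detect_foci(dog, NucleusLabelMap(labels=shuffled), params)
        base_counts = base.counts()
        re_counts = remapped.counts()
        assert {perm[k]: v for k, v in base_counts.items()} == re_counts

    def test_zstack_projection_required(self):
        spec = ImageSimSpec(n_nuclei=3, foci_per_nucleus=6, z_planes=4, seed=29,
                            image_size=(320, 320))
        stack, truth = simulate_images(spec)
        assert stack.z_planes == 4
        table = run_irif_pipeline(stack, FociParams())
        assert table["focus_count"].sum() == len(truth.foci)
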