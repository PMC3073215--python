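import numpy as np
import pytest
from scipy import ndimage as ndi
from scipy.spatial import ConvexHull

from conftest import disc_mask, draw_disc
from fishscore.nuclei import (
    NucleusLabelMap,
    SegmentationParams,
    filter_objects,
    qc_dapi,
    segment_nuclei,
    watershed_split,
)
from fishscore.synthetic import SyntheticSpec, generate_case
from fishscore.image_io import split_channels

SMALL_PARAMS = SegmentationParams(min_area=200, max_area=20_000)


def _disc_image(centers, radius=20, shape=(256, 256), value=0.8):
    img = np.full(shape, 0.05)
    for c in centers:
        draw_disc(img, c, radius, value)
    return img


class TestSegmentNuclei:
    def test_three_disjoint_discs(self):
        img = _disc_image([(60, 60), (60, 190), (190, 120)])
        nmap = segment_nuclei(img, SMALL_PARAMS)
        # oracle: connected components of the thresholded fixture
        n_cc = ndi.label(img > 0.4)[1]
        assert n_cc == 3
        assert nmap.n_nuclei == 3

    def test_blank_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="no foreground"):
            nmap = segment_nuclei(np.zeros((64, 64)), SMALL_PARAMS)
        assert nmap.n_nuclei == 0
        assert np.all(nmap.labels == 0)

    def test_overlapping_discs_are_split(self):
        # centers 1.4 r apart: ~30% overlap of radius
        img = _disc_image([(100, 100), (100, 128)], radius=20)
        nmap = segment_nuclei(img, SMALL_PARAMS)
        assert nmap.n_nuclei == 2

    def test_deterministic(self):
        img = _disc_image([(60, 60), (190, 120)])
        a = segment_nuclei(img, SMALL_PARAMS)
        b = segment_nuclei(img, SMALL_PARAMS)
        assert np.array_equal(a.labels, b.labels)
        assert a.features == b.features

    def test_min_area_monotonicity(self):
        img = _disc_image([(60, 60), (60, 190), (190, 120)], radius=12)
        ks = []
        for min_area in (10, 200, 400, 1000):
            params = SegmentationParams(min_area=min_area, max_area=20_000)
            ks.append(segment_nuclei(img, params).n_nuclei)
        assert ks == sorted(ks, reverse=True)

    @pytest.mark.parametrize("n", range(1, 11))
    def test_recovers_n_well_separated_nuclei(self, n):
        spec = SyntheticSpec(seed=100 + n, n_nuclei=n, image_size=(500, 500))
        img, _ = generate_case(spec)
        _, _, blue = split_channels(img)
        assert segment_nuclei(blue).n_nuclei == n


class TestWatershedSplit:
    def test_single_disc_passes_through(self):
        mask = disc_mask((128, 128), (64, 64), 25)
        labels = watershed_split(mask, 0.1)
        assert labels.max() == 1
        assert np.array_equal(labels > 0, mask)

    def test_dumbbell_splits_in_two(self):
        mask = disc_mask((128, 160), (64, 55), 25) | disc_mask((128, 160), (64, 100), 25)
        # oracle: two clear peaks in the distance transform
        dist = ndi.distance_transform_edt(mask)
        peak_at_centers = dist[64, 55] > 0.8 * dist.max() and dist[64, 100] > 0.8 * dist.max()
        assert peak_at_centers
        labels = watershed_split(mask, 0.1)
        assert labels.max() == 2
        assert np.array_equal(labels > 0, mask)

    def test_empty_mask(self):
        labels = watershed_split(np.zeros((16, 16), dtype=bool), 0.1)
        assert labels.shape == (16, 16) and labels.max() == 0

    def test_partition_property_on_random_blobs(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            seeds = np.zeros((100, 100), dtype=bool)
            idx = rng.integers(10, 90, size=(6, 2))
            seeds[idx[:, 0], idx[:, 1]] = True
            mask = ndi.binary_dilation(seeds, iterations=int(rng.integers(4, 12)))
            labels = watershed_split(mask, 0.1)
            assert np.array_equal(labels > 0, mask)  # union = mask, bg stays 0


class TestFilterObjects:
    def test_small_speck_removed(self):
        labels = np.zeros((64, 64), dtype=int)
        labels[5:7, 5:10] = 1  # 10-px speck
        nmap = filter_objects(labels, SegmentationParams(min_area=200, max_area=20_000))
        assert nmap.n_nuclei == 0

    def test_solid_disc_retained(self):
        mask = disc_mask((128, 128), (64, 64), 20)
        labels, _ = ndi.label(mask)
        nmap = filter_objects(labels, SegmentationParams(min_area=200, max_area=20_000, min_solidity=0.9))
        assert nmap.n_nuclei == 1
        # oracle: solidity of a rasterized disc from an independent convex hull
        pts = np.argwhere(mask)
        hull_area = ConvexHull(pts).volume
        assert pts.shape[0] / hull_area > 0.9
        assert nmap.features[0].solidity > 0.9

    def test_border_clipped_disc_removed(self):
        mask = disc_mask((128, 128), (0, 64), 20)
        labels, _ = ndi.label(mask)
        nmap = filter_objects(labels, SegmentationParams(min_area=50, max_area=20_000))
        assert nmap.n_nuclei == 0

    def test_relabeling_is_raster_ordered_and_consecutive(self):
        img = _disc_image([(190, 60), (60, 190), (60, 60)])
        nmap = segment_nuclei(img, SMALL_PARAMS)
        ids = [f.label_id for f in nmap.features]
        assert ids == [1, 2, 3]
        cents = [f.centroid for f in nmap.features]
        assert cents == sorted(cents)
        for f in nmap.features:
            assert f.area == int(np.sum(nmap.labels == f.label_id))
            assert not f.touches_border


class TestQcDapi:
    def test_all_zero_blue_flags_no_dapi(self):
        blue = np.zeros((64, 64))
        nmap = NucleusLabelMap(labels=np.zeros((64, 64), dtype=int))
        report = qc_dapi(blue, nmap)
        assert report.no_dapi_suspected
        assert report.nuclear_area_fraction == 0.0

    def test_bright_discs_pass(self):
        blue = _disc_image([(60, 60), (60, 190), (190, 120)], radius=26.35)
        nmap = segment_nuclei(blue, SMALL_PARAMS)
        report = qc_dapi(blue, nmap)
        assert not report.no_dapi_suspected
        assert report.nuclear_area_fraction == pytest.approx(0.10, abs=0.02)

    def test_dim_blue_flags_no_dapi_via_intensity_floor(self):
        blue = np.full((64, 64), 0.02)
        nmap = NucleusLabelMap(labels=np.ones((64, 64), dtype=int))
        assert qc_dapi(blue, nmap).no_dapi_suspected
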