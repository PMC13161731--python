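"""Raster round-trips, component labelling and calibrated morphometry."""

import math
from collections import deque

import numpy as np
import pytest
from shapely.geometry import Polygon

from vesselquant import (
    InputError,
    LabelField,
    PixelCalibration,
    ProbabilityField,
    extract_instances,
    label_components,
    read_instances_csv,
    read_mask,
    read_roi_points,
    read_roi_polygon,
    threshold_probability,
    write_instances_csv,
    write_mask,
    write_roi_points,
    write_roi_polygon,
)


def flood_fill_count(binary, connectivity=2):
    """Independent BFS component counter."""
    if connectivity == 2:
        steps = [(di, dj) for di in (-1, 0, 1) for dj in (-1, 0, 1) if (di, dj) != (0, 0)]
    else:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    seen = np.zeros_like(binary, dtype=bool)
    count = 0
    H, W = binary.shape
    for i in range(H):
        for j in range(W):
            if binary[i, j] and not seen[i, j]:
                count += 1
                q = deque([(i, j)])
                seen[i, j] = True
                while q:
                    ci, cj = q.popleft()
                    for di, dj in steps:
                        ni, nj = ci + di, cj + dj
                        if 0 <= ni < H and 0 <= nj < W and binary[ni, nj] and not seen[ni, nj]:
                            seen[ni, nj] = True
                            q.append((ni, nj))
    return count


class TestMaskRoundTrip:
    @pytest.mark.parametrize("suffix", [".tif", ".png"])
    def test_write_read_bit_exact(self, tmp_path, calib, suffix, rng):
        labels = rng.integers(0, 300, size=(64, 64)).astype(np.int64)
        field = LabelField(labels=labels, calib=calib)
        path = tmp_path / f"mask{suffix}"
        write_mask(field, path)
        back = read_mask(path, calib)
        assert np.array_equal(back.labels, labels)
        assert back.n_instances == labels.max()

    def test_all_zero_field(self, tmp_path, calib):
        field = LabelField(labels=np.zeros((8, 8), dtype=np.int64), calib=calib)
        path = tmp_path / "zero.tif"
        write_mask(field, path)
        assert extract_instances(read_mask(path, calib)) == []

    def test_multichannel_rejected(self, tmp_path, calib):
        import imageio.v3 as iio

        path = tmp_path / "rgb.png"
        iio.imwrite(path, np.zeros((8, 8, 3), dtype=np.uint8))
        with pytest.raises(InputError):
            read_mask(path, calib)


class TestThreshold:
    def test_uniform_fields(self, calib):
        hi = ProbabilityField(values=np.full((4, 4), 0.6), calib=calib)
        lo = ProbabilityField(values=np.full((4, 4), 0.4), calib=calib)
        assert threshold_probability(hi, 0.5).binary().all()
        assert not threshold_probability(lo, 0.5).binary().any()

    def test_split_field_thresholds_exactly(self, calib):
        vals = np.full((4, 4), 0.3)
        vals[:, 2:] = 0.8
        out = threshold_probability(ProbabilityField(values=vals, calib=calib), 0.5)
        assert out.binary().sum() == 8
        assert out.binary()[:, 2:].all()

    def test_threshold_bounds(self, calib):
        prob = ProbabilityField(values=np.full((2, 2), 0.5), calib=calib)
        assert threshold_probability(prob, 0.0).binary().all()
        with pytest.raises(InputError):
            threshold_probability(prob, 1.5)


class TestLabelComponents:
    def test_two_disjoint_squares(self, calib):
        a = np.zeros((10, 10), dtype=np.int64)
        a[1:4, 1:4] = 1
        a[6:9, 6:9] = 1
        out = label_components(LabelField(labels=a, calib=calib))
        assert out.n_instances == 2

    def test_diagonal_touch_depends_on_connectivity(self, calib):
        a = np.zeros((6, 6), dtype=np.int64)
        a[1:3, 1:3] = 1
        a[3:5, 3:5] = 1  # touches only at the corner (2,2)-(3,3)
        f = LabelField(labels=a, calib=calib)
        assert label_components(f, connectivity=2).n_instances == 1
        assert label_components(f, connectivity=1).n_instances == 2

    @pytest.mark.parametrize("connectivity", [1, 2])
    def test_random_specks_match_flood_fill(self, calib, rng, connectivity):
        binary = (rng.random((40, 40)) < 0.25).astype(np.int64)
        f = LabelField(labels=binary, calib=calib)
        got = label_components(f, connectivity=connectivity).n_instances
        assert got == flood_fill_count(binary.astype(bool), connectivity)


class TestExtractInstances:
    def test_ten_pixel_blob_area(self, calib):
        a = np.zeros((8, 8), dtype=np.int64)
        a[2:4, 2:7] = 1  # 10 px
        recs = extract_instances(LabelField(labels=a, calib=calib))
        assert len(recs) == 1
        assert recs[0].area_px == 10
        assert recs[0].area_um2 == pytest.approx(0.18769)

    def test_single_pixel_centroid_convention(self, calib):
        a = np.zeros((8, 8), dtype=np.int64)
        a[3, 5] = 1
        (rec,) = extract_instances(LabelField(labels=a, calib=calib))
        s = calib.microns_per_pixel
        assert rec.centroid_x_um == pytest.approx((5 + 0.5) * s)
        assert rec.centroid_y_um == pytest.approx((3 + 0.5) * s)

    def test_disc_perimeter_close_to_analytic(self, calib):
        r = 40
        n = 2 * r + 5
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2
        disc = ((yy - c) ** 2 + (xx - c) ** 2 <= r * r).astype(np.int64)
        (rec,) = extract_instances(LabelField(labels=disc, calib=calib))
        expected = 2 * math.pi * r * calib.microns_per_pixel
        assert rec.perimeter_um == pytest.approx(expected, rel=0.05)

    def test_ellipse_morphometry(self, calib):
        a_ax, b_ax = 20, 10
        n = 2 * a_ax + 5
        yy, xx = np.mgrid[0:n, 0:n]
        c = (n - 1) / 2
        ell = ((xx - c) ** 2 / a_ax**2 + (yy - c) ** 2 / b_ax**2 <= 1).astype(np.int64)
        (rec,) = extract_instances(LabelField(labels=ell, calib=calib))
        s = calib.microns_per_pixel
        assert rec.area_um2 == pytest.approx(math.pi * a_ax * b_ax * s * s, rel=0.02)
        # Ramanujan's approximation for the ellipse perimeter
        h = ((a_ax - b_ax) / (a_ax + b_ax)) ** 2
        per = math.pi * (a_ax + b_ax) * (1 + 3 * h / (10 + math.sqrt(4 - 3 * h))) * s
        assert rec.perimeter_um == pytest.approx(per, rel=0.05)

    def test_pixel_conservation_and_label_permutation(self, calib, rng):
        labels = label_components(
            LabelField(labels=(rng.random((50, 50)) < 0.2).astype(np.int64), calib=calib)
        )
        recs = extract_instances(labels)
        assert sum(r.area_px for r in recs) == int(labels.binary().sum())
        # permute the labels: morphometry is the same up to id relabeling
        k = labels.n_instances
        perm = rng.permutation(k) + 1
        lut = np.zeros(k + 1, dtype=np.int64)
        lut[1:] = perm
        permuted = LabelField(labels=lut[labels.labels], calib=calib)
        recs_p = extract_instances(permuted)
        key = lambda r: (round(r.centroid_x_um, 9), round(r.centroid_y_um, 9))
        assert sorted((key(r), r.area_px) for r in recs) == sorted(
            (key(r), r.area_px) for r in recs_p
        )


class TestAnnotations:
    def test_polygon_round_trip(self, tmp_path):
        poly = Polygon([(0, 0), (10, 0), (10, 10), (0, 10)])
        path = tmp_path / "roi.geojson"
        write_roi_polygon(poly, path)
        back = read_roi_polygon(path)
        assert back.equals(poly)

    def test_self_intersecting_polygon_rejected(self, tmp_path):
        import json

        bowtie = {
            "type": "Feature",
            "properties": {"units": "um"},
            "geometry": {
                "type": "Polygon",
                "coordinates": [[[0, 0], [10, 10], [10, 0], [0, 10], [0, 0]]],
            },
        }
        path = tmp_path / "bad.geojson"
        path.write_text(json.dumps(bowtie))
        with pytest.raises(InputError):
            read_roi_polygon(path)

    def test_points_round_trip_and_pixel_units(self, tmp_path, calib):
        pts = np.array([[1.5, 2.5], [30.0, 4.0], [7.0, 19.0]])
        path = tmp_path / "pts.geojson"
        write_roi_points(pts, path)
        assert np.allclose(read_roi_points(path), pts)
        # pixel-unit file converts through the calibration
        import json

        doc = json.loads(path.read_text())
        doc["properties"]["units"] = "px"
        path.write_text(json.dumps(doc))
        assert np.allclose(read_roi_points(path, calib), pts * calib.microns_per_pixel)
        with pytest.raises(InputError):
            read_roi_points(path)  # px units but no calibration given


class TestInstanceCsv:
    def test_round_trip_thousand_instances(self, tmp_path, rng):
        from conftest import make_instance

        recs = [
            make_instance(i, rng.uniform(0, 500), rng.uniform(0, 500),
                          rng.uniform(6.5, 5000), area_px=int(rng.integers(1, 10000)))
            for i in range(1000)
        ]
        path = tmp_path / "inst.csv"
        write_instances_csv(recs, path)
        back = read_instances_csv(path)
        assert len(back) == 1000
        for a, b in zip(recs, back):
            assert a.id == b.id and a.area_px == b.area_px
            assert a.centroid_x_um == b.centroid_x_um
            assert a.centroid_y_um == b.centroid_y_um
            assert a.area_um2 == b.area_um2
            assert a.eq_radius_um == b.eq_radius_um
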