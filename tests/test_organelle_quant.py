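import numpy as np
import pytest

from phenodyn.organelle_quant import (
    MitoCellResult,
    classify_mito_morphology,
    line_profile,
    mito_morphometrics,
    sample_area_lengths,
    segment_mitochondria,
)
from phenodyn.synthetic_cells import (
    ActinSpec,
    ImagingSpec,
    MitoSpec,
    MTSpec,
    _polyline_aa,
    default_geometry,
    render_scene,
)


@pytest.fixture(scope="module")
def geometry():
    return default_geometry(seed=23)


@pytest.fixture(scope="module")
def mito_scene(geometry):
    stack, truth = render_scene(
        geometry, ActinSpec.for_class(4), MitoSpec(n_objects=25, median_length_um=1.8),
        MTSpec(), ImagingSpec.noiseless(seed=14))
    labels = segment_mitochondria(stack[2], geometry.cell_mask())
    return stack, truth, labels


class TestSegmentation:
    def test_blank_channel_gives_empty_label_map(self, geometry):
        labels = segment_mitochondria(np.zeros(geometry.shape), geometry.cell_mask())
        assert labels.max() == 0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            segment_mitochondria(np.zeros((64, 64)),
                                 np.zeros((64, 64), dtype=bool))

    def test_noiseless_count_exact(self, mito_scene):
        _, truth, labels = mito_scene
        assert labels.max() == len(truth.mito_polylines)

    def test_noisy_count_within_two(self, geometry):
        stack, truth = render_scene(
            geometry, ActinSpec.for_class(4), MitoSpec(n_objects=25),
            MTSpec(), ImagingSpec(seed=15))
        labels = segment_mitochondria(stack[2], geometry.cell_mask())
        assert abs(labels.max() - 25) <= 2


class TestLengths:
    @pytest.mark.parametrize("angle_deg", [0, 30, 45, 75, 110, 155])
    @pytest.mark.parametrize("length_px", [12, 30, 50])
    def test_straight_tubule_length_within_five_percent(self, angle_deg, length_px):
        geometry = default_geometry(seed=23)
        a = np.deg2rad(angle_deg)
        d = np.array([np.sin(a), np.cos(a)])
        p0 = np.array([128.0, 128.0]) - length_px / 2 * d
        poly = np.vstack([p0, p0 + length_px * d])
        rho = _polyline_aa(geometry.shape, poly, 3)
        channel = np.round(rho * 255).astype(np.uint16)
        labels = (rho >= 0.5).astype(int)
        res = mito_morphometrics(labels, geometry, channel=channel, classify=False)
        est_px = res.objects[0].length_um / geometry.pixel_size_um
        assert est_px == pytest.approx(length_px, rel=0.05)

    def test_scene_mean_length_close_to_truth(self, geometry, mito_scene):
        stack, truth, labels = mito_scene
        res = mito_morphometrics(labels, geometry, channel=stack[2])
        assert res.mean_length_um == pytest.approx(
            np.mean(truth.mito_lengths_um), rel=0.10)

    def test_label_only_fallback_is_reasonable(self, geometry, mito_scene):
        _, truth, labels = mito_scene
        res = mito_morphometrics(labels, geometry)
        assert res.mean_length_um == pytest.approx(
            np.mean(truth.mito_lengths_um), rel=0.2)


class TestMorphologyClass:
    def _result(self, lengths):
        from phenodyn.organelle_quant import MitoObject

        objs = [MitoObject(i + 1, np.zeros((1, 2)), l, 10, (0.0, 0.0), 0.5)
                for i, l in enumerate(lengths)]
        return MitoCellResult(cell_id="x", objects=objs, count=len(objs),
                              mean_length_um=float(np.mean(lengths)),
                              median_length_um=float(np.median(lengths)),
                              mean_radial_position=0.5, peripheral_fraction=0.0)

    def test_all_long_is_tubular(self):
        assert classify_mito_morphology(self._result([3.0] * 10)) == "tubular"

    def test_all_short_is_fragmented(self):
        assert classify_mito_morphology(self._result([0.4] * 10)) == "fragmented"

    def test_half_and_half_is_mixed(self):
        assert classify_mito_morphology(self._result([3.0] * 5 + [0.4] * 5)) == "mixed"

    def test_empty_cell_flagged(self):
        res = MitoCellResult(cell_id="x", objects=[], count=0, mean_length_um=0,
                             median_length_um=0, mean_radial_position=0,
                             peripheral_fraction=0)
        with pytest.raises(ValueError, match="undefined"):
            classify_mito_morphology(res)


class TestAreaSampling:
    def test_uniform_population_sampled_values_constant(self, geometry):
        res = TestMorphologyClass()._result([2.0] * 40)
        for i, o in enumerate(res.objects):
            o.centroid = (100.0 + 5 * (i % 8), 100.0 + 5 * (i // 8))
        records = sample_area_lengths(res, geometry, n_areas=10, per_area=5,
                                      area_size_px=60, seed=1)
        assert records
        assert all(r["length_um"] == 2.0 for r in records)

    def test_seed_determinism(self, geometry):
        res = TestMorphologyClass()._result(list(np.linspace(0.5, 3.0, 30)))
        for i, o in enumerate(res.objects):
            o.centroid = (90.0 + 7 * (i % 6), 90.0 + 7 * (i // 6))
        r1 = sample_area_lengths(res, geometry, seed=3)
        r2 = sample_area_lengths(res, geometry, seed=3)
        assert r1 == r2

    def test_no_objects_errors(self, geometry):
        res = MitoCellResult(cell_id="x", objects=[], count=0, mean_length_um=0,
                             median_length_um=0, mean_radial_position=0,
                             peripheral_fraction=0)
        with pytest.raises(ValueError):
            sample_area_lengths(res, geometry)


class TestLineProfile:
    def test_uniform_image_gives_constant_profile(self):
        img = np.full((64, 64), 7.0)
        poly = np.array([[10.0, 10.0], [10.0, 50.0]])
        prof = line_profile(img, poly, width_px=3)
        assert np.allclose(prof.gray_value, 7.0)
        assert np.all(np.diff(prof.arclength_um) > 0)

    def test_width_irrelevant_on_uniform_image(self):
        img = np.full((64, 64), 3.0)
        poly = np.array([[20.0, 5.0], [20.0, 60.0]])
        p1 = line_profile(img, poly, width_px=3)
        p2 = line_profile(img, poly, width_px=6)
        assert np.allclose(p1.gray_value, p2.gray_value)

    def test_peak_located_at_tubule_crossing(self):
        rho = _polyline_aa((96, 96), np.array([[48.0, 20.0], [48.0, 76.0]]), 3)
        img = rho * 200
        poly = np.array([[20.0, 48.0], [76.0, 48.0]])  # crosses at row 48
        prof = line_profile(img, poly, width_px=3)
        peak_arc = prof.arclength_um[np.argmax(prof.gray_value)]
        assert peak_arc == pytest.approx(2.8, abs=0.2)  # 28 px along the line

    def test_polyline_outside_image_rejected(self):
        with pytest.raises(ValueError, match="exits"):
            line_profile(np.zeros((32, 32)), np.array([[0.0, 0.0], [40.0, 0.0]]))


class TestPeripheralFraction:
    def test_group_means_increase_with_rho(self):
        means = []
        for rho in (0.1, 0.5, 0.9):
            vals = []
            for s in range(3):
                geometry = default_geometry(seed=60 + s)
                stack, _ = render_scene(
                    geometry, ActinSpec.for_class(4),
                    MitoSpec(n_objects=18, median_length_um=1.0, rho=rho),
                    MTSpec(), ImagingSpec.noiseless(seed=s + int(rho * 100)))
                labels = segment_mitochondria(stack[2], geometry.cell_mask())
                res = mito_morphometrics(labels, geometry)
                vals.append(res.peripheral_fraction)
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]
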