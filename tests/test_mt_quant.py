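import numpy as np
import pytest
from scipy import ndimage

from phenodyn.mt_quant import (
    OrientationField,
    classify_mt,
    estimate_centrosome,
    orientation_field,
    parallel_order_score,
    radial_alignment_score,
    score_cell,
)
from phenodyn.synthetic_cells import (
    ActinSpec,
    ImagingSpec,
    MitoSpec,
    MTSpec,
    default_geometry,
    render_scene,
)


@pytest.fixture(scope="module")
def geometry():
    return default_geometry(seed=31)


def _mt_scene(geometry, field_type, seed=0, imaging=None):
    stack, _ = render_scene(
        geometry, ActinSpec.for_class(4), MitoSpec(n_objects=0),
        MTSpec(field_type=field_type),
        imaging or ImagingSpec.noiseless(seed=seed))
    return stack[3].astype(float)


class TestOrientationField:
    def test_horizontal_stripes_read_theta_zero(self):
        rows = np.arange(128)
        img = np.sin(2 * np.pi * rows / 8)[:, None] * np.ones((1, 128))
        f = orientation_field(img, tensor_sigma=3)
        energetic = f.energy > 0.5 * f.energy.max()
        theta = f.theta[energetic]
        # stripes vary along rows -> lines run along columns (theta = 0 mod pi)
        dev = np.minimum(theta, np.pi - theta)
        assert np.median(dev) < 0.05
        assert np.median(f.coherence[energetic]) > 0.9

    def test_uniform_image_is_uninformative(self):
        f = orientation_field(np.full((64, 64), 5.0))
        assert not f.informative

    def test_rotation_equivariance_30_degrees(self):
        # stripe field at a known angle; measure only a central crop so the
        # rotation boundary does not pollute the energy weighting
        rr, cc = np.mgrid[0:256, 0:256].astype(float)
        phase = rr * np.sin(0.35) + cc * np.cos(0.35)
        img = np.sin(2 * np.pi * phase / 9)
        rot = ndimage.rotate(img, 30.0, reshape=False, order=3)

        def dominant(image):
            f = orientation_field(image, tensor_sigma=3)
            crop = np.zeros(image.shape, dtype=bool)
            crop[98:158, 98:158] = True
            w = f.energy[crop]
            th = f.theta[crop]
            vec = np.array([np.sum(w * np.cos(2 * th)), np.sum(w * np.sin(2 * th))])
            return 0.5 * np.arctan2(vec[1], vec[0]) % np.pi

        delta = (dominant(rot) - dominant(img)) % np.pi
        delta = min(delta, np.pi - delta)
        assert delta == pytest.approx(np.deg2rad(30), abs=np.deg2rad(2))


class TestScores:
    def test_radial_scene_scores_high(self, geometry):
        f = orientation_field(_mt_scene(geometry, "radial"))
        s = radial_alignment_score(f, geometry.centrosome, mask=geometry.cell_mask())
        assert s >= 0.95

    def test_concentric_rings_score_tangential(self):
        rr, cc = np.mgrid[0:128, 0:128]
        r = np.sqrt((rr - 64.0) ** 2 + (cc - 64.0) ** 2)
        img = np.sin(2 * np.pi * r / 9)
        f = orientation_field(img, tensor_sigma=2)
        s = radial_alignment_score(f, (64.0, 64.0))
        assert s <= -0.9

    def test_isotropic_noise_scores_near_zero(self):
        img = np.random.default_rng(0).normal(size=(256, 256))
        f = orientation_field(img, tensor_sigma=2)
        assert abs(radial_alignment_score(f, (128.0, 128.0))) <= 0.1
        assert parallel_order_score(f) <= 0.1

    def test_parallel_scene_has_unit_order(self, geometry):
        f = orientation_field(_mt_scene(geometry, "parallel"))
        assert parallel_order_score(f, mask=geometry.cell_mask()) >= 0.95

    def test_radial_scene_has_low_order(self, geometry):
        f = orientation_field(_mt_scene(geometry, "radial"))
        assert parallel_order_score(f, mask=geometry.cell_mask()) <= 0.35

    def test_scores_invariant_to_intensity_scaling(self, geometry):
        img = _mt_scene(geometry, "radial")
        f1 = orientation_field(img)
        f2 = orientation_field(img * 7.5)
        m = geometry.cell_mask()
        assert parallel_order_score(f1, mask=m) == pytest.approx(
            parallel_order_score(f2, mask=m), abs=1e-9)

    def test_scores_invariant_under_quarter_rotation(self, geometry):
        img = _mt_scene(geometry, "parallel")
        mask = geometry.cell_mask()
        f0 = orientation_field(img)
        f1 = orientation_field(np.rot90(img).copy())
        S0 = parallel_order_score(f0, mask=mask)
        S1 = parallel_order_score(f1, mask=np.rot90(mask).copy())
        assert S0 == pytest.approx(S1, abs=1e-3)
        c = geometry.centrosome
        c_rot = (img.shape[1] - 1 - c[1], c[0])  # np.rot90 coordinate map
        s0 = radial_alignment_score(f0, c, mask=mask)
        s1 = radial_alignment_score(f1, c_rot, mask=np.rot90(mask).copy())
        assert s0 == pytest.approx(s1, abs=1e-3)


class TestCentrosome:
    def test_estimate_close_to_true_focus(self, geometry):
        f = orientation_field(_mt_scene(geometry, "radial"))
        center, score, confident = estimate_centrosome(f, geometry.cell_mask())
        assert confident
        assert np.hypot(center[0] - geometry.centrosome[0],
                        center[1] - geometry.centrosome[1]) <= 5.0

    def test_parallel_field_flagged_low_confidence(self, geometry):
        f = orientation_field(_mt_scene(geometry, "parallel"))
        _, score, confident = estimate_centrosome(f, geometry.cell_mask())
        assert not confident

    def test_translation_equivariance(self, geometry):
        img = _mt_scene(geometry, "radial")
        mask = geometry.cell_mask()
        f0 = orientation_field(img)
        c0, _, _ = estimate_centrosome(f0, mask)
        shift = 12
        f1 = orientation_field(np.roll(img, shift, axis=0))
        c1, _, _ = estimate_centrosome(f1, np.roll(mask, shift, axis=0))
        assert c1[0] - c0[0] == pytest.approx(shift, abs=3)
        assert c1[1] - c0[1] == pytest.approx(0, abs=3)


class TestClassify:
    @pytest.mark.parametrize("s_r,S,expected", [
        (0.9, 0.1, 1),   # radial, low order
        (0.9, 0.8, 3),   # high order dominates
        (0.5, 0.45, 2),  # intermediate order
        (0.1, 0.2, 2),   # neither radial nor parallel
    ])
    def test_rule_table(self, s_r, S, expected):
        assert classify_mt(s_r, S) == expected

    @pytest.mark.parametrize("field_type,expected", [
        ("radial", 1), ("mixed", 2), ("parallel", 3)])
    def test_end_to_end_scene_classes(self, geometry, field_type, expected):
        stack, _ = render_scene(
            geometry, ActinSpec.for_class(4), MitoSpec(n_objects=0),
            MTSpec(field_type=field_type), ImagingSpec.noiseless(seed=2))
        res = score_cell(stack[3], geometry.cell_mask())
        assert res.mt_class == expected
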