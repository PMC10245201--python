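import numpy as np
import pandas as pd
import pytest

from warnsig.errors import (AlignmentError, CalibrationError, GeometryError,
                            NoPatternPixelsError)
from warnsig.phenotyping import (Transect, align_head_pattern, color_correct,
                                 count_transitions, default_transects,
                                 extract_region_color, phenotype_image)
from warnsig.synth import default_render_spec, records_from_table, render_frog
from warnsig.types import FrogImage, Patch


def make_record(**kw):
    base = dict(individual_id="f0", species="A", locality="X",
                hue_head=45.0, sat_head=0.9, hue_back=120.0, sat_back=0.8,
                hue_limb=200.0, sat_limb=0.7, dorsal_transitions_left=6,
                dorsal_transitions_right=6, limb_transitions=2,
                pattern_class="spotted", jitter_seed=42)
    base.update(kw)
    return records_from_table(pd.DataFrame([base]))[0]


def tiny_image(colors, region="dorsum"):
    """A 5xN image whose middle row carries the given RGB sequence."""
    n = len(colors)
    raster = np.zeros((5, n, 3))
    raster[2] = colors
    masks = {region: np.ones((5, n), dtype=bool)}
    return FrogImage(raster=raster, landmarks={}, masks=masks)


MILD_CAST = dict(
    cast_matrix=np.array([[0.80, 0.05, 0.00],
                          [0.02, 0.75, 0.03],
                          [0.00, 0.04, 0.70]]),
    cast_offset=np.array([0.02, 0.01, 0.03]))


class TestColorCorrect:
    def test_identity_cast_gives_identity_fit(self):
        img = render_frog(make_record())
        corrected, report = color_correct(img)
        assert report.residuals.max() < 1e-6
        assert np.allclose(report.matrix, np.eye(3), atol=1e-8)
        assert np.allclose(report.offset, 0.0, atol=1e-8)
        assert np.allclose(corrected.raster, img.raster, atol=1e-8)

    def test_scaled_cast_recovered(self):
        # oracle: the known cast is 0.8*I, so corrected patches must equal
        # the true patch RGB within 2/255 per channel
        spec = default_render_spec(cast_matrix=0.8 * np.eye(3))
        img = render_frog(make_record(), spec)
        corrected, _ = color_correct(img)
        for p in img.patches:
            observed = corrected.raster[p.row0:p.row1, p.col0:p.col1]
            assert np.abs(observed - p.true_rgb).max() < 2 / 255

    def test_three_patches_insufficient(self):
        img = render_frog(make_record())
        img.patches = img.patches[:3]
        with pytest.raises(CalibrationError):
            color_correct(img)

    def test_degenerate_patches_rejected(self):
        img = render_frog(make_record())
        grey = Patch(2, 14, 8, 20, (0.5, 0.5, 0.5))
        img.patches = [grey] * 5
        img.raster[2:14, 8:20] = 0.5
        with pytest.raises(CalibrationError):
            color_correct(img)


class TestExtractRegionColor:
    def test_pure_red_region(self):
        img = tiny_image(np.tile([1.0, 0.0, 0.0], (4, 1)))
        rc = extract_region_color(img, "dorsum")
        assert rc.hue == pytest.approx(0.0, abs=1e-9)
        assert rc.saturation == pytest.approx(1.0)

    def test_circular_mean_across_wraparound(self):
        from skimage.color import hsv2rgb
        cols = hsv2rgb(np.array([[[350 / 360, 1.0, 1.0], [10 / 360, 1.0, 1.0]]]))[0]
        img = tiny_image(np.repeat(cols, 2, axis=0))
        rc = extract_region_color(img, "dorsum")
        assert min(rc.hue, 360 - rc.hue) == pytest.approx(0.0, abs=1e-6)

    def test_generator_round_trip(self):
        img = render_frog(make_record(hue_head=45.0, sat_head=0.9))
        rc = extract_region_color(img, "head")
        assert abs(rc.hue - 45.0) < 2.0
        assert abs(rc.saturation - 0.9) < 0.02

    def test_empty_region_raises(self):
        img = tiny_image(np.zeros((4, 3)))
        with pytest.raises(NoPatternPixelsError):
            extract_region_color(img, "dorsum")


class TestAlignHeadPattern:
    def test_template_pose_is_identity(self, render_spec):
        img = render_frog(make_record(), render_spec)
        raster = align_head_pattern(img, render_spec.landmarks, grid_size=64)
        # oracle: the image is already in template pose, so the raster equals
        # direct nearest-pixel sampling of the binarized head pattern on the
        # template head window (head_left..head_right x snout..neck)
        from warnsig.phenotyping import brightness
        lm = render_spec.landmarks
        x0, x1 = lm["head_left"][0], lm["head_right"][0]
        y0, y1 = lm["snout"][1], lm["neck"][1]
        pattern = img.masks["head"] & (brightness(img.raster) > 0.2)
        xs = np.rint(x0 + (np.arange(64) + 0.5) * (x1 - x0) / 64).astype(int)
        ys = np.rint(y0 + (np.arange(64) + 0.5) * (y1 - y0) / 64).astype(int)
        direct = pattern[np.ix_(ys, xs)]
        assert np.array_equal(raster, direct)

    def test_translation_invariance(self, render_spec):
        img = render_frog(make_record(), render_spec)
        moved = render_frog(make_record(),
                            default_render_spec(translation=(10.0, 5.0)))
        a = align_head_pattern(img, render_spec.landmarks, grid_size=64)
        b = align_head_pattern(moved, render_spec.landmarks, grid_size=64)
        assert (a != b).mean() < 0.02

    def test_rotation_mismatch_small(self, render_spec):
        img = render_frog(make_record(), render_spec)
        rotated = render_frog(make_record(),
                              default_render_spec(rotation_deg=10.0))
        a = align_head_pattern(img, render_spec.landmarks, grid_size=64)
        b = align_head_pattern(rotated, render_spec.landmarks, grid_size=64)
        assert (a != b).mean() < 0.05

    def test_similarity_transform_invariance(self, render_spec):
        img = render_frog(make_record(), render_spec)
        moved = render_frog(make_record(), default_render_spec(
            rotation_deg=-8.0, translation=(-6.0, 4.0), scale=0.95))
        a = align_head_pattern(img, render_spec.landmarks, grid_size=64)
        b = align_head_pattern(moved, render_spec.landmarks, grid_size=64)
        assert (a != b).mean() < 0.05

    def test_collinear_landmarks_rejected(self, render_spec):
        img = render_frog(make_record(), render_spec)
        img.landmarks = {name: (float(i), float(i)) for i, name
                         in enumerate(img.landmarks)}
        with pytest.raises(AlignmentError):
            align_head_pattern(img, render_spec.landmarks)


class TestCountTransitions:
    def test_alternating_sequence(self):
        yellow = [1.0, 1.0, 0.0]
        black = [0.0, 0.0, 0.0]
        img = tiny_image(np.array([black, yellow, black, yellow, black]))
        t = Transect(np.array([[0.0, 2.0], [4.0, 2.0]]), "dorsal_left")
        assert count_transitions(img, t) == 4

    def test_uniform_transect_zero(self):
        img = tiny_image(np.tile([0.2, 0.9, 0.2], (6, 1)))
        t = Transect(np.array([[0.0, 2.0], [5.0, 2.0]]), "dorsal_left")
        assert count_transitions(img, t) == 0

    def test_three_bands_give_six(self, render_spec):
        img = render_frog(make_record(dorsal_transitions_left=6,
                                      dorsal_transitions_right=6), render_spec)
        tr = default_transects(img.landmarks)
        assert count_transitions(img, tr["dorsal_left"]) == 6
        assert count_transitions(img, tr["dorsal_right"]) == 6

    def test_reversal_invariance(self, render_spec):
        img = render_frog(make_record(), render_spec)
        tr = default_transects(img.landmarks)["dorsal_left"]
        fwd = count_transitions(img, tr)
        rev = count_transitions(
            img, Transect(tr.points[::-1].copy(), tr.role))
        assert fwd == rev

    def test_outside_mask_raises(self):
        img = tiny_image(np.tile([0.9, 0.9, 0.0], (6, 1)))
        img.masks["dorsum"][:, 0] = False
        t = Transect(np.array([[0.0, 2.0], [5.0, 2.0]]), "dorsal_left")
        with pytest.raises(GeometryError):
            count_transitions(img, t)


class TestPhenotypeImage:
    def test_round_trip_matches_ground_truth(self, render_spec):
        rec = make_record()
        img = render_frog(rec, render_spec)
        measured, raster = phenotype_image(
            img, render_spec.landmarks, rec.pattern_class, rec.individual_id,
            rec.species, rec.locality)
        for region in ("head", "back", "limb"):
            true_h = getattr(rec, f"hue_{region}")
            got_h = getattr(measured, f"hue_{region}")
            assert abs((got_h - true_h + 180) % 360 - 180) < 2.0
            assert abs(getattr(measured, f"sat_{region}")
                       - getattr(rec, f"sat_{region}")) < 0.02
        assert measured.dorsal_transitions_left == rec.dorsal_transitions_left
        assert measured.dorsal_transitions_right == rec.dorsal_transitions_right
        assert measured.limb_transitions == rec.limb_transitions
        assert raster.shape == (64, 64)

    def test_empty_limb_mask_raises(self, render_spec):
        img = render_frog(make_record(), render_spec)
        img.masks["limb"][:] = False
        with pytest.raises(NoPatternPixelsError):
            phenotype_image(img, render_spec.landmarks, "spotted")

    def test_jitter_does_not_change_transition_counts(self, render_spec):
        rec = make_record()
        a = render_frog(rec, render_spec, jitter_seed=1)
        b = render_frog(rec, render_spec, jitter_seed=2)
        for img in (a, b):
            tr = default_transects(img.landmarks)
            assert count_transitions(img, tr["dorsal_left"]) == 6
            assert count_transitions(img, tr["limb"]) == 2

    def test_affine_cast_invariance(self, render_spec):
        rec = make_record()
        plain = render_frog(rec, render_spec)
        cast = render_frog(rec, default_render_spec(**MILD_CAST))
        corrected, _ = color_correct(cast)
        for img_a, img_b in ((plain, corrected),):
            for region in ("head", "dorsum", "limb"):
                a = extract_region_color(img_a, region)
                b = extract_region_color(img_b, region)
                assert abs((a.hue - b.hue + 180) % 360 - 180) < 2.0
                assert abs(a.saturation - b.saturation) < 0.02
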