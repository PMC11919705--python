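"""Nucleus segmentation, focus detection, classification, aggregation."""

import numpy as np
import pytest

from catfish.errors import DataError, ParameterError
from catfish.imagequant import (
    Ellipse,
    ROI,
    SegmentationParams,
    Spot,
    SpotParams,
    ZStack,
    assign_and_classify,
    class_fractions,
    detect_spots,
    quantify_roi,
    segment_nuclei,
)
from catfish.synth import GroundTruthNucleus, render_zstack


def _disc(img, cx, cy, r, value=100.0):
    ny, nx = img.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    img[(xx - cx) ** 2 + (yy - cy) ** 2 <= r**2] = value


class TestSegmentNuclei:
    def test_disjoint_ellipses_recovered(self):
        centers = [(30, 30), (90, 30), (30, 90), (90, 90), (60, 60)]
        nuclei = [
            GroundTruthNucleus(
                id=i, center=(float(x), float(y)), axes=(8.0, 6.0),
                angle=0.5 * i, z_layer=0, active_first=False,
                active_second=False, n_dots_first=0, n_dots_second=0,
            )
            for i, (x, y) in enumerate(centers)
        ]
        stack = render_zstack(nuclei, (120, 120), noise=(0.0, 0.0), rng_seed=0)
        ellipses = segment_nuclei(stack.channel("dapi")[0])
        assert len(ellipses) == 5
        found = sorted((e.cx, e.cy) for e in ellipses)
        for (fx, fy), (tx, ty) in zip(found, sorted(centers)):
            assert abs(fx - tx) <= 1.0 and abs(fy - ty) <= 1.0

    def test_axes_and_angle_recovered(self):
        nuc = GroundTruthNucleus(
            id=0, center=(40.0, 40.0), axes=(10.0, 5.0), angle=0.6, z_layer=0,
            active_first=False, active_second=False,
            n_dots_first=0, n_dots_second=0,
        )
        stack = render_zstack([nuc], (80, 80), noise=(0.0, 0.0), rng_seed=0,
                              psf_sigma=0.8)
        (e,) = segment_nuclei(stack.channel("dapi")[0])
        assert e.a == pytest.approx(10.0, abs=1.0)
        assert e.b == pytest.approx(5.0, abs=1.0)
        assert e.angle == pytest.approx(0.6, abs=0.1)

    def test_blank_and_constant_images_give_empty_list(self):
        assert segment_nuclei(np.zeros((64, 64))) == []
        assert segment_nuclei(np.full((64, 64), 7.0)) == []

    def test_touching_discs_split_by_watershed(self):
        img = np.zeros((80, 80))
        r = 12
        # centers 1.8*r apart: the discs overlap by 20% of a radius
        _disc(img, 28, 40, r)
        _disc(img, 28 + int(1.8 * r), 40, r)
        ellipses = segment_nuclei(
            img, SegmentationParams(smoothing_sigma=1.0, min_area=50)
        )
        assert len(ellipses) == 2

    def test_invalid_params_raise(self):
        with pytest.raises(ParameterError):
            segment_nuclei(np.zeros((8, 8)), SegmentationParams(smoothing_sigma=-1))
        with pytest.raises(ParameterError):
            segment_nuclei(np.zeros((8, 8, 3)))

    def test_translation_equivariance(self):
        img = np.zeros((100, 100))
        _disc(img, 30, 40, 9)
        (e1,) = segment_nuclei(img)
        (e2,) = segment_nuclei(np.roll(img, (7, 13), axis=(0, 1)))
        assert e2.cx - e1.cx == pytest.approx(13, abs=0.01)
        assert e2.cy - e1.cy == pytest.approx(7, abs=0.01)


def _gauss_spot(img, x0, y0, sigma=1.2, amp=100.0):
    ny, nx = img.shape
    yy, xx = np.mgrid[0:ny, 0:nx]
    img += amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2))


class TestDetectSpots:
    def test_single_spot_subpixel(self):
        img = np.zeros((64, 64))
        _gauss_spot(img, 31.4, 22.7)
        img += np.random.default_rng(0).normal(0, 10.0, img.shape)  # SNR ~ 10
        spots = detect_spots(img, SpotParams(sigma=1.2, threshold=20.0))
        assert len(spots) == 1
        assert spots[0].x == pytest.approx(31.4, abs=0.5)
        assert spots[0].y == pytest.approx(22.7, abs=0.5)

    def test_two_spots_at_five_sigma_separation(self):
        img = np.zeros((64, 64))
        _gauss_spot(img, 25.0, 30.0)
        _gauss_spot(img, 31.0, 30.0)  # 5 * sigma apart
        spots = detect_spots(img, SpotParams(sigma=1.2, threshold=20.0))
        assert len(spots) == 2

    def test_pure_noise_mostly_clean_at_high_threshold(self):
        # threshold at ~6.5 noise SD of the LoG response: expected false
        # positives well below 1 per 1e5 px, so most 256x256 fields are clean
        rng_master = np.random.default_rng(42)
        sd = 2.0
        clean = 0
        n_fields = 20
        for _ in range(n_fields):
            img = rng_master.normal(0, sd, (256, 256))
            resp_sd = sd * 0.55  # empirical LoG response SD factor at sigma=1.2
            spots = detect_spots(img, SpotParams(sigma=1.2, threshold=6.5 * resp_sd))
            clean += len(spots) == 0
        assert clean >= n_fields * 0.6

    def test_bad_sigma_raises(self):
        with pytest.raises(ParameterError):
            detect_spots(np.zeros((8, 8)), SpotParams(sigma=0))


class TestAssignAndClassify:
    @pytest.mark.parametrize(
        "arc,homer,expected",
        [(2, 0, "arc_only"), (1, 1, "both"), (0, 0, "negative"), (0, 3, "homer_only")],
    )
    def test_klass_from_counts(self, arc, homer, expected):
        e = Ellipse(cx=20, cy=20, a=8, b=6, angle=0.0)
        spots = {
            "arc": [Spot(20 + i, 20, 0, "arc", 1.0) for i in range(arc)],
            "homer": [Spot(20, 20 - i, 0, "homer", 1.0) for i in range(homer)],
        }
        (rec,) = assign_and_classify([e], spots)
        assert rec.klass == expected
        assert rec.arc_dots == arc and rec.homer_dots == homer

    def test_raising_threshold_demotes_single_dot_nuclei(self):
        e = Ellipse(cx=20, cy=20, a=8, b=6, angle=0.0)
        spots = {"arc": [Spot(20, 20, 0, "arc", 1.0)], "homer": []}
        (rec1,) = assign_and_classify([e], spots, positivity_threshold=1)
        (rec2,) = assign_and_classify([e], spots, positivity_threshold=2)
        assert rec1.klass == "arc_only" and rec2.klass == "negative"

    def test_overlapping_ellipses_spot_goes_to_deepest(self):
        e1 = Ellipse(cx=20, cy=20, a=8, b=8, angle=0.0)
        e2 = Ellipse(cx=30, cy=20, a=8, b=8, angle=0.0)
        # x=26 is inside both; normalised value 0.5625 for e1, 0.25 for e2
        spots = {"arc": [Spot(26, 20, 0, "arc", 1.0)], "homer": []}
        recs = assign_and_classify([e1, e2], spots)
        assert recs[0].arc_dots == 0 and recs[1].arc_dots == 1

    def test_nuclei_outside_roi_dropped(self):
        e_in = Ellipse(cx=20, cy=20, a=5, b=5, angle=0.0)
        e_out = Ellipse(cx=70, cy=70, a=5, b=5, angle=0.0)
        roi = ROI(structure="DG", polygon=np.array([(5, 5), (40, 5), (40, 40), (5, 40)]))
        recs = assign_and_classify([e_in, e_out], {"arc": [], "homer": []},
                                   roi=roi, shape=(80, 80))
        assert len(recs) == 1 and recs[0].ellipse.cx == 20


class TestQuantifyRoi:
    def test_too_few_layers_names_trimming_rule(self, small_field):
        stack6 = ZStack(small_field["stack"].pixels[:, :6])
        with pytest.raises(ParameterError, match="trimming"):
            quantify_roi(stack6, [small_field["roi"]])

    def test_eight_layer_stack_uses_two_retained_layers(self, small_field):
        pix = small_field["stack"].pixels
        stack8 = ZStack(np.concatenate([pix, pix[:, :1]], axis=1))
        rec = quantify_roi(stack8, [small_field["roi"]])
        assert rec.n_layers_used == 2

    def test_fractions_sum_to_one(self, small_field):
        rec = quantify_roi(small_field["stack"], [small_field["roi"]])
        total = rec.f_both + rec.f_arc_only + rec.f_homer_only + rec.f_negative
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_identical_layers_median_equals_single_layer(self, small_field):
        one = small_field["stack"].pixels[:, 3:4]
        stack = ZStack(np.concatenate([one] * 7, axis=1))
        rec7 = quantify_roi(stack, [small_field["roi"]])
        stack9 = ZStack(np.concatenate([one] * 9, axis=1))
        rec9 = quantify_roi(stack9, [small_field["roi"]])
        for attr in ("f_both", "f_arc_only", "f_homer_only", "f_negative"):
            assert getattr(rec7, attr) == pytest.approx(getattr(rec9, attr))

    def test_noise_free_recovery_is_exact(self):
        from catfish.synth import ActivityModel, sample_nuclei, true_fractions
        from conftest import square_polygon

        shape = (256, 256)
        poly = square_polygon(shape)
        nuclei = sample_nuclei(
            poly, 25 / (240**2), ActivityModel(0.4, 0.3, rho=0.2),
            n_layers=7, rng_seed=21,
        )
        stack = render_zstack(nuclei, shape, noise=(0.0, 0.0), rng_seed=21,
                              n_layers=7)
        roi = ROI(structure="CA1", polygon=np.asarray(poly, float))
        rec = quantify_roi(stack, [roi])
        truth = true_fractions([u for u in nuclei if u.z_layer == 3])
        assert rec.f_both == pytest.approx(truth["both"])
        assert rec.f_arc_only == pytest.approx(truth["arc_only"])
        assert rec.f_homer_only == pytest.approx(truth["homer_only"])
        assert rec.f_negative == pytest.approx(truth["negative"])

    def test_hemisphere_pooling_weights_by_cell_count(self):
        # pooling concatenates nucleus lists before fractions, so a 3:1
        # hemisphere size imbalance weights the bigger side 3x
        left = [
            Ellipse(cx=10 + 12 * i, cy=12, a=5, b=5, angle=0.0) for i in range(3)
        ]
        right = [Ellipse(cx=20, cy=50, a=5, b=5, angle=0.0)]
        spots = {"arc": [Spot(20, 50, 0, "arc", 1.0)], "homer": []}
        recs = assign_and_classify(left + right, spots)
        fr = class_fractions(recs)
        assert fr["arc_only"] == pytest.approx(0.25)
        assert fr["negative"] == pytest.approx(0.75)


class TestZStackIO:
    def test_tiff_round_trip(self, tmp_path, small_field):
        path = tmp_path / "field.tiff"
        small_field["stack"].save(path)
        loaded = ZStack.load(path)
        assert loaded.pixels.shape == small_field["stack"].pixels.shape
        np.testing.assert_allclose(loaded.pixels, small_field["stack"].pixels)
        assert loaded.channel_names == small_field["stack"].channel_names

    def test_wrong_channel_count_rejected(self):
        with pytest.raises(ParameterError):
            ZStack(np.zeros((2, 3, 8, 8)))
        with pytest.raises(DataError):
            ZStack(np.full((3, 1, 4, 4), -1.0))
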