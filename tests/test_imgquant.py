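"""Image quantification: segmentation, corrections, fronts, kinematics
and event landmarks."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from skimage.filters import threshold_otsu

import frontcompete as fc
from frontcompete.imgquant import (_branch_masks, _skeleton_length,
                                   annotate_event, edge_speeds,
                                   fret_ratio, front_activity,
                                   front_region, kinetics,
                                   ratio_correction_image, segment)


class TestOtsu:
    def test_two_delta_histogram_brute_force(self):
        """Otsu's cut on {100 px @ 1, 100 px @ 10} maximises between-class
        variance, verified by exhaustive search over cut points."""
        img = np.concatenate([np.ones(100), np.full(100, 10.0)])
        thr = threshold_otsu(img, nbins=256)

        def between_class_var(t):
            lo, hi = img[img <= t], img[img > t]
            if lo.size == 0 or hi.size == 0:
                return -np.inf
            w0, w1 = lo.size / img.size, hi.size / img.size
            return w0 * w1 * (lo.mean() - hi.mean()) ** 2

        candidates = np.linspace(img.min(), img.max(), 512)
        best = candidates[np.argmax([between_class_var(t)
                                     for t in candidates])]
        assert between_class_var(thr) == pytest.approx(
            between_class_var(best))
        assert 1.0 < thr < 10.0


class TestSegment:
    def test_synthetic_cell_iou(self, one_movie):
        """Segmentation of a synthetic frame (signal ~10x background,
        moderate noise) recovers the ground-truth mask with IoU >= 0.90."""
        ious = []
        for t in (8, 15, 22):
            fr = one_movie.frames[t]
            img = fr.channels["fret_donor"] + fr.channels["fret_acceptor"]
            m = segment(img)
            inter = (m & fr.mask).sum()
            union = (m | fr.mask).sum()
            ious.append(inter / union)
        assert min(ious) >= 0.90

    def test_all_zero_image_error(self):
        with pytest.raises(ValueError):
            segment(np.zeros((64, 64)))

    def test_constant_image_error(self):
        with pytest.raises(ValueError):
            segment(np.full((64, 64), 3.0))

    def test_largest_component_retained(self):
        rng = np.random.default_rng(0)
        img = rng.normal(10, 0.5, (80, 80))
        img[20:50, 20:50] += 100.0      # big cell
        img[65:70, 65:70] += 100.0      # small debris
        m = segment(img)
        assert m[30, 30] and not m[67, 67]


class TestRatioCorrection:
    def test_flat_field_identity(self):
        corr = ratio_correction_image(np.ones((3, 96, 72)),
                                      np.ones((3, 96, 72), bool))
        assert np.max(np.abs(corr - 1.0)) < 0.01

    def test_imposed_ramp_flattened(self):
        """Dividing by the estimated correction flattens a 10% linear
        top-to-bottom ramp to < 2% row-mean spread."""
        h, w = 144, 96
        ramp = 1.0 + 0.1 * (0.5 - np.arange(h) / (h - 1))
        field = np.tile(ramp[:, None], (1, w))
        rng = np.random.default_rng(0)
        stack, masks = [], []
        for t in range(6):
            m = np.zeros((h, w), bool)
            r0 = rng.integers(0, h - 40)
            c0 = rng.integers(0, w - 40)
            m[r0:r0 + 40, c0:c0 + 40] = True
            stack.append(field)
            masks.append(m)
        masks[0] = np.ones((h, w), bool)     # guarantee coverage
        corr = ratio_correction_image(np.stack(stack), np.stack(masks))
        flat = field / corr
        rm = flat.mean(axis=1)
        assert (rm.max() - rm.min()) / rm.mean() < 0.02

    def test_idempotence(self):
        """Re-estimating the correction on already-corrected data yields a
        field within 1% of unity."""
        h, w = 144, 96
        ramp = 1.0 + 0.1 * (0.5 - np.arange(h) / (h - 1))
        field = np.tile(ramp[:, None], (1, w))
        stack = np.stack([field] * 4)
        masks = np.ones_like(stack, bool)
        corr = ratio_correction_image(stack, masks)
        corr2 = ratio_correction_image(stack / corr, masks)
        assert np.max(np.abs(corr2 - 1.0)) < 0.01

    def test_empty_blocks_filled_with_warning(self):
        stack = np.full((2, 96, 96), 2.0)
        masks = np.zeros_like(stack, bool)
        masks[:, :48, :] = True            # bottom half never covered
        with pytest.warns(UserWarning, match="blocks"):
            corr = ratio_correction_image(stack, masks)
        assert np.all(corr > 0)
        assert np.allclose(corr, 2.0, rtol=0.02)


class TestFretRatio:
    def test_uniform_ratio_and_mask_nan(self):
        mask = np.zeros((20, 20), bool)
        mask[5:15, 5:15] = True
        donor = np.full((20, 20), 2.0)
        acceptor = np.full((20, 20), 4.0)
        r = fret_ratio(donor, acceptor, mask)
        assert np.allclose(r[mask], 2.0)
        assert np.all(np.isnan(r[~mask]))

    def test_correction_scaling(self):
        mask = np.ones((10, 10), bool)
        r = fret_ratio(np.full((10, 10), 2.0), np.full((10, 10), 4.0),
                       mask, correction=np.full((10, 10), 2.0))
        assert np.allclose(r, 1.0)

    def test_nonpositive_donor_marked_missing(self):
        mask = np.ones((5, 5), bool)
        donor = np.ones((5, 5))
        donor[2, 2] = 0.0
        with pytest.warns(UserWarning, match="non-positive"):
            r = fret_ratio(donor, np.ones((5, 5)), mask)
        assert np.isnan(r[2, 2]) and np.isfinite(r[0, 0])

    def test_generator_truth_recovered(self, one_movie):
        """The measured in-mask ratio matches the generator's truth field
        (1 + front boost) within noise."""
        fr = one_movie.frames[15]
        donor = fr.channels["fret_donor"] - 10.0     # background level
        acceptor = fr.channels["fret_acceptor"] - 10.0
        r = fret_ratio(donor, acceptor, fr.mask)
        vals = r[fr.mask]
        vals = vals[np.isfinite(vals)]
        assert 1.0 < np.nanmedian(vals) < 1.8
        body = np.nanmedian(vals)
        assert abs(body - np.nanmedian(vals)) < 0.1


class TestFrontRegion:
    def test_region_size_capped_at_400(self, geometry, one_movie):
        ann = annotate_event(one_movie)
        fr = one_movie.frames[-6]
        edge, region = front_region(fr.mask, geometry, ann.outcome)
        assert len(region) == 400
        assert fr.mask[region[:, 0], region[:, 1]].all()

    def test_small_branch_returns_all_with_warning(self, geometry):
        # fronts only 2.5 um past the apex: well under 400 branch pixels
        mask = geometry.rasterise_cell(-10.0, 0.0, 2.5, 2.5)
        label, _ = geometry._regions()
        n_branch = int((mask & (label == 2)).sum())
        assert 0 < n_branch < 400
        with pytest.warns(UserWarning, match="available"):
            _, region = front_region(mask, geometry, "left")
        assert len(region) == n_branch

    def test_matches_brute_force_sort(self, geometry, one_movie):
        """Every excluded in-branch pixel is at least as far from the edge
        as every included pixel (exhaustive distance sort)."""
        fr = one_movie.frames[-6]
        label, _ = geometry._regions()
        for side, code in (("left", 2), ("right", 3)):
            edge, region = front_region(fr.mask, geometry, side)
            cand = np.column_stack(np.nonzero(fr.mask & (label == code)))
            d = np.hypot(cand[:, 0] - edge[0], cand[:, 1] - edge[1])
            ranked = sorted(zip(d, cand[:, 0], cand[:, 1]))
            expect = {(r, c) for _, r, c in ranked[:400]}
            got = {tuple(p) for p in region}
            # identical up to ties at the cut distance
            dmax = max(dd for dd, r, c in ranked[:400])
            strict = {(r, c) for dd, r, c in ranked if dd < dmax - 1e-12}
            assert strict <= got
            included_d = np.hypot(region[:, 0] - edge[0],
                                  region[:, 1] - edge[1])
            excluded = [dd for dd, r, c in ranked if (r, c) not in got]
            if excluded:
                assert min(excluded) >= included_d.max() - 1e-12

    def test_absent_branch_error(self, geometry):
        mask = np.zeros(geometry.image_shape, bool)
        mask[160:175, 65:85] = True       # stem only
        with pytest.raises(ValueError, match="absent"):
            front_region(mask, geometry, "left")


class TestFrontActivity:
    def test_sum_of_sums(self):
        donor = np.full((10, 10), 4.0)
        acceptor = np.full((10, 10), 8.0)
        region = np.array([[r, c] for r in range(10) for c in range(10)])
        assert front_activity(donor, acceptor, region) == 2.0

    def test_single_pixel(self):
        donor = np.array([[2.0]])
        acceptor = np.array([[3.0]])
        assert front_activity(donor, acceptor,
                              np.array([[0, 0]])) == pytest.approx(1.5)

    def test_bleach_correction_flattens_series(self):
        """A constant truth ratio under linear bleach, divided by the known
        model, gives a flat corrected series."""
        truth = np.full((30, 30), 2.0)
        slope_loss = 0.01
        region = np.array([[r, c] for r in range(30) for c in range(30)])
        series = []
        for t in range(25):
            p = fc.GeneratorParams(n_events=1, bleach_slope=slope_loss,
                                   noise_sd=0.0)
            d, a = fc.generate_fret_pair(truth, p, frame_index=t)
            series.append(front_activity(d, a, region,
                                         bleach_slope=-slope_loss,
                                         frame_index=t))
        series = np.array(series)
        fitted = np.polyfit(np.arange(25), series, 1)[0]
        assert abs(fitted) < 1e-9
        assert np.allclose(series, 2.0)

    def test_zero_donor_error(self):
        with pytest.raises(ValueError):
            front_activity(np.zeros((3, 3)), np.ones((3, 3)),
                           np.array([[0, 0]]))


class TestEdgeSpeeds:
    def test_hand_counted_example(self):
        """+10 px, -4 px at dt = 6 s and 0.21 um pixels: protrusion
        10 * 0.0441 / 0.1 = 4.41, retraction 1.764 um^2/min."""
        m1 = np.zeros((20, 20), bool)
        m1[5:10, 5:10] = True
        m2 = m1.copy()
        m2[10:12, 5:10] = True          # +10 px
        m2[5:9, 5] = False              # -4 px
        prot, ret = edge_speeds(m1, m2, 6.0, 0.21)
        assert prot == pytest.approx(4.41)
        assert ret == pytest.approx(1.764)

    def test_identical_masks_zero(self):
        m = np.ones((8, 8), bool)
        assert edge_speeds(m, m, 6.0) == (0.0, 0.0)

    def test_dt_positive_required(self):
        m = np.ones((4, 4), bool)
        with pytest.raises(ValueError):
            edge_speeds(m, m, 0.0)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(a=hnp.arrays(bool, (12, 12)), b=hnp.arrays(bool, (12, 12)))
    def test_area_bookkeeping_identity(self, a, b):
        """protruded - retracted equals the total mask-area change,
        exactly, for any pair of masks."""
        prot, ret = edge_speeds(a, b, 6.0, 0.21)
        dt_min = 0.1
        darea = (int(b.sum()) - int(a.sum())) * 0.21 ** 2 / dt_min
        assert prot - ret == pytest.approx(darea, abs=1e-12)


class TestKinetics:
    def test_straight_bar_length(self):
        bar = np.zeros((30, 120), bool)
        bar[10:20, 10:110] = True
        trace = kinetics(bar[None], 0)
        assert trace.length_um[0] == pytest.approx(100 * 0.21, rel=0.10)
        assert trace.area_um2[0] == pytest.approx(1000 * 0.21 ** 2)

    def test_y_shape_three_arms(self):
        """Three arms of ~50 px path length each: total within 10% of
        3 * 50 * 0.21 um."""
        Y = np.zeros((140, 140), bool)
        c = (75, 70)
        for k in range(50):            # vertical arm, 50 px
            Y[c[0] - k, c[1] - 2:c[1] + 3] = True
        for k in range(36):            # two diagonal arms, ~50 px long
            for dc in (-1, 1):
                r, cc = c[0] + k, c[1] + dc * k
                Y[r - 2:r + 3, cc - 2:cc + 3] = True
        trace = kinetics(Y[None], 0)
        assert trace.length_um[0] == pytest.approx(3 * 50 * 0.21,
                                                   rel=0.10)

    def test_relative_normalisation(self, one_movie):
        masks = one_movie.masks()
        trace = kinetics(masks, reference_frame=3)
        assert trace.rel_length[3] == 1.0
        assert trace.rel_area[3] == 1.0
        assert np.all(trace.area_um2 > 0)

    def test_cell_stretches_during_decision(self, one_movie):
        masks = one_movie.masks()
        trace = kinetics(masks, reference_frame=one_movie.contact_frame)
        assert trace.rel_length[one_movie.retraction_frame - 1] > 1.1

    def test_empty_mask_error(self):
        with pytest.raises(ValueError):
            kinetics(np.zeros((1, 5, 5), bool))


class TestAnnotate:
    def test_landmark_ordering_and_outcome(self, image_dataset):
        for movie, label in image_dataset.events:
            ann = annotate_event(movie)
            assert ann.contact_frame <= ann.retraction_init_frame
            if ann.big_retraction_frame is not None:
                assert ann.retraction_init_frame <= ann.big_retraction_frame
            assert ann.outcome == label.outcome
            assert ann.contact_frame == movie.contact_frame
            assert ann.retraction_init_frame == movie.retraction_frame
            assert ann.duration == movie.decision_duration

    def test_threshold_arithmetic(self, image_dataset):
        """With the 7.2 um^2 threshold, the big retraction fires at the
        first frame where cumulative retracted area strictly exceeds it
        (164 px at 0.21 um pixels)."""
        movie, _ = image_dataset.events[0]
        ann = annotate_event(movie, big_retraction_threshold=7.2)
        cum = ann.cumulative_retraction_um2
        k = ann.big_retraction_frame - ann.retraction_init_frame
        assert cum[k] > 7.2
        if k > 0:
            assert cum[k - 1] <= 7.2
        n_px = round(cum[k] / 0.21 ** 2)
        assert n_px >= 164          # 164 * 0.0441 = 7.2324 > 7.2

    def test_monotone_fronts_no_big_retraction(self, geometry):
        frames = []
        for k in range(8):
            mask = geometry.rasterise_cell(-10.0, 0.0, 1.0 + 0.4 * k,
                                           1.0 + 0.4 * k)
            frames.append(fc.FrameRecord(time=3.0 * k, mask=mask))
        # one frame of one-sided retraction to define the landmark
        frames.append(fc.FrameRecord(
            time=24.0, mask=geometry.rasterise_cell(-10.0, 0.0, 3.6,
                                                    1.0 + 0.4 * 7)))
        movie = fc.EventMovie(event_id="synthetic", frames=frames,
                              geometry=geometry, frame_interval=3.0,
                              channel_names=())
        ann = annotate_event(movie)
        assert ann.retracting_side == "left"
        assert ann.big_retraction_frame is None or \
            ann.cumulative_retraction_um2[-1] > 7.2

    def test_no_contact_error(self, geometry):
        frames = [fc.FrameRecord(time=3.0 * k,
                                 mask=geometry.rasterise_cell(-14.0,
                                                              -6.0))
                  for k in range(3)]
        movie = fc.EventMovie(event_id="far", frames=frames,
                              geometry=geometry, frame_interval=3.0,
                              channel_names=())
        with pytest.raises(ValueError, match="contact"):
            annotate_event(movie)


class TestQuantifyEvent:
    def test_trace_structure_and_activity(self, one_movie):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            trace = fc.quantify_event(one_movie)
        T = len(one_movie.frames)
        assert trace.times.shape == (T,)
        late = slice(one_movie.retraction_frame - 6,
                     one_movie.retraction_frame)
        for side in ("left", "right"):
            act = trace.activity[side][late]
            assert np.all(np.isfinite(act))
            assert np.all((act > 1.0) & (act < 2.2))
            assert np.all(np.diff(trace.extensions[side][late]) >= -1e-9)

    def test_to_dataframe(self, one_movie):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            df = fc.quantify_event(one_movie).to_dataframe()
        assert {"event_id", "frame", "side", "activity",
                "extension_um"} <= set(df.columns)
        assert len(df) == 2 * len(one_movie.frames)
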