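"""Detection stage: iterative thresholding with containment rules,
circularity, the cross-plane priority rule, and full-stack detection against
ground truth."""

import numpy as np
import pytest

from ablatio import detection as dt
from ablatio import synthgen as sg


def disc_image(shape=(64, 64), center=(32, 32), r=8, peak=3000):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    img = np.zeros(shape, dtype=np.uint16)
    img[d2 <= r * r] = peak
    return img


class TestCircularity:
    def test_ideal_circle_scores_one(self):
        r = 5.0
        assert dt.circularity(np.pi * r**2, 2 * np.pi * r) == pytest.approx(1.0)

    def test_square_scores_pi_over_four(self):
        s = 7.0
        assert dt.circularity(s * s, 4 * s) == pytest.approx(np.pi / 4)

    def test_elongated_rectangle_scores_low(self):
        # 1 x 10 rectangle: a = 10, p = 22 -> 40 pi / 484
        assert dt.circularity(10, 22) == pytest.approx(40 * np.pi / 484)

    def test_clipped_at_one(self):
        assert dt.circularity(100, 10) == 1.0

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            dt.circularity(0, 5)
        with pytest.raises(ValueError):
            dt.circularity(5, -1)

    def test_scale_invariance_of_rendered_discs(self):
        scores = []
        for r in (6, 12):
            rois = dt.iterative_threshold_rois(disc_image(r=r),
                                               area_range_px=(10, 2000))
            assert len(rois) == 1
            scores.append(rois[0].circularity)
        assert scores[0] == pytest.approx(scores[1], abs=0.05)


class TestIterativeThreshold:
    def test_blank_image_yields_empty_list(self):
        assert dt.iterative_threshold_rois(np.zeros((32, 32), np.uint16)) == []

    def test_single_disc_mask_covers_half_max_disc(self):
        """Oracle: a single global threshold at half the peak intensity."""
        img = disc_image(r=7)
        rois = dt.iterative_threshold_rois(img, area_range_px=(10, 1000))
        assert len(rois) == 1
        half_mask = set(zip(*np.nonzero(img > 1500)))
        assert half_mask <= rois[0].pixel_set()

    def test_two_close_discs_not_conflated(self):
        """Two discs that fuse only at low threshold stay two ROIs and the
        fused superset is absent."""
        img = np.zeros((64, 64), np.uint16)
        img += disc_image(center=(32, 20), r=6, peak=3000)
        img += disc_image(center=(32, 35), r=6, peak=2600)
        # faint bridge fusing them near zero threshold
        img[30:34, 20:35] = np.maximum(img[30:34, 20:35], 40)
        rois = dt.iterative_threshold_rois(img, area_range_px=(10, 3000))
        assert len(rois) == 2
        areas = sorted(r.area_px for r in rois)
        assert areas[1] < 300  # no fused superset kept

    def test_growing_disc_replaces_contained_prior(self):
        """A dim halo around a bright core: the final ROI is the full halo."""
        img = disc_image(r=4, peak=3000)
        halo = disc_image(r=9, peak=800)
        img = np.maximum(img, halo)
        rois = dt.iterative_threshold_rois(img, area_range_px=(10, 1000))
        assert len(rois) == 1
        assert rois[0].area_px == int((halo > 0).sum())

    def test_increment_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dt.iterative_threshold_rois(disc_image(), increment=5000)


class TestCircularityFilter:
    def _roi(self, area, per):
        return dt.Roi(plane=0, rows=np.zeros(area, int), cols=np.arange(area),
                      area_px=area, perimeter_px=per, centroid_px=(0, 0))

    def test_strictly_above_cutoff_accepted(self):
        # C = 0.76 and C = 0.75 exactly
        per_76 = np.sqrt(4 * np.pi * 100 / 0.76)
        per_75 = np.sqrt(4 * np.pi * 100 / 0.75)
        acc, rej = dt.circularity_filter([self._roi(100, per_76),
                                          self._roi(100, per_75)])
        assert len(acc) == 1 and len(rej) == 1
        assert acc[0].circularity == pytest.approx(0.76)
        assert rej[0].status == "rejected_circularity"

    def test_empty_input(self):
        assert dt.circularity_filter([]) == ([], [])

    def test_lowering_cutoff_never_decreases_accepted(self, rng):
        rois = [self._roi(int(a), float(p))
                for a, p in zip(rng.integers(20, 200, 40),
                                rng.uniform(15, 120, 40))]
        counts = [len(dt.circularity_filter(rois, c)[0])
                  for c in (0.9, 0.75, 0.5, 0.25, 0.0)]
        assert counts == sorted(counts)


def roi_at(plane, rows, cols):
    rows, cols = np.asarray(rows), np.asarray(cols)
    return dt.Roi(plane=plane, rows=rows, cols=cols, area_px=rows.size,
                  perimeter_px=4.0, centroid_px=(float(cols.mean()),
                                                 float(rows.mean())))


class TestPriorityRule:
    def test_same_footprint_two_planes_keeps_deepest(self):
        shallow = roi_at(1, [5, 5, 6], [5, 6, 5])
        deep = roi_at(2, [5, 5, 6], [5, 6, 5])
        tmap = dt.priority_rule({1: [shallow], 2: [deep]}, z_step_um=10)
        assert len(tmap) == 1
        assert tmap.targets[0].plane == 2
        assert tmap.targets[0].depth_um == 20
        assert shallow.status == "rejected_priority"

    def test_non_overlapping_rois_both_retained(self):
        a = roi_at(1, [2, 2], [2, 3])
        b = roi_at(2, [20, 20], [2, 3])
        tmap = dt.priority_rule({1: [a], 2: [b]})
        assert len(tmap) == 2

    def test_three_plane_chain_keeps_only_deepest(self):
        """Brute-force oracle on the overlap graph: one component, deepest
        node survives."""
        chain = {p: [roi_at(p, [5, 5], [5, 6])] for p in (0, 1, 2)}
        tmap = dt.priority_rule(chain)
        assert len(tmap) == 1
        assert tmap.targets[0].plane == 2

    def test_idempotent_on_own_output(self):
        rois = {0: [roi_at(0, [1, 1], [1, 2]), roi_at(0, [9, 9], [1, 2])],
                1: [roi_at(1, [1, 1], [1, 2])],
                2: [roi_at(2, [5], [5])]}
        first = dt.priority_rule(rois)
        survivors = {}
        for p, rs in rois.items():
            survivors[p] = [r for r in rs if r.status == "accepted"]
        second = dt.priority_rule(survivors)
        assert [(t.plane, t.x_um, t.y_um) for t in first.targets] == \
               [(t.plane, t.x_um, t.y_um) for t in second.targets]

    def test_nonadjacent_planes_do_not_interact(self):
        a = roi_at(0, [5, 5], [5, 6])
        c = roi_at(2, [5, 5], [5, 6])
        tmap = dt.priority_rule({0: [a], 2: [c]})
        assert len(tmap) == 2


@pytest.fixture(scope="module")
def phantom():
    cfg = sg.StackConfig(count_range=(6, 9), n_planes=3, seed=21)
    stack, objs = sg.make_stack(cfg)
    return stack, objs, dt.detect_targets(stack)


class TestDetectTargets:

    def test_recall_of_somata_at_zero_noise(self, phantom):
        stack, objs, tmap = phantom
        somata = [o for o in objs if o.kind == "soma"]
        hits = 0
        for o in somata:
            for t in tmap.targets:
                if (abs(t.x_um - o.center[0]) < 4 and abs(t.y_um - o.center[1]) < 4
                        and t.plane in o.plane_span):
                    hits += 1
                    break
        assert hits / len(somata) >= 0.95

    def test_zero_debris_or_dendrites_accepted(self, phantom):
        stack, objs, tmap = phantom
        somata = [o for o in objs if o.kind == "soma"]
        for t in tmap.targets:
            assert any(abs(t.x_um - o.center[0]) < 6
                       and abs(t.y_um - o.center[1]) < 6 for o in somata)

    def test_dendrite_only_stack_yields_no_targets(self):
        cfg = sg.StackConfig(count_range=(1, 1), n_planes=2,
                             dendrite_fraction=1.0, debris_fraction=0.0,
                             two_plane_fraction=0.0, seed=3)
        stack, objs = sg.make_stack(cfg)
        # suppress the lone somata by masking them out of the image
        px = stack.pixel_size_um
        planes = stack.planes.copy()
        for o in objs:
            if o.kind == "soma":
                cx, cy = int(o.center[0] / px), int(o.center[1] / px)
                for plane in o.plane_span:
                    planes[plane, max(0, cy - 10):cy + 11,
                           max(0, cx - 10):cx + 11] = 0
        masked = sg.ImageStack(planes, pixel_size_um=px)
        tmap = dt.detect_targets(masked)
        assert len(tmap) == 0

    def test_status_partition_is_exhaustive(self, phantom):
        _, _, tmap = phantom
        valid = {"accepted", "rejected_circularity", "rejected_priority",
                 "rejected_merge"}
        for rois in tmap.rois_by_plane.values():
            for r in rois:
                assert r.status in valid

    def test_counts_by_side(self, phantom):
        _, objs, tmap = phantom
        sides = tmap.counts_by_side()
        assert set(sides) <= {"left", "right"}
        assert sum(sides.values()) == len(tmap)
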