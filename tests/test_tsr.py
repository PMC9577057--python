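"""TSR formula, sampling layouts and error metrics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from wsisampler import (
    ClassifierBundle,
    TissueClass,
    error_report,
    gt_annotation_points,
    gt_point_tsr,
    max_density_centre,
    randomspot_layout,
    tsr_box_max_density,
    tsr_from_counts,
    tsr_gt_locations,
    tsr_sliding_mean,
    tsr_uniform_roi,
)
from wsisampler.errors import ParameterError, UndefinedMetricError
from wsisampler.sampling import Patch
from wsisampler.slide_model import gt_area_tsr
from wsisampler.tsr import BOX_3MM_PX, classify_at_points


class TestTsrFromCounts:
    @pytest.mark.parametrize("t, s, want", [(50, 50, 0.5), (0, 10, 0.0), (10, 0, 1.0)])
    def test_formula(self, t, s, want):
        assert tsr_from_counts(t, s) == want

    def test_zero_denominator(self):
        with pytest.raises(UndefinedMetricError):
            tsr_from_counts(0, 0)

    def test_negative_counts(self):
        with pytest.raises(ParameterError):
            tsr_from_counts(-1, 5)


class TestRandomspotLayout:
    def test_exactly_120_points_inside_3mm_box(self):
        pts = randomspot_layout((5000, 5000), BOX_3MM_PX, 120, np.random.default_rng(0))
        assert pts.shape == (120, 2)
        assert np.all(pts[:, 0] >= 5000 - BOX_3MM_PX / 2)
        assert np.all(pts[:, 0] < 5000 + BOX_3MM_PX / 2)
        assert np.all(pts[:, 1] >= 5000 - BOX_3MM_PX / 2)
        assert np.all(pts[:, 1] < 5000 + BOX_3MM_PX / 2)

    def test_triangular_lattice_geometry(self):
        """Every point's nearest neighbour is one pitch away (quantization
        aside) — the signature of an equilateral triangular lattice."""
        pts = randomspot_layout((0, 0), BOX_3MM_PX, 120, np.random.default_rng(1))
        d = squareform(pdist(pts))
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        pitch = np.median(nn)
        assert pitch >= 224.0
        assert np.all(np.abs(nn - pitch) <= 1.0)

    def test_offsets_random_pitch_fixed(self):
        a = randomspot_layout((0, 0), BOX_3MM_PX, 120, np.random.default_rng(2))
        b = randomspot_layout((0, 0), BOX_3MM_PX, 120, np.random.default_rng(3))
        assert not np.allclose(a, b)

        def pitch(pts):
            d = squareform(pdist(pts))
            np.fill_diagonal(d, np.inf)
            return np.median(d.min(axis=1))

        assert pitch(a) == pytest.approx(pitch(b), abs=1.0)

    def test_box_too_small_rejected(self):
        with pytest.raises(ParameterError):
            randomspot_layout((0, 0), 1000, 120, np.random.default_rng(0))


class TestMaxDensityCentre:
    def test_two_blobs_picks_denser(self):
        rng = np.random.default_rng(0)
        small = rng.uniform(0, 2000, size=(10, 2))
        big = rng.uniform(0, 2000, size=(30, 2)) + 40000
        centre = max_density_centre(np.vstack([small, big]), (50000, 50000))
        assert centre[0] > 30000 and centre[1] > 30000

    def test_single_point_covered(self):
        centre = max_density_centre(np.array([(12000.0, 9000.0)]), (20000, 20000))
        assert abs(centre[0] - 12000) <= BOX_3MM_PX / 2
        assert abs(centre[1] - 9000) <= BOX_3MM_PX / 2

    def test_matches_exhaustive_candidate_scan(self):
        """Oracle identity: recount points over every candidate centre."""
        rng = np.random.default_rng(5)
        for _ in range(10):
            pts = rng.uniform(0, 20000, size=(int(rng.integers(1, 80)), 2))
            window, stride = 6122.0, 6122.0 / 4.0
            got = max_density_centre(pts, (20000, 20000), window, stride)
            half = window / 2.0
            best = None
            cys = np.arange(half, 20000 - half + 1e-9, stride)
            cxs = np.arange(half, 20000 - half + 1e-9, stride)
            for cy in cys:
                for cx in cxs:
                    n = int(
                        np.sum(
                            (pts[:, 0] >= cx - half) & (pts[:, 0] < cx + half)
                            & (pts[:, 1] >= cy - half) & (pts[:, 1] < cy + half)
                        )
                    )
                    if best is None or n > best[0]:
                        best = (n, (cx, cy))
            assert got == best[1]

    def test_no_points_undefined(self):
        with pytest.raises(UndefinedMetricError):
            max_density_centre(np.empty((0, 2)), (20000, 20000))


class TestTsrMethods:
    def test_uniform_roi_recovers_area_tsr(self, default_slide):
        """Perfect classifier: the estimate sits within 3 binomial sigma of
        the ground-truth area TSR."""
        hull = default_slide.gt_roi.convex_hull
        res = tsr_uniform_roi(
            default_slide, [hull], ClassifierBundle.perfect(),
            np.random.default_rng(0),
        )
        assert res.method_id == "uniform_roi"
        assert len(res.locations) == 100
        truth = gt_area_tsr(default_slide)
        sigma = math.sqrt(truth * (1 - truth) / (res.T + res.S))
        assert abs(res.value - truth) <= 3 * sigma

    def test_uniform_roi_empty_hulls_undefined(self, default_slide):
        with pytest.raises(UndefinedMetricError):
            tsr_uniform_roi(
                default_slide, [], ClassifierBundle.perfect(),
                np.random.default_rng(0),
            )

    def test_box_max_density_120_points(self, default_slide):
        from wsisampler.slide_model import CLASS_CODES

        d = default_slide.raster_step
        rows, cols = np.nonzero(
            default_slide.label_raster == CLASS_CODES[TissueClass.TUMOUR]
        )
        tumour_pts = np.column_stack([(cols + 0.5) * d, (rows + 0.5) * d])
        res = tsr_box_max_density(
            default_slide, tumour_pts, ClassifierBundle.perfect(),
            np.random.default_rng(1),
        )
        assert len(res.locations) == 120
        assert 0.0 <= res.value <= 1.0

    def test_box_max_density_no_tumour_points(self, default_slide):
        with pytest.raises(UndefinedMetricError):
            tsr_box_max_density(
                default_slide, np.empty((0, 2)), ClassifierBundle.perfect(),
                np.random.default_rng(0),
            )

    def test_sliding_mean_single_window(self):
        """With one participating window the mean equals that window's TSR."""
        patches = []
        for i in range(8):
            patches.append(
                Patch(x=1000 + 230 * i, y=1000, box_idx=(0, 0), iteration=0,
                      pred_class=TissueClass.TUMOUR)
            )
        for i in range(4):
            patches.append(
                Patch(x=1000 + 230 * i, y=1300, box_idx=(0, 0), iteration=0,
                      pred_class=TissueClass.STROMA_FIBROSIS)
            )
        from shapely.geometry import box as shapely_box

        hull = shapely_box(0, 0, 6122, 6122)
        res = tsr_sliding_mean(patches, [hull], (6400, 6400), stride_px=6122.0)
        assert res.value == pytest.approx(8 / 12)
        assert (res.T, res.S) == (8, 4)

    def test_sliding_mean_min_counts_unmet(self):
        patches = [
            Patch(x=1000, y=1000, box_idx=(0, 0), iteration=0,
                  pred_class=TissueClass.TUMOUR)
        ]
        from shapely.geometry import box as shapely_box

        with pytest.raises(UndefinedMetricError):
            tsr_sliding_mean(patches, [shapely_box(0, 0, 6122, 6122)],
                             (6400, 6400), min_counts=10)

    def test_gt_locations_oracle_identity(self, default_slide):
        """Perfect classifier at the GT points reproduces the GT point TSR
        exactly."""
        ann = gt_annotation_points(default_slide)
        assert len(ann.sample_points) == 50
        pts = np.array([(x, y) for x, y, _ in ann.sample_points])
        res = tsr_gt_locations(
            default_slide, pts, ClassifierBundle.perfect(), np.random.default_rng(0)
        )
        assert res.value == gt_point_tsr(ann)
        assert 0.0 <= res.value <= 1.0

    def test_gt_locations_empty_rejected(self, default_slide):
        with pytest.raises(ParameterError):
            tsr_gt_locations(
                default_slide, np.empty((0, 2)), ClassifierBundle.perfect(),
                np.random.default_rng(0),
            )

    def test_gt_annotation_points_deterministic(self, default_slide):
        a = gt_annotation_points(default_slide)
        b = gt_annotation_points(default_slide)
        assert a.sample_points == b.sample_points


class TestErrorReport:
    @pytest.mark.parametrize(
        "pairs, rmse, me",
        [
            ([(0.5, 0.6)], 0.1, -0.1),
            ([(0.3, 0.3), (0.7, 0.7)], 0.0, 0.0),
            ([(0.0, 1.0), (1.0, 0.0)], 1.0, 0.0),
        ],
    )
    def test_hand_computed_examples(self, pairs, rmse, me):
        rep = error_report(pairs)
        assert rep.rmse == pytest.approx(rmse, abs=1e-12)
        assert rep.me == pytest.approx(me, abs=1e-12)
        assert rep.n_slides == len(pairs)

    def test_empty_rejected(self):
        with pytest.raises(UndefinedMetricError):
            error_report([])

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            error_report([(0.5, 1.2)])

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 1, allow_nan=False), st.floats(0, 1, allow_nan=False)
            ),
            min_size=1,
            max_size=30,
        )
    )
    def test_rmse_dominates_mean_error(self, pairs):
        rep = error_report(pairs)
        assert rep.rmse + 1e-12 >= abs(rep.me)
        assert rep.rmse >= 0


def test_classify_at_points_clamps_patches_into_slide(default_slide):
    patches = classify_at_points(
        default_slide,
        np.array([(5.0, 5.0), (19995.0, 19995.0)]),
        ClassifierBundle.perfect(),
        np.random.default_rng(0),
    )
    for p in patches:
        assert 0 <= p.x <= default_slide.width_px - 224
        assert 0 <= p.y <= default_slide.height_px - 224
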