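"""Grid construction, patch placement rules and densification invariants."""

from collections import defaultdict

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wsisampler import (
    Patch,
    TissueClass,
    allocate_initial,
    allocate_resample,
    allocate_roi_fill,
    build_grid,
    overlaps,
)
from wsisampler.errors import ParameterError
from wsisampler.sampling import PATCH_PX

from conftest import make_uniform_slide


def group_by_box(patches):
    by_box = defaultdict(list)
    for p in patches:
        by_box[p.box_idx].append(p)
    return by_box


def assert_no_overlap_within_boxes(patches):
    for box_patches in group_by_box(patches).values():
        for i in range(len(box_patches)):
            for j in range(i + 1, len(box_patches)):
                assert not overlaps(box_patches[i], box_patches[j])


class TestBuildGrid:
    @pytest.mark.parametrize(
        "dims, box, want",
        [((6400, 3200), 640, (10, 5)), ((6401, 3200), 640, (11, 5))],
    )
    def test_ceiling_cover(self, dims, box, want):
        grid = build_grid(dims, box)
        assert (grid.n_cols, grid.n_rows) == want

    def test_box_smaller_than_patch_rejected(self):
        with pytest.raises(ParameterError):
            build_grid((6400, 6400), 100)


class TestOverlaps:
    @pytest.mark.parametrize(
        "b, want",
        [((224, 0), False), ((223, 0), True), ((0, 0), True), ((0, 224), False),
         ((223, 223), True), ((-223, 0), True), ((-224, 0), False)],
    )
    def test_half_open_semantics(self, b, want):
        a = Patch(x=0, y=0, box_idx=(0, 0), iteration=0)
        other = Patch(x=b[0], y=b[1], box_idx=(0, 0), iteration=0)
        assert overlaps(a, other) is want
        assert overlaps(other, a) is want

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        ax=st.integers(-500, 500), ay=st.integers(-500, 500),
        bx=st.integers(-500, 500), by=st.integers(-500, 500),
    )
    def test_matches_interval_intersection_oracle(self, ax, ay, bx, by):
        a = Patch(x=ax, y=ay, box_idx=(0, 0), iteration=0)
        b = Patch(x=bx, y=by, box_idx=(0, 0), iteration=0)
        w = max(0, min(ax, bx) + PATCH_PX - max(ax, bx))
        h = max(0, min(ay, by) + PATCH_PX - max(ay, by))
        assert overlaps(a, b) == (w * h > 0)


class TestAllocateInitial:
    def test_one_patch_per_tissue_box(self):
        slide = make_uniform_slide(6400, 6400)
        grid = build_grid(slide.dims, 640)
        patches = allocate_initial(grid, slide, np.random.default_rng(0))
        assert len(patches) == 100
        assert {p.box_idx for p in patches} == {
            (c, r) for c in range(10) for r in range(10)
        }
        assert all(p.iteration == 0 for p in patches)

    def test_all_background_slide_yields_nothing(self):
        slide = make_uniform_slide(6400, 6400, TissueClass.BACKGROUND)
        grid = build_grid(slide.dims, 640)
        assert allocate_initial(grid, slide, np.random.default_rng(0)) == []

    def test_patches_inside_slide_and_parent_box(self, small_slide):
        grid = build_grid(small_slide.dims, 640)
        for p in allocate_initial(grid, small_slide, np.random.default_rng(1)):
            assert 0 <= p.x <= small_slide.width_px - PATCH_PX
            assert 0 <= p.y <= small_slide.height_px - PATCH_PX
            col, row = p.box_idx
            assert col * 640 <= p.x and row * 640 <= p.y
            # top-left inside the (possibly edge-clamped) box
            assert p.x < (col + 1) * 640 and p.y < (row + 1) * 640

    def test_deterministic_under_seed(self, small_slide):
        grid = build_grid(small_slide.dims, 640)
        a = allocate_initial(grid, small_slide, np.random.default_rng(9))
        b = allocate_initial(grid, small_slide, np.random.default_rng(9))
        assert [(p.x, p.y) for p in a] == [(p.x, p.y) for p in b]


class TestAllocateResample:
    def test_four_new_patches_around_one_tumour_hit(self):
        slide = make_uniform_slide(1280, 1280)
        grid = build_grid(slide.dims, 640)
        seed_patch = Patch(x=100, y=100, box_idx=(0, 0), iteration=0,
                           pred_class=TissueClass.TUMOUR)
        new = allocate_resample(
            [seed_patch], [seed_patch], grid, slide,
            np.random.default_rng(4), iteration=1,
        )
        assert len(new) == 4
        assert all(p.iteration == 1 for p in new)
        assert_no_overlap_within_boxes([seed_patch] + new)

    def test_box_at_cap_gains_nothing(self):
        slide = make_uniform_slide(1280, 1280)
        grid = build_grid(slide.dims, 640)
        existing = [
            Patch(x=i * 230, y=0, box_idx=(0, 0), iteration=0,
                  pred_class=TissueClass.TUMOUR)
            for i in range(5)
        ]
        new = allocate_resample(
            existing[:1], existing, grid, slide,
            np.random.default_rng(4), iteration=1,
        )
        assert new == []

    def test_cap_binds_before_per_tumour_arithmetic(self):
        slide = make_uniform_slide(1280, 1280)
        grid = build_grid(slide.dims, 640)
        t1 = Patch(x=0, y=0, box_idx=(0, 0), iteration=0,
                   pred_class=TissueClass.TUMOUR)
        t2 = Patch(x=300, y=0, box_idx=(0, 0), iteration=0,
                   pred_class=TissueClass.TUMOUR)
        other = Patch(x=0, y=300, box_idx=(0, 0), iteration=0)
        new = allocate_resample(
            [t1, t2], [t1, t2, other], grid, slide,
            np.random.default_rng(4), iteration=1,
        )
        assert len(new) <= 4  # cap 5 minus existing, never 2 x 4
        assert len([t1, t2, other]) + len(new) <= 5


class TestAllocateRoiFill:
    def test_boxes_inside_hull_topped_up_to_cap(self):
        from shapely.geometry import box as shapely_box

        slide = make_uniform_slide(3200, 3200)
        grid = build_grid(slide.dims, 640)
        hull = shapely_box(0, 0, 1280, 1280)  # covers boxes (0,0),(1,0),(0,1),(1,1)
        existing = [Patch(x=10, y=10, box_idx=(0, 0), iteration=0)]
        new = allocate_roi_fill(
            grid, [hull], existing, slide, np.random.default_rng(0), iteration=3
        )
        by_box = group_by_box(existing + new)
        assert len(by_box[(0, 0)]) == 5  # 1 existing + 4 added
        assert len(by_box[(1, 0)]) == 5
        assert len(by_box[(0, 1)]) == 5
        assert len(by_box[(1, 1)]) == 5
        # boxes outside the hull untouched
        assert all(b in {(0, 0), (1, 0), (0, 1), (1, 1)} for b in by_box)
        assert_no_overlap_within_boxes(existing + new)

    def test_box_already_at_cap_unchanged(self):
        from shapely.geometry import box as shapely_box

        slide = make_uniform_slide(640, 640)
        grid = build_grid(slide.dims, 640)
        existing = [
            Patch(x=i * 230 % 416, y=(i // 2) * 230, box_idx=(0, 0), iteration=0)
            for i in range(5)
        ]
        new = allocate_roi_fill(
            grid, [shapely_box(0, 0, 640, 640)], existing, slide,
            np.random.default_rng(2), iteration=3,
        )
        assert new == []

    def test_no_hulls_no_fill(self, small_slide):
        grid = build_grid(small_slide.dims, 640)
        assert allocate_roi_fill(
            grid, [], [], small_slide, np.random.default_rng(0), iteration=3
        ) == []


class TestDensificationInvariants:
    """Cap conservation, non-overlap and monotone densification across the
    three allocation generations."""

    @pytest.mark.parametrize("seed", range(20))
    def test_full_stage_scan(self, small_slide, seed):
        rng = np.random.default_rng(seed)
        grid = build_grid(small_slide.dims, 640)
        patches = allocate_initial(grid, small_slide, rng)
        counts0 = {b: len(v) for b, v in group_by_box(patches).items()}
        assert all(c <= 1 for c in counts0.values())

        # perfect detector: mark ground-truth tumour patches as predicted
        for p in patches:
            cx, cy = p.centre
            d = small_slide.raster_step
            from wsisampler.slide_model import CLASS_CODES

            if small_slide.label_raster[cy // d, cx // d] == CLASS_CODES[
                TissueClass.TUMOUR
            ]:
                p.pred_class = TissueClass.TUMOUR
        tumour = [p for p in patches if p.pred_class is TissueClass.TUMOUR]
        new = allocate_resample(tumour, patches, grid, small_slide, rng, iteration=1)
        patches += new
        hull = small_slide.gt_roi.convex_hull
        fill = allocate_roi_fill(grid, [hull], patches, small_slide, rng, iteration=2)
        patches += fill

        by_box = group_by_box(patches)
        assert all(len(v) <= 5 for v in by_box.values())
        assert_no_overlap_within_boxes(patches)
        counts_final = {b: len(v) for b, v in by_box.items()}
        for b, c0 in counts0.items():
            assert counts_final[b] >= c0
        from shapely.geometry import Point

        touched = {p.box_idx for p in tumour} | {
            b for b in by_box if hull.contains(Point(*grid.box_centre(*b)))
        }
        for b, c in counts_final.items():
            if b not in touched:
                assert c <= 1
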