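import math

import numpy as np
import pytest
from shapely.geometry import box as shapely_box

from wsisampler import PipelineConfig, generate_slide
from wsisampler.slide_model import CLASS_CODES, TissueClass, VirtualSlide

DEFAULT_SLIDE_PX = 20000
DEFAULT_ROI_FRACTION = 0.15


def make_uniform_slide(
    width: int = 6400,
    height: int = 6400,
    tissue_class: TissueClass = TissueClass.TUMOUR,
    raster_step: int = 32,
) -> VirtualSlide:
    """A slide whose every cell holds one class; the whole slide is the ROI."""
    shape = (math.ceil(height / raster_step), math.ceil(width / raster_step))
    return VirtualSlide(
        width_px=width,
        height_px=height,
        microns_per_px=0.49,
        raster_step=raster_step,
        label_raster=np.full(shape, CLASS_CODES[tissue_class], dtype=np.uint8),
        gt_roi=shapely_box(0, 0, width, height),
        composition={},
        seed=0,
    )


@pytest.fixture(scope="session")
def small_slide() -> VirtualSlide:
    """A 6400 px synthetic slide — fast to sample, full structure."""
    return generate_slide(6400, 6400, DEFAULT_ROI_FRACTION, seed=3)


@pytest.fixture(scope="session")
def default_slide() -> VirtualSlide:
    """One default-size (20000 px) synthetic slide."""
    return generate_slide(DEFAULT_SLIDE_PX, DEFAULT_SLIDE_PX, DEFAULT_ROI_FRACTION, seed=7)


@pytest.fixture(scope="session")
def eval_slides() -> list[VirtualSlide]:
    """The 20-slide synthetic evaluation set."""
    return [
        generate_slide(DEFAULT_SLIDE_PX, DEFAULT_SLIDE_PX, DEFAULT_ROI_FRACTION, seed=s)
        for s in range(20)
    ]


@pytest.fixture()
def perfect_config() -> PipelineConfig:
    return PipelineConfig(
        box_px=640,
        resample_iterations=2,
        classifier_accuracy=1.0,
        normal_epi_to_tumour_rate=0.0,
        fp_sensitivity=1.0,
        fp_specificity=1.0,
        seed=11,
    )


def dbscan_oracle(points: np.ndarray, eps: float, min_samples: int) -> np.ndarray:
    """Brute-force O(n^2) DBSCAN: neighbour counting + BFS over core points.

    Independent of the package implementation; labels are -1 for noise and
    0..k-1 for clusters in discovery order.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = points.shape[0]
    labels = np.full(n, -1, dtype=int)
    if n == 0:
        return labels
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=-1)
    neigh = d2 <= eps * eps  # includes self
    core = neigh.sum(axis=1) >= min_samples
    cid = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cid
        stack = [i]
        while stack:
            j = stack.pop()
            if not core[j]:
                continue
            for k in np.flatnonzero(neigh[j]):
                if labels[k] == -1:
                    labels[k] = cid
                    stack.append(k)
        cid += 1
    return labels


def assert_dbscan_equivalent(
    points: np.ndarray,
    got: np.ndarray,
    want: np.ndarray,
    eps: float,
    min_samples: int,
) -> None:
    """Equality of two DBSCAN labelings under standard semantics.

    Cluster ids are arbitrary, and a border point may legitimately be
    claimed by any cluster that has a core point within eps of it; the
    noise set and the partition of core points must agree exactly.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    n = points.shape[0]
    assert got.shape == want.shape == (n,)
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(axis=-1)
    neigh = d2 <= eps * eps  # includes self
    core = neigh.sum(axis=1) >= min_samples
    np.testing.assert_array_equal(got == -1, want == -1, "noise sets differ")
    assert not np.any(core & (got == -1)), "core point labelled noise"
    gc, wc = got[core], want[core]
    np.testing.assert_array_equal(
        gc[:, None] == gc[None, :],
        wc[:, None] == wc[None, :],
        "core-point partition differs",
    )
    # border points: assigned cluster must own a core point within eps
    for labels in (got, want):
        for i in np.flatnonzero(~core & (got != -1)):
            cluster_core = core & (labels == labels[i])
            assert np.any(neigh[i] & cluster_core), (
                f"border point {i} assigned to a cluster with no core "
                "point in reach"
            )
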