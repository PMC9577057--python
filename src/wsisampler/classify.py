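"""Patch-classifier contract, confusion-matrix simulator and FP correction.

Rather than running a trained network, the simulated classifier draws each
patch's predicted class from a row-stochastic confusion matrix conditioned on
the patch's ground-truth class (the slide label at its centre pixel). The
dominant real-world failure modes are built in: tumour and stroma/fibrosis
are confused with each other more than with other classes, and normal
epithelium outside the tumour region is misread as tumour at a configurable
rate — the false-positive source a second-stage binary classifier is then
simulated to clean up.

A real classifier can be substituted anywhere a :class:`ClassifierBundle` is
accepted: the contract is a callable over patch centre coordinates returning
one of the nine output classes per patch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, ParameterError, UndefinedMetricError
from .sampling import Patch
from .slide_model import (
    CLASS_CODES,
    CLASSIFIER_CLASSES,
    CODE_TO_CLASS,
    TissueClass,
    VirtualSlide,
)

ALL_CLASSES: tuple[TissueClass, ...] = tuple(CLASS_CODES)


@dataclass(frozen=True)
class ConfusionSpec:
    """Row-stochastic confusion matrix of the simulated 9-class classifier.

    Rows are indexed by all 11 ground-truth classes (including background and
    normal epithelium); columns by the 9 classifier output classes.
    """

    classes: tuple[TissueClass, ...]
    matrix: np.ndarray  # shape (11, 9)

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.classes), len(CLASSIFIER_CLASSES)):
            raise ConfigurationError(
                f"confusion matrix shape {self.matrix.shape} does not match "
                f"{len(self.classes)} input x {len(CLASSIFIER_CLASSES)} output classes"
            )
        if np.any(self.matrix < 0):
            raise ConfigurationError("confusion matrix entries must be >= 0")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("confusion matrix rows must sum to 1")

    def row(self, cls: TissueClass) -> np.ndarray:
        try:
            return self.matrix[self.classes.index(cls)]
        except ValueError as exc:
            raise ConfigurationError(f"no confusion row for class {cls}") from exc


@dataclass(frozen=True)
class FpStageSpec:
    """Binary false-positive-correction stage.

    ``sensitivity``: probability a true tumour-epithelium patch is retained
    as tumour. ``specificity``: probability a normal-epithelium patch is
    relabelled away from tumour. The single published accuracy of the
    reference two-way network (92.7%) is used for both by default.
    """

    sensitivity: float = 0.927
    specificity: float = 0.927

    def __post_init__(self) -> None:
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ParameterError("sensitivity and specificity must be in [0, 1]")


@dataclass(frozen=True)
class ClassifierBundle:
    """The two simulated classification stages used throughout the pipeline."""

    confusion: "ConfusionSpec"
    fp_stage: FpStageSpec

    @staticmethod
    def perfect() -> "ClassifierBundle":
        """An error-free classifier with an error-free FP stage."""
        return ClassifierBundle(
            confusion=make_confusion(1.0, 0.0),
            fp_stage=FpStageSpec(sensitivity=1.0, specificity=1.0),
        )


def make_confusion(
    overall_accuracy: float = 0.79, normal_epi_to_tumour_rate: float = 0.3
) -> ConfusionSpec:
    """Build the default simulated confusion matrix.

    Each of the nine true classes keeps ``overall_accuracy`` on the diagonal.
    The residual error mass is spread over the off-diagonal classes, with
    the tumour<->stroma/fibrosis partner receiving double the share of any
    other class in those two rows (the dominant documented confusion).
    Background always maps to non-informative. Normal epithelium emits
    tumour with probability ``normal_epi_to_tumour_rate`` and otherwise
    splits evenly between non-informative and stroma/fibrosis.
    """
    if not (0.0 < overall_accuracy <= 1.0):
        raise ParameterError(f"overall_accuracy {overall_accuracy} outside (0, 1]")
    if not (0.0 <= normal_epi_to_tumour_rate <= 1.0):
        raise ParameterError(
            f"normal_epi_to_tumour_rate {normal_epi_to_tumour_rate} outside [0, 1]"
        )
    n_out = len(CLASSIFIER_CLASSES)
    out_index = {c: i for i, c in enumerate(CLASSIFIER_CLASSES)}
    i_tum = out_index[TissueClass.TUMOUR]
    i_str = out_index[TissueClass.STROMA_FIBROSIS]
    i_ni = out_index[TissueClass.NON_INFORMATIVE]

    matrix = np.zeros((len(ALL_CLASSES), n_out))
    for r, cls in enumerate(ALL_CLASSES):
        if cls == TissueClass.BACKGROUND:
            matrix[r, i_ni] = 1.0
        elif cls == TissueClass.NORMAL_EPITHELIUM:
            rate = normal_epi_to_tumour_rate
            matrix[r, i_tum] = rate
            matrix[r, i_ni] = (1.0 - rate) / 2.0
            matrix[r, i_str] = (1.0 - rate) / 2.0
        else:
            c = out_index[cls]
            resid = 1.0 - overall_accuracy
            row = np.zeros(n_out)
            row[c] = overall_accuracy
            if cls == TissueClass.TUMOUR:
                others = [i for i in range(n_out) if i not in (c, i_str)]
                row[i_str] = 2.0 * resid / (len(others) + 2)
                row[others] = resid / (len(others) + 2)
            elif cls == TissueClass.STROMA_FIBROSIS:
                others = [i for i in range(n_out) if i not in (c, i_tum)]
                row[i_tum] = 2.0 * resid / (len(others) + 2)
                row[others] = resid / (len(others) + 2)
            else:
                others = [i for i in range(n_out) if i != c]
                row[others] = resid / len(others)
            matrix[r] = row
    return ConfusionSpec(classes=ALL_CLASSES, matrix=matrix)


def simulate_classify(
    patches: list[Patch],
    slide: VirtualSlide,
    confusion: ConfusionSpec,
    rng: np.random.Generator,
) -> list[Patch]:
    """Assign ground-truth and simulated predicted classes to patches.

    Sets ``gt_class`` to the slide label at each patch centre and samples
    ``pred_class`` from the confusion row of that class. Patches are
    modified in place and returned; only the nine classifier classes are
    ever emitted.
    """
    if not patches:
        return patches
    xs = np.array([p.centre[0] for p in patches])
    ys = np.array([p.centre[1] for p in patches])
    gt_codes = slide.label_codes_at(xs, ys)
    row_index = {cls: i for i, cls in enumerate(confusion.classes)}
    out_classes = list(CLASSIFIER_CLASSES)
    # sample per ground-truth class group so each group is one vectorised draw
    for code in np.unique(gt_codes):
        cls = CODE_TO_CLASS[int(code)]
        if cls not in row_index:
            raise ConfigurationError(f"ground-truth class {cls} missing from spec")
        sel = np.nonzero(gt_codes == code)[0]
        draws = rng.choice(len(out_classes), size=sel.size, p=confusion.row(cls))
        for i, d in zip(sel, draws):
            patches[i].gt_class = cls
            patches[i].pred_class = out_classes[int(d)]
    return patches


def fp_correct(
    patches: list[Patch],
    fp_spec: FpStageSpec,
    slide: VirtualSlide,
    rng: np.random.Generator,
) -> list[Patch]:
    """Apply the simulated second-stage false-positive correction.

    Operates only on tumour-predicted patches, mirroring the binary
    true-tumour-epithelium vs false-positive second stage: a patch whose
    ground truth is tumour keeps its label with probability ``sensitivity``;
    any other tumour-predicted patch (normal epithelium, or another tissue
    the first stage misread) is relabelled ``normal_epithelium`` — the
    stage's negative output — with probability ``specificity``. Relabelled
    patches carry the ``fp_corrected`` flag; non-tumour predictions are
    never touched and the tumour-predicted count never increases.
    """
    targets = [p for p in patches if p.pred_class == TissueClass.TUMOUR]
    if not targets:
        return patches
    u = rng.random(len(targets))
    for p, ui in zip(targets, u):
        if p.gt_class == TissueClass.TUMOUR:
            if ui >= fp_spec.sensitivity:
                p.pred_class = TissueClass.NORMAL_EPITHELIUM
                p.fp_corrected = True
        elif ui < fp_spec.specificity:
            p.pred_class = TissueClass.NORMAL_EPITHELIUM
            p.fp_corrected = True
    return patches


def tumour_inside_fraction(patches: list[Patch], gt_roi) -> float:
    """Percentage of tumour-predicted patch centres inside the true ROI."""
    import shapely

    tum = [p for p in patches if p.pred_class == TissueClass.TUMOUR]
    if not tum:
        raise UndefinedMetricError("no tumour-predicted patches")
    xs = np.array([p.centre[0] for p in tum], dtype=float)
    ys = np.array([p.centre[1] for p in tum], dtype=float)
    inside = shapely.intersects_xy(gt_roi, xs, ys)
    return 100.0 * float(inside.sum()) / len(tum)
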