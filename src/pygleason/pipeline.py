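"""End-to-end orchestration: preprocess -> tile -> classify -> fuse -> grade.

The inference path runs every patch of every group through the per-level
cascade (or the ground-truth oracle), paints one label image per group,
stacks them into the vote stack (39 votes per pixel at the default
configuration) and fuses/grades the result.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, maximum_filter

from .cascade import (
    LevelCascade,
    OracleClassifier,
    TuningConfig,
    balance_training_set,
    train_level_cascade,
    patches_to_float,
)
from .fusion import GradeResult, VoteStack, accumulate_votes, grade_from_gp_map, majority_vote
from .preprocess import PreprocessConfig, enhance_edges, histogram_equalize, tissue_mask
from .synthetic import SlideImage
from .tiling import (
    DEFAULT_LEVELS,
    LevelConfig,
    PatchGroup,
    extract_window,
    generate_patch_groups,
    paint_group_labels,
    select_training_patches,
)

__all__ = [
    "GradingOutput",
    "extract_group_windows",
    "predict_group_labels",
    "grade_slide",
    "collect_training_patches",
    "train_pipeline",
    "boundary_quantization_bound",
    "grade_from_truth",
]


def _ee_batch(patches: np.ndarray, cfg: PreprocessConfig) -> np.ndarray:
    """Vectorized unsharp mask over a (N,S,S,3) uint8 stack.

    Per-sample result is identical to :func:`pygleason.preprocess.enhance_edges`
    because the Gaussian is separable and sigma is 0 along the batch axis.
    """
    if cfg.ee_amount == 0:
        return patches
    as_float = patches.astype(np.float64)
    blurred = gaussian_filter(as_float, sigma=(0, cfg.ee_radius, cfg.ee_radius, 0))
    sharp = as_float + cfg.ee_amount * (as_float - blurred)
    return np.clip(np.rint(sharp), 0, 255).astype(patches.dtype)


def extract_group_windows(arr: np.ndarray, group: PatchGroup, fill) -> np.ndarray:
    """Stack of all windows of one patch group, in :meth:`PatchGroup.refs` order."""
    return np.stack(
        [extract_window(arr, ref.origin, ref.size, fill) for ref in group.refs()]
    )


def predict_group_labels(
    slide_rgb: np.ndarray,
    group: PatchGroup,
    classifier: LevelCascade | OracleClassifier,
    cfg: PreprocessConfig,
    label_map: np.ndarray | None = None,
    routing: str = "argmax",
) -> np.ndarray:
    """Classify every patch of a group and paint the labels onto the canvas."""
    if isinstance(classifier, OracleClassifier):
        if label_map is None:
            raise ValueError("oracle classification requires a ground-truth label map")
        windows = [extract_window(label_map, ref.origin, ref.size, 0) for ref in group.refs()]
        labels = classifier.classify_windows(windows)
    else:
        windows = extract_group_windows(slide_rgb, group, fill=255)
        if cfg.apply_ee_at_test:
            windows = _ee_batch(windows, cfg)
        labels = classifier.classify(patches_to_float(windows), routing=routing)
    return paint_group_labels(group, labels)


@dataclasses.dataclass
class GradingOutput:
    """Everything the grading path produces for one slide."""

    vote_stack: VoteStack
    gp_map: np.ndarray
    grade: GradeResult
    groups_run: int


def grade_slide(
    slide: SlideImage,
    model: Mapping[int, LevelCascade] | OracleClassifier,
    levels: Sequence[LevelConfig] = DEFAULT_LEVELS,
    cfg: PreprocessConfig | None = None,
    tie_break: str = "low",
    benign_threshold: float = 0.005,
    routing: str = "argmax",
) -> GradingOutput:
    """Run the full inference path on one slide.

    ``model`` maps patch size -> trained level cascade, or is the oracle
    test double (which reads the slide's ground-truth label map).
    """
    cfg = cfg or PreprocessConfig()
    cfg.validate()
    oracle = isinstance(model, OracleClassifier)
    if not oracle:
        missing = [lv.S for lv in levels if lv.S not in model]
        if missing:
            raise ValueError(f"no trained cascade for levels {missing}")

    heq = histogram_equalize(slide, cfg)
    label_images: list[np.ndarray] = []
    for level in levels:
        for group in generate_patch_groups(slide.shape, level):
            classifier = model if oracle else model[level.S]
            label_images.append(
                predict_group_labels(
                    heq.rgb, group, classifier, cfg,
                    label_map=slide.label_map, routing=routing,
                )
            )
    expected = sum(generate_patch_groups(slide.shape, lv)[0].level.n_groups for lv in levels)
    stack = accumulate_votes(label_images, expected_groups=expected)
    gp_map = majority_vote(stack, tie_break=tie_break)
    tissue = tissue_mask(slide, cfg)
    grade = grade_from_gp_map(gp_map, tissue, benign_threshold=benign_threshold)
    return GradingOutput(stack, gp_map, grade, groups_run=len(label_images))


# -- training path ----------------------------------------------------------

def collect_training_patches(
    slides: Sequence[SlideImage],
    level: LevelConfig,
    cfg: PreprocessConfig | None = None,
) -> dict[int, list[np.ndarray]]:
    """Pool the filtered, edge-enhanced training patches of many slides."""
    cfg = cfg or PreprocessConfig()
    by_label: dict[int, list[np.ndarray]] = {lab: [] for lab in (1, 2, 3, 4, 5)}
    for slide in slides:
        heq = histogram_equalize(slide, cfg)
        for patch, label in select_training_patches(heq, level):
            by_label[label].append(enhance_edges(patch, cfg))
    return by_label


def train_pipeline(
    slides: Sequence[SlideImage],
    levels: Sequence[LevelConfig] = DEFAULT_LEVELS,
    tuning: TuningConfig | None = None,
    cfg: PreprocessConfig | None = None,
    seed: int = 0,
    max_patches_per_class: int | None = None,
) -> dict[int, LevelCascade]:
    """Train the 4-node cascade of every level (12 nodes at 3 levels).

    Balancing happens once at the 5-class stage per level; each node then
    regroups the balanced pool into its binary task.  ``max_patches_per_class``
    caps the balanced class size to bound CPU time.
    """
    tuning = tuning or TuningConfig()
    cfg = cfg or PreprocessConfig()
    model: dict[int, LevelCascade] = {}
    for i, level in enumerate(levels):
        by_label = collect_training_patches(slides, level, cfg)
        balanced = balance_training_set(by_label, seed=seed + i)
        if max_patches_per_class is not None:
            balanced = {k: v[:max_patches_per_class] for k, v in balanced.items()}
        level_tuning = dataclasses.replace(tuning, seed=seed * 101 + i)
        model[level.S] = train_level_cascade(level.S, balanced, level_tuning)
    return model


# -- analysis helpers -------------------------------------------------------

def boundary_quantization_bound(label_map: np.ndarray, s_max: int) -> float:
    """Upper bound on the oracle pipeline's pixel error rate.

    A tissue pixel can only be misvoted if some covering patch straddles a
    class boundary, i.e. if a pixel of a *different* tissue class lies within
    Chebyshev distance ``s_max - 1``.  Returns the fraction of tissue pixels
    for which that holds; pixels outside it receive 39 unanimous correct
    votes from the ground-truth oracle.
    """
    lm = np.asarray(label_map)
    tissue = lm != 0
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("label map has no tissue")
    size = 2 * s_max - 1
    unsafe = np.zeros_like(tissue)
    for lab in np.unique(lm[tissue]):
        other = tissue & (lm != lab)
        near_other = maximum_filter(other.astype(np.uint8), size=size).astype(bool)
        unsafe |= (lm == lab) & near_other
    return float(unsafe[tissue].sum() / n_tissue)


def grade_from_truth(slide: SlideImage, benign_threshold: float = 0.005) -> GradeResult:
    """Grade directly from the ground-truth label map (reference grading)."""
    if slide.label_map is None:
        raise ValueError("slide has no ground-truth label map")
    lm = np.asarray(slide.label_map)
    return grade_from_gp_map(lm, lm != 0, benign_threshold=benign_threshold)
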