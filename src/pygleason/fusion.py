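"""Per-pixel vote accumulation, majority fusion, and slide-level grading.

Every patch group contributes one label per pixel, so a three-level run at
20% shift yields 39 votes per pixel (13 per level).  Majority fusion picks
the modal label per pixel, grading derives the two most common malignant
patterns (labels 3-5) by tissue area, sums them into the score, and maps the
ordered pair to a grade group:

    3+3 -> GG1;  3+4 -> GG2;  4+3 -> GG3;
    4+4, 3+5, 5+3 -> GG4;  4+5, 5+4, 5+5 -> GG5.

Labels 1 (stroma) and 2 (benign) never grade; a slide whose malignant area
fraction falls below a threshold is called Benign.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

__all__ = [
    "VoteStack",
    "GradeResult",
    "GRADE_GROUP_TABLE",
    "accumulate_votes",
    "majority_vote",
    "grade_from_gp_map",
    "grade_group_for_pair",
]

MALIGNANT = (3, 4, 5)

#: (primary, secondary) -> grade group index
GRADE_GROUP_TABLE: dict[tuple[int, int], int] = {
    (3, 3): 1,
    (3, 4): 2,
    (4, 3): 3,
    (4, 4): 4,
    (3, 5): 4,
    (5, 3): 4,
    (4, 5): 5,
    (5, 4): 5,
    (5, 5): 5,
}


@dataclasses.dataclass
class VoteStack:
    """Stack of per-group label images: one vote per pixel per group."""

    votes: np.ndarray  # (G, H, W) uint8, values 1..5 (0 = no vote)
    valid_mask: np.ndarray  # (H, W) bool

    @property
    def n_votes(self) -> int:
        return self.votes.shape[0]

    def votes_per_pixel(self) -> np.ndarray:
        """Count of nonzero votes at each pixel."""
        return (self.votes != 0).sum(axis=0)


def accumulate_votes(
    label_images: Sequence[np.ndarray],
    expected_groups: int | None = None,
    valid_mask: np.ndarray | None = None,
) -> VoteStack:
    """Stack one label image per patch group into a vote stack."""
    if len(label_images) == 0:
        raise ValueError("no label images given")
    if expected_groups is not None and len(label_images) != expected_groups:
        raise ValueError(f"expected {expected_groups} label images, got {len(label_images)}")
    shape = np.asarray(label_images[0]).shape
    for img in label_images:
        if np.asarray(img).shape != shape:
            raise ValueError("label images differ in shape")
    votes = np.stack([np.asarray(img, dtype=np.uint8) for img in label_images])
    if valid_mask is None:
        valid_mask = np.ones(shape, dtype=bool)
    elif valid_mask.shape != shape:
        raise ValueError("valid_mask shape mismatch")
    return VoteStack(votes=votes, valid_mask=valid_mask)


def majority_vote(stack: VoteStack, tie_break: str = "low") -> np.ndarray:
    """Fuse the stack into a single label image by per-pixel modal vote.

    ``tie_break='low'`` resolves count ties toward the lower (less
    aggressive) label; ``'high'`` toward the higher one.
    """
    if tie_break not in ("low", "high"):
        raise ValueError("tie_break must be 'low' or 'high'")
    counts = np.stack([(stack.votes == lab).sum(axis=0) for lab in (1, 2, 3, 4, 5)])
    total = counts.sum(axis=0)
    if (total[stack.valid_mask] == 0).any():
        raise ValueError("some valid pixels received zero votes")
    if tie_break == "low":
        fused = counts.argmax(axis=0) + 1  # argmax picks the first (lowest) max
    else:
        fused = 5 - counts[::-1].argmax(axis=0)
    fused = fused.astype(np.uint8)
    fused[~stack.valid_mask] = 0
    return fused


@dataclasses.dataclass
class GradeResult:
    """Slide-level grading outcome."""

    gp_histogram: dict[int, int]  # tissue pixel counts per label 1..5
    primary_pattern: int | None  # in {3,4,5} or None when benign
    secondary_pattern: int | None
    gleason_score: int | None  # 6..10 or None when benign
    grade_group: int  # 0 = Benign, 1..5 = GG1..GG5
    malignant_fraction: float

    @property
    def grade_group_name(self) -> str:
        return "Benign" if self.grade_group == 0 else f"GG{self.grade_group}"

    def to_dict(self) -> dict:
        return {
            "gp_histogram": {int(k): int(v) for k, v in self.gp_histogram.items()},
            "primary_pattern": self.primary_pattern,
            "secondary_pattern": self.secondary_pattern,
            "gleason_score": self.gleason_score,
            "grade_group": self.grade_group,
            "grade_group_name": self.grade_group_name,
            "malignant_fraction": self.malignant_fraction,
        }


def grade_group_for_pair(primary: int, secondary: int) -> int:
    """Grade group index for an ordered malignant pattern pair."""
    key = (int(primary), int(secondary))
    if key not in GRADE_GROUP_TABLE:
        raise ValueError(f"patterns must be in {MALIGNANT}, got {key}")
    return GRADE_GROUP_TABLE[key]


def grade_from_gp_map(
    gp_map: np.ndarray,
    tissue_mask: np.ndarray | None = None,
    benign_threshold: float = 0.005,
) -> GradeResult:
    """Derive score and grade group from a fused label map.

    primary = malignant label with the largest tissue area, secondary = the
    second largest (primary again if it is the only malignant label; no
    minimum secondary-area rule).  If the malignant fraction of tissue falls
    below ``benign_threshold`` the slide is Benign.
    """
    gp_map = np.asarray(gp_map)
    if tissue_mask is None:
        tissue_mask = gp_map != 0
    labels = gp_map[np.asarray(tissue_mask, dtype=bool)]
    labels = labels[labels != 0]
    if labels.size == 0:
        raise ValueError("no tissue pixels to grade")
    counts = np.bincount(labels, minlength=6)
    hist = {lab: int(counts[lab]) for lab in (1, 2, 3, 4, 5)}
    mal_counts = {lab: hist[lab] for lab in MALIGNANT if hist[lab] > 0}
    mal_fraction = float(sum(mal_counts.values()) / labels.size)

    if not mal_counts or mal_fraction < benign_threshold:
        return GradeResult(hist, None, None, None, 0, mal_fraction)

    # sort by area desc, lower label first on equal area (deterministic)
    ranked = sorted(mal_counts.items(), key=lambda kv: (-kv[1], kv[0]))
    primary = ranked[0][0]
    secondary = ranked[1][0] if len(ranked) > 1 else primary
    gs = primary + secondary
    gg = grade_group_for_pair(primary, secondary)
    return GradeResult(hist, primary, secondary, gs, gg, mal_fraction)
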