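"""Overlapping patch-group generation and training-patch selection.

For one patch size ``S`` and shift fraction ``f`` (default 0.2) the slide is
covered by ``1 + 3*(1/f - 1)`` complete non-overlapping tilings ("patch
groups"): the unshifted grid plus, for each direction in {X, Y, diagonal}
and each step k in 1..(1/f - 1), the grid whose anchor is offset by
``k*f*S`` along that direction.  At the default 20% shift that is 13 groups
per level and 39 across the three default levels.

Coordinates are 0-based and row-major; a patch occupies the half-open
window ``[row, row+S) x [col, col+S)``.  Shifted grids are anchored at
``offset - S`` so that every canvas pixel is covered by exactly one patch of
every group; windows reaching outside the canvas are padded with background.
"""

from __future__ import annotations

import dataclasses
from typing import Iterator, Sequence

import numpy as np

from .preprocess import PreprocessConfig, tissue_mask
from .synthetic import SlideImage

__all__ = [
    "LevelConfig",
    "PatchRef",
    "PatchGroup",
    "PatchSelectionRecord",
    "DEFAULT_LEVELS",
    "generate_patch_groups",
    "select_training_patches",
    "selection_records",
    "background_ratio",
    "modal_tissue_label",
    "extract_window",
    "paint_group_labels",
]

_DIRECTIONS = ("x", "y", "diag")


@dataclasses.dataclass(frozen=True)
class LevelConfig:
    """One pyramid level: patch side ``S`` and the per-step shift fraction."""

    S: int
    shift_fraction: float = 0.2

    def validate(self) -> None:
        if self.S < 1:
            raise ValueError("S must be positive")
        if not (0.0 < self.shift_fraction < 1.0):
            raise ValueError("shift_fraction must lie in (0, 1)")
        inv = 1.0 / self.shift_fraction
        if abs(inv - round(inv)) > 1e-9:
            raise ValueError("1/shift_fraction must be an integer")
        step = self.S * self.shift_fraction
        if abs(step - round(step)) > 1e-9:
            raise ValueError("S * shift_fraction must be a whole number of pixels")

    @property
    def step(self) -> int:
        """Shift step in pixels."""
        return int(round(self.S * self.shift_fraction))

    @property
    def steps_per_cycle(self) -> int:
        """Number of shift steps after which the grid returns to its origin."""
        return int(round(1.0 / self.shift_fraction))

    @property
    def n_groups(self) -> int:
        """Group count: the unshifted grid plus shifted grids in 3 directions."""
        return 1 + 3 * (self.steps_per_cycle - 1)


DEFAULT_LEVELS: tuple[LevelConfig, ...] = (
    LevelConfig(100),
    LevelConfig(75),
    LevelConfig(50),
)


@dataclasses.dataclass(frozen=True)
class PatchRef:
    """Locates one patch: level size, group, and top-left origin (may be
    negative for shifted groups; the window is then background-padded)."""

    level_s: int
    group_id: int
    origin: tuple[int, int]
    size: int


@dataclasses.dataclass(frozen=True)
class PatchGroup:
    """One complete tiling of the canvas at a given level and anchor offset."""

    level: LevelConfig
    group_id: int  # 0 = unshifted; 1..4 X, 5..8 Y, 9..12 diagonal (20% shift)
    offset: tuple[int, int]  # (row, col) anchor shift in pixels
    canvas_shape: tuple[int, int]

    def _starts(self, extent: int, off: int) -> list[int]:
        s = self.level.S
        first = off - s if off > 0 else 0
        return list(range(first, extent, s))

    @property
    def row_starts(self) -> list[int]:
        return self._starts(self.canvas_shape[0], self.offset[0])

    @property
    def col_starts(self) -> list[int]:
        return self._starts(self.canvas_shape[1], self.offset[1])

    def __len__(self) -> int:
        return len(self.row_starts) * len(self.col_starts)

    def refs(self) -> Iterator[PatchRef]:
        for r in self.row_starts:
            for c in self.col_starts:
                yield PatchRef(self.level.S, self.group_id, (r, c), self.level.S)


def generate_patch_groups(
    slide: SlideImage | tuple[int, int], level: LevelConfig
) -> list[PatchGroup]:
    """All complete tilings of the slide at one level (13 at 20% shift)."""
    level.validate()
    shape = slide if isinstance(slide, tuple) else slide.shape
    h, w = shape
    if h < level.S or w < level.S:
        raise ValueError(f"slide {shape} smaller than patch size {level.S}")

    step = level.step
    groups = [PatchGroup(level, 0, (0, 0), shape)]
    gid = 1
    for direction in _DIRECTIONS:
        for k in range(1, level.steps_per_cycle):
            d = k * step
            if direction == "x":
                off = (0, d)
            elif direction == "y":
                off = (d, 0)
            else:
                off = (d, d)
            groups.append(PatchGroup(level, gid, off, shape))
            gid += 1
    assert len(groups) == level.n_groups
    return groups


def extract_window(
    arr: np.ndarray, origin: tuple[int, int], size: int, fill
) -> np.ndarray:
    """Window ``[r, r+size) x [c, c+size)`` of ``arr``, background-padded
    where it reaches outside the canvas."""
    h, w = arr.shape[:2]
    r, c = origin
    out_shape = (size, size) + arr.shape[2:]
    out = np.full(out_shape, fill, dtype=arr.dtype)
    r0, r1 = max(r, 0), min(r + size, h)
    c0, c1 = max(c, 0), min(c + size, w)
    if r0 < r1 and c0 < c1:
        out[r0 - r : r1 - r, c0 - c : c1 - c] = arr[r0:r1, c0:c1]
    return out


def background_ratio(label_window: np.ndarray) -> float:
    """Fraction of background pixels in a patch window.

    Accepts a label window (background == 0) or a boolean tissue mask window
    (background == False).
    """
    window = np.asarray(label_window)
    if window.dtype == bool:
        return float(np.mean(~window))
    return float(np.mean(window == 0))


def modal_tissue_label(label_window: np.ndarray) -> tuple[int | None, bool]:
    """Most frequent tissue label (1..5) in the window.

    Returns ``(label, tie)``; label is None when the window has no tissue.
    Ties report the lowest tied label with ``tie=True``.
    """
    counts = np.bincount(np.asarray(label_window).ravel(), minlength=6)[1:6]
    if counts.sum() == 0:
        return None, False
    top = int(np.argmax(counts))
    tie = int(np.sum(counts == counts[top])) > 1
    return top + 1, tie


@dataclasses.dataclass(frozen=True)
class PatchSelectionRecord:
    """Algorithm-1 bookkeeping for one candidate training patch."""

    ref: PatchRef
    mv: int | None  # modal tissue label
    pc: int  # ground-truth label at the patch center
    br: float  # background ratio
    tie: bool
    selected: bool


def selection_records(
    slide: SlideImage, level: LevelConfig, max_br: float = 0.5
) -> list[PatchSelectionRecord]:
    """Evaluate the training-patch filter on every unshifted-grid patch.

    A patch is selected iff its modal tissue label equals the ground-truth
    label of its center pixel (so the center is tissue), the modal label is
    unambiguous, and the background ratio is <= ``max_br`` (boundary
    inclusive).
    """
    if slide.label_map is None:
        raise ValueError("training-patch selection requires a ground-truth label map")
    level.validate()
    lm = np.asarray(slide.label_map)
    h, w = lm.shape
    s = level.S
    group0 = generate_patch_groups((h, w), level)[0]
    records = []
    for ref in group0.refs():
        window = extract_window(lm, ref.origin, s, fill=0)
        mv, tie = modal_tissue_label(window)
        cr, cc = ref.origin[0] + s // 2, ref.origin[1] + s // 2
        pc = int(lm[cr, cc]) if (0 <= cr < h and 0 <= cc < w) else 0
        br = background_ratio(window)
        selected = (mv is not None) and (not tie) and (mv == pc) and (br <= max_br)
        records.append(PatchSelectionRecord(ref, mv, pc, br, tie, selected))
    return records


def select_training_patches(
    slide: SlideImage, level: LevelConfig, max_br: float = 0.5
) -> list[tuple[np.ndarray, int]]:
    """Return ``(patch_rgb, label)`` pairs passing the selection filter."""
    rgb = np.asarray(slide.rgb)
    out = []
    for rec in selection_records(slide, level, max_br=max_br):
        if rec.selected:
            patch = extract_window(rgb, rec.ref.origin, rec.ref.size, fill=255)
            out.append((patch, int(rec.mv)))
    return out


def paint_group_labels(
    group: PatchGroup, labels: Sequence[int]
) -> np.ndarray:
    """Rasterize one predicted label per patch onto the canvas.

    ``labels`` follows the order of :meth:`PatchGroup.refs`.  Because each
    group tiles the canvas exactly, the result assigns one label to every
    canvas pixel.
    """
    h, w = group.canvas_shape
    out = np.zeros((h, w), dtype=np.uint8)
    refs = list(group.refs())
    if len(labels) != len(refs):
        raise ValueError(f"expected {len(refs)} labels, got {len(labels)}")
    s = group.level.S
    for ref, lab in zip(refs, labels):
        r, c = ref.origin
        out[max(r, 0) : r + s, max(c, 0) : c + s] = lab
    return out


def write_patch_manifest(groups: Sequence[PatchGroup], path) -> None:
    """Dump all patch references of the given groups as a CSV manifest."""
    import pandas as pd

    rows = [
        {
            "level": ref.level_s,
            "group_id": ref.group_id,
            "row": ref.origin[0],
            "col": ref.origin[1],
            "size": ref.size,
        }
        for group in groups
        for ref in group.refs()
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def slide_tissue_labels(slide: SlideImage, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Label raster used for patch bookkeeping: the ground truth when present,
    otherwise a binarized tissue mask (1 = tissue)."""
    if slide.label_map is not None:
        return np.asarray(slide.label_map)
    return tissue_mask(slide, cfg).astype(np.uint8)
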