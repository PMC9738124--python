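"""Seeded generator of histology-like slides with known per-pixel ground truth.

A synthetic slide is a near-white canvas carrying one connected tissue
silhouette.  The silhouette is partitioned into contiguous blobs (a random
Voronoi mosaic) whose per-class areas follow a configurable prevalence, and
each class is painted with a distinct procedural texture so that a small
classifier can separate the classes from pixel statistics alone.

Label conventions: 0 = background, 1..5 = tissue pattern classes with 1
("stroma") the most prevalent by default and 5 the rarest.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

__all__ = [
    "SyntheticSpec",
    "SlideImage",
    "DEFAULT_PREVALENCE",
    "DEFAULT_TEXTURES",
    "make_label_map",
    "render_slide",
    "make_slide",
    "save_slide",
    "save_label_png",
    "load_slide",
]

GP_LABELS = (1, 2, 3, 4, 5)

#: Default class mix: label 1 dominant (~40% of tissue), label 5 rare.
DEFAULT_PREVALENCE: dict[int, float] = {1: 0.40, 2: 0.20, 3: 0.20, 4: 0.15, 5: 0.05}

#: Per-class procedural texture descriptors.  ``base`` is the mean RGB color,
#: ``granularity`` the correlation length of the band-limited noise in pixels,
#: ``noise_amplitude`` the peak amplitude of noise + motif, ``motif`` a
#: deterministic spatial pattern mixed into the noise channel.
DEFAULT_TEXTURES: dict[int, dict] = {
    # base hues are spread far apart so class identity survives slide-wide
    # luminance equalization (which preserves chroma but stretches intensity)
    1: {"base": (232, 148, 170), "granularity": 6.0, "noise_amplitude": 18.0, "motif": "none"},
    2: {"base": (130, 160, 225), "granularity": 4.0, "noise_amplitude": 18.0, "motif": "dots"},
    3: {"base": (135, 200, 130), "granularity": 3.0, "noise_amplitude": 20.0, "motif": "stripes"},
    4: {"base": (225, 175, 100), "granularity": 2.0, "noise_amplitude": 20.0, "motif": "dots"},
    5: {"base": (120, 60, 160), "granularity": 1.5, "noise_amplitude": 22.0, "motif": "stripes"},
}

BACKGROUND_RGB = 252  # near-white; all channels >= 245 before noise

_PREVALENCE_TOL = 1e-6


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Full description of one synthetic slide; the seed determines all output.

    Parameters
    ----------
    width, height:
        Canvas size in pixels.
    class_prevalence:
        Mapping label -> fraction of *tissue* area; must sum to 1 over 1..5.
    texture_params:
        Per-class texture descriptors (see :data:`DEFAULT_TEXTURES`).
    tissue_fraction:
        Fraction of the canvas covered by the tissue silhouette.
    n_regions:
        Number of Voronoi cells used to partition the silhouette.  More cells
        give finer-grained mosaics and tighter prevalence matching.
    seed:
        Integer seed; identical specs produce bit-identical slides.
    """

    width: int = 600
    height: int = 600
    class_prevalence: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_PREVALENCE)
    )
    texture_params: Mapping[int, dict] = dataclasses.field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_TEXTURES.items()}
    )
    tissue_fraction: float = 0.55
    n_regions: int = 160
    seed: int = 0

    def validate(self) -> None:
        if self.width < 3 or self.height < 3:
            raise ValueError("canvas must be at least 3x3 pixels")
        prevs = {int(k): float(v) for k, v in self.class_prevalence.items()}
        if any(k not in GP_LABELS for k in prevs):
            raise ValueError(f"prevalence keys must be in {GP_LABELS}, got {sorted(prevs)}")
        if any(v < 0 for v in prevs.values()):
            raise ValueError("prevalences must be >= 0")
        total = sum(prevs.values())
        if abs(total - 1.0) > _PREVALENCE_TOL:
            raise ValueError(f"class prevalences must sum to 1, got {total}")
        if not (0.0 < self.tissue_fraction < 1.0):
            raise ValueError("tissue_fraction must lie in (0, 1)")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")

    def prevalence_vector(self) -> np.ndarray:
        """Prevalence as a length-5 array indexed by label-1."""
        v = np.zeros(5)
        for k, p in self.class_prevalence.items():
            v[int(k) - 1] = p
        return v

    def to_dict(self) -> dict:
        return {
            "width": self.width,
            "height": self.height,
            "class_prevalence": {int(k): float(v) for k, v in self.class_prevalence.items()},
            "texture_params": {int(k): dict(v) for k, v in self.texture_params.items()},
            "tissue_fraction": self.tissue_fraction,
            "n_regions": self.n_regions,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "SyntheticSpec":
        d = dict(d)
        if "class_prevalence" in d:
            d["class_prevalence"] = {int(k): float(v) for k, v in d["class_prevalence"].items()}
        if "texture_params" in d:
            tex = {}
            for k, v in d["texture_params"].items():
                v = dict(v)
                if "base" in v:
                    v["base"] = tuple(v["base"])
                tex[int(k)] = v
            d["texture_params"] = tex
        return cls(**d)


@dataclasses.dataclass
class SlideImage:
    """An RGB raster with an optional per-pixel ground-truth label map."""

    rgb: np.ndarray  # H x W x 3, uint8
    label_map: np.ndarray | None = None  # H x W, uint8, 0=background

    def __post_init__(self) -> None:
        rgb = np.asarray(self.rgb)
        if rgb.ndim != 3 or rgb.shape[2] != 3:
            raise ValueError(f"rgb must be HxWx3, got shape {rgb.shape}")
        if self.label_map is not None:
            lm = np.asarray(self.label_map)
            if lm.shape != rgb.shape[:2]:
                raise ValueError("label_map shape must match rgb")
            bad = set(np.unique(lm)) - {0, 1, 2, 3, 4, 5}
            if bad:
                raise ValueError(f"label_map contains invalid labels {sorted(bad)}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


def _tissue_silhouette(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    """A single connected star-convex blob covering ~tissue_fraction of canvas.

    The blob is defined in polar coordinates around the canvas center with a
    smoothly varying radius; the radial scale is tuned by bisection so that
    the clipped blob area matches the target fraction.
    """
    h, w = spec.height, spec.width
    yy, xx = np.mgrid[0:h, 0:w]
    cy = h / 2 + rng.uniform(-0.05, 0.05) * h
    cx = w / 2 + rng.uniform(-0.05, 0.05) * w
    theta = np.arctan2(yy - cy, xx - cx)
    rr = np.hypot(yy - cy, xx - cx)

    # band-limited periodic radius modulation
    n_harm = 6
    amp = 0.18
    mod = np.zeros_like(theta)
    for k in range(1, n_harm + 1):
        a = rng.normal() / k
        b = rng.normal() / k
        mod += a * np.cos(k * theta) + b * np.sin(k * theta)
    mod = 1.0 + amp * mod / max(1.0, np.abs(mod).max())

    target = spec.tissue_fraction * h * w

    def area(scale: float) -> float:
        return float(np.count_nonzero(rr <= scale * mod))

    lo, hi = 1.0, float(np.hypot(h, w))
    for _ in range(50):
        mid = 0.5 * (lo + hi)
        if area(mid) < target:
            lo = mid
        else:
            hi = mid
    scale = 0.5 * (lo + hi)
    return rr <= scale * mod


def make_label_map(spec: SyntheticSpec) -> np.ndarray:
    """Generate the ground-truth label raster for ``spec``.

    Returns an ``(height, width)`` uint8 array with 0 outside the tissue
    silhouette and labels 1..5 inside, with per-class tissue-area fractions
    matching ``spec.class_prevalence`` to within about +/-2 percentage points
    for canvases of a few hundred pixels and up.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    tissue = _tissue_silhouette(spec, rng)
    n_tissue = int(tissue.sum())
    if n_tissue == 0:
        raise ValueError("tissue silhouette is empty; increase tissue_fraction or canvas")

    prev = spec.prevalence_vector()
    active = np.nonzero(prev > 0)[0]  # label-1 indices
    if active.size == 1:
        out = np.zeros((spec.height, spec.width), dtype=np.uint8)
        out[tissue] = active[0] + 1
        return out

    # Voronoi mosaic: seeds inside tissue, nearest-seed cells.
    ty, tx = np.nonzero(tissue)
    n_cells = min(spec.n_regions, ty.size)
    pick = rng.choice(ty.size, size=n_cells, replace=False)
    seeds = np.stack([ty[pick], tx[pick]], axis=1).astype(np.float64)

    pts = np.stack([ty, tx], axis=1).astype(np.float64)
    # chunked nearest-seed assignment to bound memory
    cell_of = np.empty(ty.size, dtype=np.int64)
    chunk = 1 << 18
    for start in range(0, pts.shape[0], chunk):
        block = pts[start : start + chunk]
        d2 = ((block[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        cell_of[start : start + block.shape[0]] = np.argmin(d2, axis=1)

    cell_areas = np.bincount(cell_of, minlength=n_cells)

    # Contiguous class regions: order cells by (slightly noised) distance of
    # their seed from a random anchor, then slice the ordered list into
    # consecutive runs whose cumulative areas match the class quotas.  Each
    # class then occupies one connected-ish swath of the mosaic instead of a
    # salt-and-pepper scatter, so regions stay large relative to the patch
    # sizes downstream.  The per-class area error is at most one cell.
    anchor = np.array(
        [rng.uniform(-0.3, 1.3) * spec.height, rng.uniform(-0.3, 1.3) * spec.width]
    )
    dist = np.hypot(seeds[:, 0] - anchor[0], seeds[:, 1] - anchor[1])
    dist = dist * (1.0 + rng.normal(scale=0.04, size=n_cells))
    order = np.argsort(dist)

    class_order = rng.permutation(active)
    quotas = prev[class_order] * n_tissue
    cum_quota = np.cumsum(quotas)
    cell_class = np.empty(n_cells, dtype=np.int64)
    acc = 0.0
    k = 0
    for c in order:
        # advance to the next class once its quota is met (boundary cell goes
        # to whichever side leaves the smaller error)
        while k < len(class_order) - 1 and acc + cell_areas[c] / 2.0 >= cum_quota[k]:
            k += 1
        cell_class[c] = class_order[k]
        acc += cell_areas[c]

    out = np.zeros((spec.height, spec.width), dtype=np.uint8)
    out[ty, tx] = cell_class[cell_of] + 1
    return out


def _motif_field(kind: str, h: int, w: int, granularity: float) -> np.ndarray:
    """Deterministic zero-centered spatial pattern in [-1, 1]."""
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    period = max(3.0, 4.0 * granularity)
    if kind == "stripes":
        return np.sin(2 * np.pi * (xx + 0.5 * yy) / period)
    if kind == "dots":
        return np.sin(2 * np.pi * xx / period) * np.sin(2 * np.pi * yy / period)
    if kind == "none":
        return np.zeros((h, w))
    raise ValueError(f"unknown motif {kind!r}")


def render_slide(label_map: np.ndarray, spec: SyntheticSpec) -> SlideImage:
    """Paint each label with its procedural texture; background stays near-white.

    With ``noise_amplitude`` 0 for a class, its pixels are exactly the base
    color, which makes class separability directly tunable in tests.
    """
    label_map = np.asarray(label_map)
    h, w = label_map.shape
    labels_present = set(np.unique(label_map)) - {0}
    unknown = labels_present - set(int(k) for k in spec.texture_params)
    if unknown:
        raise ValueError(f"no texture configured for labels {sorted(unknown)}")

    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x7E57]))
    img = np.full((h, w, 3), float(BACKGROUND_RGB))

    for label in sorted(labels_present):
        params = spec.texture_params[int(label)]
        mask = label_map == label
        base = np.asarray(params["base"], dtype=np.float64)
        gran = float(params.get("granularity", 3.0))
        amp = float(params.get("noise_amplitude", 20.0))
        motif = _motif_field(str(params.get("motif", "none")), h, w, gran)

        # band-limited noise, normalized to unit peak before scaling
        noise = rng.normal(size=(h, w, 3))
        noise = gaussian_filter(noise, sigma=(gran, gran, 0))
        peak = np.abs(noise).max()
        if peak > 0:
            noise /= peak

        field = base[None, None, :] + amp * (0.7 * noise + 0.3 * motif[:, :, None])
        img[mask] = field[mask]

    # faint background speckle so the canvas is not a constant field
    bg = label_map == 0
    if bg.any():
        bg_noise = rng.normal(scale=0.8, size=(h, w, 3))
        img[bg] = np.clip(img[bg] + bg_noise[bg], 246, 255)

    rgb = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return SlideImage(rgb=rgb, label_map=label_map.astype(np.uint8))


def make_slide(spec: SyntheticSpec) -> SlideImage:
    """Convenience wrapper: label map + rendering in one call."""
    return render_slide(make_label_map(spec), spec)


# -- file I/O ---------------------------------------------------------------

_PALETTE = {
    0: (255, 255, 255),
    1: (231, 178, 202),
    2: (198, 168, 224),
    3: (168, 118, 188),
    4: (118, 82, 158),
    5: (76, 40, 108),
}


def save_label_png(label_map: np.ndarray, path: Path | str) -> Path:
    """Write a label raster as a paletted PNG."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = Image.fromarray(np.asarray(label_map, dtype=np.uint8), mode="P")
    palette = []
    for i in range(256):
        palette.extend(_PALETTE.get(i, (0, 0, 0)))
    img.putpalette(palette)
    img.save(path)
    return path


def save_slide(slide: SlideImage, stem: Path | str, spec: SyntheticSpec | None = None) -> list[Path]:
    """Write ``<stem>.png`` (RGB), ``<stem>_labels.png`` (paletted) and an
    optional ``<stem>.json`` sidecar with the generating spec."""
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    written = []
    rgb_path = stem.with_suffix(".png")
    Image.fromarray(slide.rgb, mode="RGB").save(rgb_path)
    written.append(rgb_path)
    if slide.label_map is not None:
        lab_path = save_label_png(slide.label_map, stem.parent / f"{stem.name}_labels.png")
        written.append(lab_path)
    if spec is not None:
        json_path = stem.with_suffix(".json")
        json_path.write_text(json.dumps(spec.to_dict(), indent=2))
        written.append(json_path)
    return written


def load_slide(stem: Path | str) -> SlideImage:
    """Load a slide written by :func:`save_slide`; the label map is optional."""
    stem = Path(stem)
    rgb = np.asarray(Image.open(stem.with_suffix(".png")).convert("RGB"))
    lab_path = stem.parent / f"{stem.name}_labels.png"
    label_map = None
    if lab_path.exists():
        label_map = np.asarray(Image.open(lab_path)).astype(np.uint8)
    return SlideImage(rgb=rgb, label_map=label_map)
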