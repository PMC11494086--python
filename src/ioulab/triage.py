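"""Whole-slide patch triage for lymphocytic infiltration, at desk scale.

The pipeline mirrors an auxiliary-diagnosis flow for labial-gland biopsy
slides: filter the background of the slide, tile the tissue into fixed-size
patches, count lymphocytes per patch through a pluggable detector, flag
patches whose count strictly exceeds a threshold, and render a red overlay of
flagged patches for review.

The real trained detector is represented only as an interface — any callable
``detector(patch_pixels, patch) -> int``. The shipped default is the
synthetic-fixture oracle, which reads the ground-truth ledger emitted by
:func:`make_synthetic_slide`; a simple stain-blob counter is provided for
running the pipeline on arbitrary rasters. Slides are plain PNG/TIFF RGB
rasters; pyramidal WSI formats are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from skimage import color, draw, filters, measure, transform

__all__ = [
    "SlideImage",
    "Patch",
    "PatchGrid",
    "TriageResult",
    "filter_background",
    "tile",
    "count_patches",
    "flag",
    "make_synthetic_slide",
    "ledger_oracle_detector",
    "blob_count_detector",
    "render_overlay",
    "run_triage",
]

# pink tissue and dark-purple nuclei, roughly H&E-like
_TISSUE_RGB = np.array([228, 160, 183], dtype=float)
_CELL_RGB = np.array([104, 58, 138], dtype=float)

_SAT_FLOOR = 0.02  # saturation below this counts as (white) background
_SAT_CAP = 0.35  # saturations are clipped here before choosing the threshold


@dataclass
class SlideImage:
    """An RGB slide raster with optional microns-per-pixel metadata."""

    pixels: np.ndarray  # (H, W, 3) uint8
    mpp: Optional[float] = None

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("SlideImage expects an (H, W, 3) RGB raster")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    @classmethod
    def open(cls, path, mpp=None) -> "SlideImage":
        from PIL import Image

        with Image.open(path) as im:
            return cls(np.asarray(im.convert("RGB")), mpp=mpp)

    def save(self, path):
        from PIL import Image

        Image.fromarray(self.pixels.astype(np.uint8)).save(path)


@dataclass(frozen=True)
class Patch:
    row: int
    col: int
    x: int  # left offset in pixels
    y: int  # top offset in pixels


@dataclass
class PatchGrid:
    """Non-overlapping tiling of a slide; edge remainders are dropped."""

    patch_size: int
    stride: int
    patches: list[Patch]

    def extract(self, slide: SlideImage, patch: Patch) -> np.ndarray:
        s = self.patch_size
        return slide.pixels[patch.y:patch.y + s, patch.x:patch.x + s]


@dataclass
class TriageResult:
    """Per-patch counts and flags; ``flag == (count > threshold)``."""

    counts: np.ndarray  # (n,) int; -1 marks a patch whose detector failed
    flags: np.ndarray  # (n,) bool
    threshold: int
    errors: dict[int, str] = field(default_factory=dict)

    @property
    def total_count(self) -> int:
        return int(self.counts[self.counts >= 0].sum())

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


# -------------------------------------------------------------------------
# pipeline stages
# -------------------------------------------------------------------------

def filter_background(slide: SlideImage, *, max_thumb: int = 512) -> np.ndarray:
    """Boolean tissue mask at slide resolution.

    Saturation-channel thresholding: stained tissue is saturated, white slide
    background is not. The global threshold is chosen automatically (Otsu) on
    a downsampled copy, over pixels above a small saturation floor so that
    pure-white area — however much of it there is — cannot shift it.
    """
    sat = color.rgb2hsv(slide.pixels)[..., 1]
    factor = max(1, int(np.ceil(max(slide.height, slide.width) / max_thumb)))
    # clipping merges the strongly stained modes (nuclei) with the tissue
    # mode, so the automatic threshold separates white from stained rather
    # than pale tissue from dark nuclei
    thumb = np.minimum(sat[::factor, ::factor], _SAT_CAP)
    if thumb.max() <= _SAT_FLOOR:
        return np.zeros(sat.shape, dtype=bool)
    if thumb.min() == thumb.max():
        thr = thumb.max() / 2.0
    else:
        thr = filters.threshold_otsu(thumb)
    # never keep near-white pixels, whatever the histogram looks like
    thr = max(thr, _SAT_FLOOR)
    return sat > thr


def tile(slide: SlideImage, mask: Optional[np.ndarray] = None, *,
         patch_size: int = 640, stride: Optional[int] = None,
         min_tissue_fraction: float = 0.05) -> PatchGrid:
    """Regular non-overlapping grid of ``patch_size`` tiles.

    Patches with less than ``min_tissue_fraction`` tissue by mask are
    dropped; edge remainders are dropped so every patch is exactly
    ``patch_size`` square.
    """
    stride = patch_size if stride is None else stride
    if slide.height < patch_size or slide.width < patch_size:
        raise ValueError(
            f"slide {slide.width}x{slide.height} smaller than one "
            f"{patch_size}-pixel patch"
        )
    patches = []
    n_rows = (slide.height - patch_size) // stride + 1
    n_cols = (slide.width - patch_size) // stride + 1
    for r in range(n_rows):
        for c in range(n_cols):
            y, x = r * stride, c * stride
            if mask is not None:
                frac = mask[y:y + patch_size, x:x + patch_size].mean()
                if frac < min_tissue_fraction:
                    continue
            patches.append(Patch(row=r, col=c, x=x, y=y))
    return PatchGrid(patch_size=patch_size, stride=stride, patches=patches)


def count_patches(slide: SlideImage, grid: PatchGrid,
                  detector: Callable) -> tuple[np.ndarray, dict[int, str]]:
    """Apply the per-patch detector; returns (counts, errors).

    A detector failure on a patch is recorded (count -1 and an error entry),
    never silently zero.
    """
    counts = np.empty(len(grid.patches), dtype=np.int64)
    errors: dict[int, str] = {}
    for i, patch in enumerate(grid.patches):
        try:
            c = int(detector(grid.extract(slide, patch), patch))
            if c < 0:
                raise ValueError(f"detector returned negative count {c}")
            counts[i] = c
        except Exception as exc:  # noqa: BLE001 - contract: record, don't hide
            counts[i] = -1
            errors[i] = f"{type(exc).__name__}: {exc}"
    return counts, errors


def flag(counts: Sequence[int], threshold: int = 50) -> TriageResult:
    """Flag patches whose count strictly exceeds the threshold.

    The threshold default (50 cells per patch) is a configuration choice,
    not a clinically fixed value. Invalid patches (count -1) are never
    flagged but remain visible through ``TriageResult.errors``.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    counts = np.asarray(counts, dtype=np.int64)
    return TriageResult(
        counts=counts, flags=counts > threshold, threshold=int(threshold)
    )


# -------------------------------------------------------------------------
# synthetic slides and detectors
# -------------------------------------------------------------------------

def make_synthetic_slide(counts_per_patch: dict[tuple[int, int], int], *,
                         patch_size: int = 640, n_rows: int = 2, n_cols: int = 2,
                         seed: int = 0, cell_radius: float = 6.0,
                         mpp: Optional[float] = None):
    """Deterministic synthetic slide plus its ground-truth cell ledger.

    Emulates an H&E-stained section at patch scale: every patch listed in
    ``counts_per_patch`` (keyed by ``(row, col)``) gets a pale-pink tissue
    wash and the requested number of dark-purple cell ellipses, the dense
    focal aggregates the triage flow is meant to flag; unlisted patches stay
    white background. Returns ``(SlideImage, ledger)`` where the ledger is a
    DataFrame with one row per generated cell (x, y, row, col).
    """
    rng = np.random.default_rng(seed)
    H, W = n_rows * patch_size, n_cols * patch_size
    pixels = np.full((H, W, 3), 255.0)

    records = []
    for (row, col), n_cells in sorted(counts_per_patch.items()):
        if not (0 <= row < n_rows and 0 <= col < n_cols):
            raise ValueError(f"patch ({row}, {col}) outside the {n_rows}x{n_cols} grid")
        y0, x0 = row * patch_size, col * patch_size
        # tissue wash with mild texture so the region is saturated
        texture = rng.uniform(0.85, 1.0, (patch_size, patch_size, 1))
        pixels[y0:y0 + patch_size, x0:x0 + patch_size] = (
            255.0 - (255.0 - _TISSUE_RGB) * texture
        )
        margin = int(np.ceil(2 * cell_radius)) + 1
        for _ in range(int(n_cells)):
            cy = y0 + rng.uniform(margin, patch_size - margin)
            cx = x0 + rng.uniform(margin, patch_size - margin)
            ry = cell_radius * rng.uniform(0.7, 1.0)
            rx = cell_radius * rng.uniform(0.7, 1.0)
            rr, cc = draw.ellipse(cy, cx, ry, rx, shape=(H, W))
            pixels[rr, cc] = _CELL_RGB
            records.append({"x": cx, "y": cy, "row": row, "col": col})

    ledger = pd.DataFrame(records, columns=["x", "y", "row", "col"])
    return SlideImage(pixels.astype(np.uint8), mpp=mpp), ledger


def ledger_oracle_detector(ledger: pd.DataFrame) -> Callable:
    """Detector that reads the synthetic ground truth: counts ledger cells
    whose center falls inside the patch bounds."""

    x = ledger["x"].to_numpy() if len(ledger) else np.empty(0)
    y = ledger["y"].to_numpy() if len(ledger) else np.empty(0)

    def detector(pixels: np.ndarray, patch: Patch) -> int:
        s = pixels.shape[0]
        inside = (
            (x >= patch.x) & (x < patch.x + s) & (y >= patch.y) & (y < patch.y + s)
        )
        return int(inside.sum())

    return detector


def blob_count_detector(pixels: np.ndarray, patch: Patch = None) -> int:
    """Image-based counter: connected components of dark, stained blobs.

    Intended for synthetic-style rasters with well-separated nuclei; a stand-in
    for a trained detector, not a validated cell counter.
    """
    hsv = color.rgb2hsv(pixels)
    dark_stained = (hsv[..., 2] < 0.75) & (hsv[..., 1] > 0.25)
    labels = measure.label(dark_stained)
    props = measure.regionprops(labels)
    return sum(1 for p in props if p.area >= 9)


# -------------------------------------------------------------------------
# rendering and the end-to-end flow
# -------------------------------------------------------------------------

def render_overlay(slide: SlideImage, grid: PatchGrid, result: TriageResult,
                   *, border: int = 6, tint: float = 0.25) -> np.ndarray:
    """Red-highlight flagged patches; unflagged pixels are untouched."""
    out = slide.pixels.astype(float).copy()
    red = np.array([255.0, 0.0, 0.0])
    s = grid.patch_size
    for patch, flagged in zip(grid.patches, result.flags):
        if not flagged:
            continue
        block = out[patch.y:patch.y + s, patch.x:patch.x + s]
        block[:] = (1 - tint) * block + tint * red
        block[:border], block[-border:] = red, red
        block[:, :border], block[:, -border:] = red, red
    return out.astype(np.uint8)


def run_triage(slide: SlideImage, detector: Callable, *, patch_size: int = 640,
               threshold: int = 50, min_tissue_fraction: float = 0.05):
    """Full pipeline: background filter → tile → count → flag.

    Returns ``(grid, result)``.
    """
    mask = filter_background(slide)
    grid = tile(slide, mask, patch_size=patch_size,
                min_tissue_fraction=min_tissue_fraction)
    counts, errors = count_patches(slide, grid, detector)
    result = flag(counts, threshold=threshold)
    result.errors = errors
    result.flags = result.flags & (counts >= 0)
    return grid, result
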