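"""Panicle coverage from canopy images via a pluggable segmenter.

The measurement pipeline: a nadir canopy image covering roughly 1 m^2 is
resized to 1536 x 1536 pixels, divided into nine 512 x 512 tiles, each tile
is segmented into panicle / background, per-tile coverage is the fraction
of panicle pixels (PC = PA / (PA + BA)), and the plot's coverage is the
arithmetic mean of the nine tiles. For equal-area tiles this mean equals
the coverage of the stitched mask exactly.

A segmenter is any callable mapping an RGB tile (H x W x 3) to a binary
mask of the same height and width. Deep segmentation networks plug in
through this contract; the module ships a deterministic color-rule
segmenter (an RGB box classifier) so the pipeline runs end-to-end without
trained weights, and an adapter that serves precomputed mask files.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize

from .dataset_prep import crop_to_tiles

__all__ = [
    "CoverageSeries",
    "ColorRule",
    "coverage_from_mask",
    "color_rule_segmenter",
    "make_color_rule_segmenter",
    "MaskDirectorySegmenter",
    "plot_coverage",
    "build_series",
    "MIN_OBSERVATIONS",
]

WORKING_SIZE = 1536
TILE = 512
MIN_OBSERVATIONS = 5  # fewer cannot support the 5-parameter growth-curve fit


@dataclass
class CoverageSeries:
    """Per-plot (day, coverage) observations, days strictly increasing."""

    plot_id: str
    days: np.ndarray
    coverage: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.coverage = np.asarray(self.coverage, dtype=float)
        if self.days.shape != self.coverage.shape or self.days.ndim != 1:
            raise ValueError("days and coverage must be 1-D and equal length")
        if np.any(np.diff(self.days) <= 0):
            raise ValueError("days must be strictly increasing")
        if np.any((self.coverage < 0) | (self.coverage > 1)):
            raise ValueError("coverage must lie in [0, 1]")

    def __len__(self) -> int:
        return self.days.size


def coverage_from_mask(mask: np.ndarray) -> float:
    """Fraction of panicle pixels: PA / (PA + BA)."""
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError(f"mask must be binary {{0,1}}, found {vals}")
    return float(np.count_nonzero(mask)) / mask.size


@dataclass(frozen=True)
class ColorRule:
    """Axis-aligned RGB acceptance box: lo[c] <= pixel[c] <= hi[c] per channel."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]
    invert: bool = False


def color_rule_segmenter(tile: np.ndarray, rule: ColorRule) -> np.ndarray:
    """Classify each pixel by the RGB box rule; deterministic.

    A degenerate rule (empty acceptance region) yields an all-zero mask
    with a warning rather than an error.
    """
    lo = np.asarray(rule.lo)
    hi = np.asarray(rule.hi)
    if np.any(lo > hi):
        warnings.warn("degenerate color rule (lo > hi); returning all-background mask")
        mask = np.zeros(tile.shape[:2], dtype=np.uint8)
        return (1 - mask) if rule.invert else mask
    inside = np.all((tile >= lo) & (tile <= hi), axis=-1)
    mask = inside.astype(np.uint8)
    return (1 - mask).astype(np.uint8) if rule.invert else mask


def make_color_rule_segmenter(rule: ColorRule):
    """Bind a rule into a segmenter callable satisfying the tile contract."""

    def segmenter(tile: np.ndarray) -> np.ndarray:
        return color_rule_segmenter(tile, rule)

    return segmenter


class MaskDirectorySegmenter:
    """Serve precomputed whole-image masks (e.g. network outputs) by image id.

    Masks are single-channel PNGs where any nonzero value maps to panicle.
    ``plot_coverage`` slices the stored mask tile-by-tile, so external
    model predictions flow through the identical averaging path.
    """

    def __init__(self, mask_dir: str | Path):
        self.mask_dir = Path(mask_dir)
        self._current: np.ndarray | None = None
        self._offset = 0

    def load(self, image_id: str) -> None:
        from .io import read_mask_png

        path = self.mask_dir / f"{image_id}.png"
        if not path.exists():
            raise FileNotFoundError(f"no mask for image id {image_id!r} at {path}")
        self._current = read_mask_png(path)
        self._offset = 0

    def __call__(self, tile: np.ndarray) -> np.ndarray:
        if self._current is None:
            raise RuntimeError("call load(image_id) before segmenting tiles")
        h, w = tile.shape[:2]
        mh, mw = self._current.shape
        per_row = mw // w
        r, c = divmod(self._offset, per_row)
        self._offset += 1
        if (r + 1) * h > mh:
            raise ValueError("more tiles requested than the stored mask covers")
        return self._current[r * h : (r + 1) * h, c * w : (c + 1) * w]


def _resize_image(image: np.ndarray, size: int) -> np.ndarray:
    if image.shape[0] == size and image.shape[1] == size:
        return image
    out = _sk_resize(image, (size, size), order=1, preserve_range=True, anti_aliasing=True)
    return out.astype(image.dtype)


def plot_coverage(
    image: np.ndarray, segmenter, size: int = WORKING_SIZE, tile: int = TILE
) -> float:
    """Whole-plot coverage: resize, tile, segment per tile, average.

    Segmenter contract violations (wrong shape or non-binary values) are
    surfaced with the offending tile index.
    """
    img = _resize_image(image, size)
    tiles = crop_to_tiles(img, tile)
    per_tile = []
    for i, t in enumerate(tiles):
        mask = np.asarray(segmenter(t))
        if mask.shape != t.shape[:2]:
            raise ValueError(
                f"segmenter returned shape {mask.shape} for tile {i}, expected {t.shape[:2]}"
            )
        try:
            per_tile.append(coverage_from_mask(mask))
        except ValueError as exc:
            raise ValueError(f"segmenter output invalid on tile {i}: {exc}") from exc
    return float(np.mean(per_tile))


def build_series(entries, segmenter, **coverage_kwargs) -> list[CoverageSeries]:
    """Turn dated images into per-plot coverage series.

    ``entries`` is an iterable of (plot_id, day, image) triples (image =
    RGB array). Observations are sorted by day within each plot; multiple
    images on the same day are averaged. Plots with fewer than
    MIN_OBSERVATIONS observations are kept but flagged with a warning.
    """
    by_plot: dict[str, dict[float, list[float]]] = {}
    order: list[str] = []
    for plot_id, day, image in entries:
        day = float(day)
        if day < 0:
            raise ValueError(f"negative day {day} for plot {plot_id}")
        cov = plot_coverage(image, segmenter, **coverage_kwargs)
        if plot_id not in by_plot:
            by_plot[plot_id] = {}
            order.append(plot_id)
        by_plot[plot_id].setdefault(day, []).append(cov)

    out = []
    for plot_id in order:
        days = np.array(sorted(by_plot[plot_id]))
        cov = np.array([np.mean(by_plot[plot_id][d]) for d in days])
        if days.size < MIN_OBSERVATIONS:
            warnings.warn(
                f"plot {plot_id!r} has only {days.size} observations; "
                f"a {MIN_OBSERVATIONS}-parameter growth-curve fit needs at least "
                f"{MIN_OBSERVATIONS}"
            )
        out.append(CoverageSeries(plot_id, days, cov))
    return out
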