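"""Whole-slide scanning with an HPF-sized kernel and per-HPF score maps.

The slide is scanned with a square high-power-field (HPF) window stepped by
a fixed stride along both axes; the trailing window is clamped to end
exactly at the slide edge when the stride grid does not.  Each HPF is tiled
into sub-patches, every sub-patch is segmented, tiles are OR-merged into
the HPF mask, small regions are filtered per class, and two local scores
are taken: the number of intact eosinophils and the basal-zone area
fraction (BZ pixels / HPF pixels).  The per-HPF scores form two score maps
whose cells also carry a tissue-validity flag — an HPF counts as tissue
when at least a configurable fraction of its pixels is tissue (saturation
above a threshold; slide background is near-white).
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .config import ScanConfig
from .segmentation import (
    ClassMaskPair,
    Segmenter,
    SegmenterError,
    count_components,
    filter_small_regions,
    merge_tiles,
    segment_subpatch,
    split_tiles,
)

__all__ = ["ScoreMap", "hpf_positions", "axis_anchors", "tissue_fraction", "score_hpf", "segment_hpf", "scan_slide"]


@dataclass(frozen=True)
class ScoreMap:
    """A grid of per-HPF local scores with tissue-validity flags.

    ``grid[i, j]`` is the score of the HPF anchored (top-left) at
    ``(row_anchors[i], col_anchors[j])`` in slide pixel coordinates.
    ``feature`` is ``"eos_count"`` (non-negative integers) or
    ``"bz_fraction"`` (reals in [0, 1]).
    """

    grid: np.ndarray
    tissue_valid: np.ndarray
    row_anchors: np.ndarray
    col_anchors: np.ndarray
    stride_px: int
    hpf_side_px: int
    feature: str

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid)
        valid = np.asarray(self.tissue_valid, dtype=bool)
        if grid.shape != valid.shape:
            raise ValueError("grid and tissue_valid must share shape")
        if grid.shape != (len(self.row_anchors), len(self.col_anchors)):
            raise ValueError("grid shape must match anchor counts")
        if self.feature not in ("eos_count", "bz_fraction"):
            raise ValueError("feature must be 'eos_count' or 'bz_fraction'")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "tissue_valid", valid)
        object.__setattr__(self, "row_anchors", np.asarray(self.row_anchors, dtype=int))
        object.__setattr__(self, "col_anchors", np.asarray(self.col_anchors, dtype=int))

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape


def axis_anchors(dim_px: int, hpf_side_px: int, stride_px: int) -> np.ndarray:
    """Top-left anchors of HPF windows along one axis, with edge clamping.

    Anchors sit at multiples of the stride; if the last stride-aligned
    window does not end exactly at the slide edge, one clamped anchor at
    ``dim - hpf_side`` is appended so the final window ends at the edge.
    A dimension smaller than one HPF yields the single anchor 0 (the caller
    pads the window).
    """
    if dim_px <= hpf_side_px:
        return np.array([0], dtype=int)
    last = dim_px - hpf_side_px
    anchors = list(range(0, last + 1, stride_px))
    if anchors[-1] != last:
        anchors.append(last)
    return np.array(anchors, dtype=int)


def hpf_positions(slide_w: int, slide_h: int, cfg: ScanConfig) -> list[tuple[int, int]]:
    """All (row, col) HPF anchors for a slide, row-major.

    Slides smaller than one HPF in a dimension get a single clamped
    position along that axis provided the dimension still fits one
    sub-patch; smaller slides are rejected.
    """
    if slide_w < cfg.subpatch_side_px or slide_h < cfg.subpatch_side_px:
        raise ValueError(
            f"slide {slide_w}x{slide_h} is smaller than one sub-patch "
            f"({cfg.subpatch_side_px} px) and cannot be scanned"
        )
    rows = axis_anchors(slide_h, cfg.hpf_side_px, cfg.stride_px)
    cols = axis_anchors(slide_w, cfg.hpf_side_px, cfg.stride_px)
    return [(int(r), int(c)) for r in rows for c in cols]


def tissue_fraction(rgb: np.ndarray, saturation_threshold: float) -> float:
    """Fraction of pixels whose HSV saturation exceeds the threshold.

    Saturation is ``(max - min) / max`` over the RGB channels (0 for pure
    white/grey background), so stained tissue scores high and the slide
    background near zero.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim != 3 or arr.shape[2] < 3:
        raise ValueError("expected an RGB raster of shape (H, W, 3)")
    cmax = arr[..., :3].max(axis=2)
    cmin = arr[..., :3].min(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        sat = np.where(cmax > 0, (cmax - cmin) / np.where(cmax > 0, cmax, 1), 0.0)
    return float(np.mean(sat > saturation_threshold))


def score_hpf(hpf_masks: ClassMaskPair, cfg: ScanConfig) -> tuple[int, float]:
    """Local scores of one HPF: (intact-eosinophil count, BZ area fraction).

    The masks must already be merged to HPF scope and area-filtered, and be
    square with side ``cfg.hpf_side_px``.  The eosinophil count is the
    number of connected components (or positive area over the nominal disk
    area under ``count_mode="area_over_disk"``); the BZ fraction divides
    positive BZ pixels by the full HPF pixel count.
    """
    side = cfg.hpf_side_px
    if hpf_masks.shape != (side, side):
        raise ValueError(
            f"HPF masks must be {side}x{side}, got {hpf_masks.shape}; "
            "merge and filter tiles before scoring"
        )
    if cfg.count_mode == "components":
        eos_count = count_components(hpf_masks.eos_mask, connectivity=cfg.connectivity)
    else:
        area = int(np.count_nonzero(hpf_masks.eos_mask))
        eos_count = int(round(area / cfg.nominal_eos_area_px))
    bz_fraction = float(np.count_nonzero(hpf_masks.bz_mask)) / (side * side)
    return eos_count, bz_fraction


def segment_hpf(hpf_rgb: np.ndarray, segmenter: Segmenter, cfg: ScanConfig) -> ClassMaskPair:
    """Tile -> segment -> OR-merge -> area-filter one HPF image.

    Small-region filtering runs after merging, at HPF scope, so regions
    split across tile seams are not spuriously deleted.
    """
    grid = cfg.tile_grid()
    tiles = split_tiles(hpf_rgb, grid)
    pairs = [
        segment_subpatch(
            tile, segmenter, threshold=cfg.probability_threshold, tile_origin=origin
        )
        for tile, origin in zip(tiles, grid.tile_origins)
    ]
    merged = merge_tiles(pairs, grid)
    return ClassMaskPair(
        eos_mask=filter_small_regions(
            merged.eos_mask, cfg.eos_min_area_px, connectivity=cfg.connectivity
        ),
        bz_mask=filter_small_regions(
            merged.bz_mask, cfg.bz_min_area_px, connectivity=cfg.connectivity
        ),
    )


def _pad_to_hpf(image: np.ndarray, cfg: ScanConfig) -> np.ndarray:
    """White-pad the slide on the right/bottom up to at least one HPF."""
    h, w = image.shape[:2]
    ph = max(0, cfg.hpf_side_px - h)
    pw = max(0, cfg.hpf_side_px - w)
    if ph == 0 and pw == 0:
        return image
    pad = [(0, ph), (0, pw)] + [(0, 0)] * (image.ndim - 2)
    return np.pad(image, pad, mode="constant", constant_values=255)


def scan_slide(
    image: np.ndarray, segmenter: Segmenter, cfg: ScanConfig
) -> tuple[ScoreMap, ScoreMap]:
    """Scan a slide and return the (eos_count, bz_fraction) score maps.

    Every HPF position is checked against the tissue gate first; HPFs below
    the gate carry score 0 and ``tissue_valid=False`` and are not
    segmented.  Both maps share shape, anchors and validity flags.
    Segmenter failures are reported with the offending HPF anchor.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] < 3:
        raise ValueError("expected an RGB slide raster of shape (H, W, 3)")
    if min(image.shape[:2]) < cfg.subpatch_side_px:
        raise ValueError(
            f"slide {image.shape[1]}x{image.shape[0]} is smaller than one "
            f"sub-patch ({cfg.subpatch_side_px} px)"
        )
    image = _pad_to_hpf(image, cfg)
    h, w = image.shape[:2]
    rows = axis_anchors(h, cfg.hpf_side_px, cfg.stride_px)
    cols = axis_anchors(w, cfg.hpf_side_px, cfg.stride_px)
    eos_grid = np.zeros((len(rows), len(cols)), dtype=int)
    bz_grid = np.zeros((len(rows), len(cols)), dtype=float)
    valid = np.zeros((len(rows), len(cols)), dtype=bool)
    side = cfg.hpf_side_px
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            window = image[r : r + side, c : c + side]
            if tissue_fraction(window, cfg.tissue_saturation_threshold) < cfg.tissue_fraction_gate:
                continue
            try:
                masks = segment_hpf(window, segmenter, cfg)
            except SegmenterError as exc:
                raise SegmenterError(f"HPF at anchor ({r}, {c}): {exc}") from exc
            eos_grid[i, j], bz_grid[i, j] = score_hpf(masks, cfg)
            valid[i, j] = True
    common = dict(
        tissue_valid=valid,
        row_anchors=rows,
        col_anchors=cols,
        stride_px=cfg.stride_px,
        hpf_side_px=side,
    )
    return (
        ScoreMap(grid=eos_grid, feature="eos_count", **common),
        ScoreMap(grid=bz_grid, feature="bz_fraction", **common),
    )
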