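"""Sub-patch tiling, pluggable segmentation, mask merging and noise filtering.

A whole-slide scan processes one high-power field (HPF) at a time.  Each HPF
is split into a uniform grid of square sub-patches (the segmenter's input
size), every sub-patch is segmented into two binary masks (intact
eosinophils and basal zone), the tile masks are stitched back with a logical
OR in the overlap regions, and contiguous regions smaller than a per-class
area threshold are relabeled as background.

The production segmenter behind this interface is a deep semantic
segmentation network; it is deliberately out of scope here.  Any callable
that maps an RGB tile to two per-pixel probability maps can be plugged in.
The bundled :class:`ReferenceColorSegmenter` recovers the masks from the
synthetic renderer's color palette and is exact on synthetic slides.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Protocol, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "ClassMaskPair",
    "TileGrid",
    "SegmenterError",
    "Segmenter",
    "ReferenceColorSegmenter",
    "get_segmenter",
    "register_segmenter",
    "plan_tiling",
    "split_tiles",
    "segment_subpatch",
    "merge_tiles",
    "filter_small_regions",
]


@dataclass(frozen=True)
class ClassMaskPair:
    """Aligned binary masks for the two segmentation classes over one image.

    A pixel may be positive in both masks (an eosinophil sitting inside a
    basal-zone area) or in neither.
    """

    eos_mask: np.ndarray
    bz_mask: np.ndarray

    def __post_init__(self) -> None:
        eos = np.asarray(self.eos_mask, dtype=bool)
        bz = np.asarray(self.bz_mask, dtype=bool)
        if eos.shape != bz.shape:
            raise ValueError(
                f"mask shapes differ: eos {eos.shape} vs bz {bz.shape}"
            )
        if eos.ndim != 2:
            raise ValueError("masks must be 2-D rasters")
        object.__setattr__(self, "eos_mask", eos)
        object.__setattr__(self, "bz_mask", bz)

    @property
    def height_px(self) -> int:
        return self.eos_mask.shape[0]

    @property
    def width_px(self) -> int:
        return self.eos_mask.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.eos_mask.shape


@dataclass(frozen=True)
class TileGrid:
    """A uniform square tiling of a square patch with exact uniform overlap.

    Tile origins are 0-based (row, col) offsets of each tile's top-left
    corner, row-major.  Coordinates use half-open extents: a tile occupies
    ``[r, r + tile_side)`` x ``[c, c + tile_side)``.
    """

    patch_side_px: int
    tile_side_px: int
    n_tiles_per_axis: int
    overlap_px: int
    tile_origins: tuple[tuple[int, int], ...] = field(repr=False)

    @property
    def n_tiles(self) -> int:
        return self.n_tiles_per_axis**2


def plan_tiling(patch_side_px: int, tile_side_px: int) -> TileGrid:
    """Plan the minimal uniform tile grid that exactly spans a square patch.

    The grid uses ``n = ceil(patch/tile)`` tiles per axis.  For ``n > 1``
    the total overhang ``n*tile - patch`` must divide evenly into ``n - 1``
    inter-tile overlaps, otherwise no uniform-overlap grid exists and a
    :class:`ValueError` is raised.

    A 2144-px HPF with 448-px tiles yields a 5x5 grid (25 tiles) with a
    24-px overlap; a 1200-px patch yields a 3x3 grid with a 72-px overlap.
    """
    if tile_side_px <= 0 or patch_side_px <= 0:
        raise ValueError("patch and tile sides must be positive")
    if tile_side_px > patch_side_px:
        raise ValueError(
            f"tile side {tile_side_px} exceeds patch side {patch_side_px}"
        )
    n = -(-patch_side_px // tile_side_px)  # ceil division
    if n == 1:
        overlap = 0
        steps = [0]
    else:
        overhang = n * tile_side_px - patch_side_px
        if overhang % (n - 1) != 0:
            raise ValueError(
                f"no uniform integer overlap tiles a {patch_side_px}-px patch "
                f"with {tile_side_px}-px tiles ({n} tiles per axis leave an "
                f"overhang of {overhang} px over {n - 1} seams)"
            )
        overlap = overhang // (n - 1)
        if overlap >= tile_side_px:
            raise ValueError(
                f"uniform overlap {overlap} px would not be smaller than the "
                f"tile side {tile_side_px} px"
            )
        stride = tile_side_px - overlap
        steps = [k * stride for k in range(n)]
    origins = tuple((r, c) for r in steps for c in steps)
    return TileGrid(
        patch_side_px=patch_side_px,
        tile_side_px=tile_side_px,
        n_tiles_per_axis=n,
        overlap_px=overlap,
        tile_origins=origins,
    )


def split_tiles(image: np.ndarray, grid: TileGrid) -> list[np.ndarray]:
    """Crop an image (2-D mask or H x W x C raster) into the grid's tiles."""
    if image.shape[0] != grid.patch_side_px or image.shape[1] != grid.patch_side_px:
        raise ValueError(
            f"image shape {image.shape[:2]} does not match patch side "
            f"{grid.patch_side_px}"
        )
    t = grid.tile_side_px
    return [image[r : r + t, c : c + t] for r, c in grid.tile_origins]


class Segmenter(Protocol):
    """Per-tile segmenter contract: RGB tile -> two probability maps.

    Returns ``(eos_prob, bz_prob)``, each a float array in [0, 1] with the
    tile's spatial shape.  Probabilities are thresholded downstream; the
    positive decision is ``prob >= threshold`` (a pixel exactly at the
    threshold is positive).
    """

    def __call__(self, tile: np.ndarray) -> tuple[np.ndarray, np.ndarray]: ...


class SegmenterError(RuntimeError):
    """A segmenter failure, annotated with the coordinates of the tile."""


@dataclass(frozen=True)
class ReferenceColorSegmenter:
    """Recover class masks from the synthetic renderer's color code.

    The synthetic slides paint eosinophils green-dominant and the basal zone
    red-dominant, with a yellow blend where both overlap and a pale pink for
    plain tissue.  Channel thresholds separate these exactly: a pixel is an
    eosinophil candidate when its green channel is high and blue low, and a
    basal-zone candidate when red is high and blue low.
    """

    green_min: int = 120
    red_min: int = 150
    blue_max: int = 100

    def __call__(self, tile: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        tile = np.asarray(tile)
        if tile.ndim != 3 or tile.shape[2] < 3:
            raise ValueError("expected an RGB raster of shape (H, W, 3)")
        r = tile[..., 0].astype(np.int32)
        g = tile[..., 1].astype(np.int32)
        b = tile[..., 2].astype(np.int32)
        eos = ((g >= self.green_min) & (b <= self.blue_max)).astype(float)
        bz = ((r >= self.red_min) & (b <= self.blue_max)).astype(float)
        return eos, bz


_SEGMENTERS: dict[str, Callable[[], Segmenter]] = {
    "reference_color": ReferenceColorSegmenter,
}


def register_segmenter(name: str, factory: Callable[[], Segmenter]) -> None:
    """Register a segmenter plug-in under a config key."""
    _SEGMENTERS[name] = factory


def get_segmenter(name: str) -> Segmenter:
    """Instantiate a registered segmenter by its config key."""
    try:
        return _SEGMENTERS[name]()
    except KeyError:
        known = ", ".join(sorted(_SEGMENTERS))
        raise KeyError(f"unknown segmenter {name!r}; registered: {known}") from None


def segment_subpatch(
    tile: np.ndarray,
    segmenter: Segmenter,
    *,
    threshold: float = 0.5,
    tile_origin: tuple[int, int] | None = None,
) -> ClassMaskPair:
    """Segment one sub-patch into a binary :class:`ClassMaskPair`.

    The segmenter's probability maps are thresholded with an inclusive
    comparison: a probability exactly equal to ``threshold`` is positive.
    Failures are re-raised as :class:`SegmenterError` carrying the tile's
    origin coordinates when provided.
    """
    try:
        eos_prob, bz_prob = segmenter(np.asarray(tile))
    except Exception as exc:  # noqa: BLE001 - contract: annotate and propagate
        where = f" at tile origin {tile_origin}" if tile_origin is not None else ""
        raise SegmenterError(f"segmenter failed{where}: {exc}") from exc
    eos_prob = np.asarray(eos_prob, dtype=float)
    bz_prob = np.asarray(bz_prob, dtype=float)
    if eos_prob.shape != tile.shape[:2] or bz_prob.shape != tile.shape[:2]:
        where = f" at tile origin {tile_origin}" if tile_origin is not None else ""
        raise SegmenterError(
            f"segmenter returned maps of shape {eos_prob.shape}/{bz_prob.shape} "
            f"for a {tile.shape[:2]} tile{where}"
        )
    return ClassMaskPair(eos_mask=eos_prob >= threshold, bz_mask=bz_prob >= threshold)


def merge_tiles(tiles: Sequence[ClassMaskPair], grid: TileGrid) -> ClassMaskPair:
    """Stitch tile masks into a patch-sized pair, OR-ing overlap regions.

    Tiles must be supplied row-major in the order of ``grid.tile_origins``.
    A pixel covered by several tiles is positive if any tile marks it
    positive, independently for each class.
    """
    if len(tiles) != grid.n_tiles:
        raise ValueError(
            f"expected {grid.n_tiles} tiles for a "
            f"{grid.n_tiles_per_axis}x{grid.n_tiles_per_axis} grid, "
            f"got {len(tiles)}"
        )
    side = grid.patch_side_px
    t = grid.tile_side_px
    eos = np.zeros((side, side), dtype=bool)
    bz = np.zeros((side, side), dtype=bool)
    for pair, (r, c) in zip(tiles, grid.tile_origins):
        if pair.shape != (t, t):
            raise ValueError(f"tile at {(r, c)} has shape {pair.shape}, expected {(t, t)}")
        eos[r : r + t, c : c + t] |= pair.eos_mask
        bz[r : r + t, c : c + t] |= pair.bz_mask
    return ClassMaskPair(eos_mask=eos, bz_mask=bz)


_STRUCTURES = {
    1: ndimage.generate_binary_structure(2, 1),  # 4-connectivity
    2: ndimage.generate_binary_structure(2, 2),  # 8-connectivity
}


def filter_small_regions(
    mask: np.ndarray, min_area_px: int, *, connectivity: int = 2
) -> np.ndarray:
    """Relabel contiguous regions smaller than ``min_area_px`` as background.

    Components with area exactly ``min_area_px`` are kept (the threshold is
    a strict "smaller than" removal).  Connectivity defaults to
    8-connectivity (``connectivity=2``); pass 1 for 4-connectivity.
    """
    if min_area_px < 0:
        raise ValueError("min_area_px must be non-negative")
    if connectivity not in (1, 2):
        raise ValueError("connectivity must be 1 (4-conn) or 2 (8-conn)")
    mask = np.asarray(mask, dtype=bool)
    if min_area_px <= 1 or not mask.any():
        return mask.copy()
    labels, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_area_px  # area exactly at the floor is kept
    keep[0] = False
    return keep[labels]


def count_components(mask: np.ndarray, *, connectivity: int = 2) -> int:
    """Number of connected components in a binary mask."""
    _, n = ndimage.label(np.asarray(mask, dtype=bool), structure=_STRUCTURES[connectivity])
    return int(n)
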