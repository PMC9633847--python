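"""Toy whole-slide images with exact ground-truth masks.

These renders stand in for H&E-stained esophageal biopsy slides: a tissue
band on a white background, a basal-zone (BZ) band attached to one tissue
edge (the basal zone is anatomically a layer at one epithelial edge), and
intact eosinophils drawn as filled disks — mirroring how eosinophils are
labeled for segmentation, as a disk of fixed radius (default 25 px) around
the cell centre.  Colors are flat and distinct so the reference color
segmenter can recover both truth masks exactly; no attempt is made at
photorealistic stain texture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..segmentation import ClassMaskPair

__all__ = ["SynthImageSpec", "generate_wsi", "disk_mask", "PALETTE"]

#: Flat RGB color code of the renderer.  Eosinophils are green-dominant,
#: the basal zone red-dominant, their overlap yellow, plain tissue pale
#: pink, background white — chosen so channel thresholds separate classes.
PALETTE: dict[str, tuple[int, int, int]] = {
    "background": (255, 255, 255),
    "tissue": (240, 200, 210),
    "bz": (190, 70, 90),
    "eos": (60, 160, 70),
    "eos_bz": (210, 170, 40),
}


@dataclass(frozen=True)
class SynthImageSpec:
    """Parameters of one synthetic slide.

    ``tissue_fraction`` is the fraction of the image height occupied by the
    tissue band; ``bz_band_fraction`` the fraction of the tissue thickness
    occupied by the basal-zone band (the quantity the BZH grade bins);
    ``n_eos`` disks of radius ``eos_radius_px`` are placed fully inside the
    tissue, pairwise disjoint unless ``allow_overlap``.
    """

    width_px: int
    height_px: int
    tissue_fraction: float = 0.6
    n_eos: int = 10
    eos_radius_px: int = 25
    bz_band_fraction: float = 0.3
    seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.width_px <= 0 or self.height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if not 0.0 <= self.tissue_fraction <= 1.0:
            raise ValueError("tissue_fraction must lie in [0, 1]")
        if not 0.0 <= self.bz_band_fraction <= 1.0:
            raise ValueError("bz_band_fraction must lie in [0, 1]")
        if self.n_eos < 0:
            raise ValueError("n_eos must be non-negative")
        if self.eos_radius_px < 1:
            raise ValueError("eos_radius_px must be >= 1")


def disk_mask(radius: int) -> np.ndarray:
    """Boolean template of a rasterized disk: dy^2 + dx^2 <= radius^2."""
    y, x = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    return (y * y + x * x) <= radius * radius


def generate_wsi(spec: SynthImageSpec) -> tuple[np.ndarray, ClassMaskPair]:
    """Render one synthetic slide and its ground-truth mask pair.

    Deterministic for a fixed spec (including seed).  The eosinophil truth
    mask is the union of the placed disks; the BZ truth mask is the band.
    Raises :class:`ValueError` when the tissue band cannot host the
    requested disks.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    image = np.full((h, w, 3), PALETTE["background"], dtype=np.uint8)
    eos_mask = np.zeros((h, w), dtype=bool)
    bz_mask = np.zeros((h, w), dtype=bool)

    band_h = int(round(spec.tissue_fraction * h))
    if spec.tissue_fraction > 0:
        band_h = max(band_h, 1)
    if band_h > 0:
        top = int(rng.integers(0, h - band_h + 1))
        image[top : top + band_h, :] = PALETTE["tissue"]
        bz_h = int(round(spec.bz_band_fraction * band_h))
        if spec.bz_band_fraction > 0:
            bz_h = max(bz_h, 1)
        if bz_h > 0:
            # The basal zone is a layer: attach to one band edge at random.
            if rng.random() < 0.5:
                bz_mask[top : top + bz_h, :] = True
            else:
                bz_mask[top + band_h - bz_h : top + band_h, :] = True
    else:
        top = 0

    if spec.n_eos > 0:
        r = spec.eos_radius_px
        row_lo, row_hi = top + r, top + band_h - 1 - r
        col_lo, col_hi = r, w - 1 - r
        if band_h == 0 or row_hi < row_lo or col_hi < col_lo:
            raise ValueError(
                f"tissue band of {band_h} px in a {w}x{h} image cannot host "
                f"disks of radius {r} px; enlarge the image or tissue_fraction"
            )
        template = disk_mask(r)
        centers: list[tuple[int, int]] = []
        attempts = 0
        max_attempts = 1000 * spec.n_eos
        min_d2 = (2 * r + 1) ** 2
        while len(centers) < spec.n_eos:
            attempts += 1
            if attempts > max_attempts:
                raise ValueError(
                    f"could not place {spec.n_eos} non-overlapping disks of "
                    f"radius {r} px in the tissue band after {max_attempts} "
                    "attempts; enlarge the image or allow_overlap"
                )
            cy = int(rng.integers(row_lo, row_hi + 1))
            cx = int(rng.integers(col_lo, col_hi + 1))
            if not spec.allow_overlap and any(
                (cy - py) ** 2 + (cx - px) ** 2 < min_d2 for py, px in centers
            ):
                continue
            centers.append((cy, cx))
            eos_mask[cy - r : cy + r + 1, cx - r : cx + r + 1] |= template

    image[bz_mask & ~eos_mask] = PALETTE["bz"]
    image[eos_mask & ~bz_mask] = PALETTE["eos"]
    image[eos_mask & bz_mask] = PALETTE["eos_bz"]
    return image, ClassMaskPair(eos_mask=eos_mask, bz_mask=bz_mask)
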