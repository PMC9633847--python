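"""Scan geometry and pipeline configuration.

All geometric constants of the whole-slide scan live in :class:`ScanConfig`.
The defaults reproduce the reference pipeline: a 2144 x 2144-px high-power
field (548 x 548 um at 400X), a 500-px stride between consecutive HPFs,
448-px segmentation sub-patches (5 x 5 = 25 per HPF with a 24-px overlap),
minimum-area noise filters of 1800 px for intact eosinophils and 2007 px
(1% of a sub-patch) for the basal zone, and a 15% tissue-fraction gate for
counting an HPF as tissue.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

from .segmentation import plan_tiling

__all__ = ["ScanConfig", "DEFAULT_BZ_MIN_AREA_PX"]

_DEFAULT_SUBPATCH_SIDE = 448

#: The basal-zone minimum area is defined as 1% of the sub-patch pixel count.
DEFAULT_BZ_MIN_AREA_PX = int(0.01 * _DEFAULT_SUBPATCH_SIDE**2)
assert DEFAULT_BZ_MIN_AREA_PX == 2007


@dataclass(frozen=True)
class ScanConfig:
    """Geometry and thresholds for scanning a whole-slide image.

    Parameters
    ----------
    hpf_side_px:
        Side of the square high-power-field window, in pixels.
    hpf_side_um:
        Physical side of the HPF in micrometres (metadata only).
    stride_px:
        Step between consecutive HPF anchors along each axis.
    subpatch_side_px:
        Side of the square sub-patches fed to the segmenter.  The HPF side
        must admit a uniform-overlap tiling by this size.
    eos_min_area_px, bz_min_area_px:
        Minimum contiguous-region areas below which segmented regions are
        relabeled as background, per class.
    tissue_fraction_gate:
        Minimum fraction of tissue pixels for an HPF to count as a tissue
        HPF; non-tissue HPFs are excluded from spatial score denominators.
    tissue_saturation_threshold:
        A pixel counts as tissue when its HSV saturation exceeds this value
        (slide background is near-white, hence near-zero saturation).
    probability_threshold:
        Segmentation probability cut; a pixel at exactly the threshold is
        positive.
    connectivity:
        Pixel connectivity for contiguous regions: 2 = 8-connectivity
        (default), 1 = 4-connectivity.
    count_mode:
        How the per-HPF eosinophil count is taken from the filtered mask:
        ``"components"`` counts connected components (each labeled disk is
        one cell); ``"area_over_disk"`` divides the positive area by the
        nominal disk area of one eosinophil label.
    nominal_eos_area_px:
        Area of one nominal eosinophil label disk, used by the
        ``"area_over_disk"`` count mode.
    segmenter:
        Config key of the segmenter plug-in.
    """

    hpf_side_px: int = 2144
    hpf_side_um: float = 548.0
    stride_px: int = 500
    subpatch_side_px: int = _DEFAULT_SUBPATCH_SIDE
    eos_min_area_px: int = 1800
    bz_min_area_px: int = DEFAULT_BZ_MIN_AREA_PX
    tissue_fraction_gate: float = 0.15
    tissue_saturation_threshold: float = 0.10
    probability_threshold: float = 0.5
    connectivity: int = 2
    count_mode: str = "components"
    nominal_eos_area_px: int = 1961  # pixels in a rasterized radius-25 disk
    segmenter: str = "reference_color"

    def __post_init__(self) -> None:
        if self.hpf_side_px <= 0 or self.subpatch_side_px <= 0:
            raise ValueError("hpf_side_px and subpatch_side_px must be positive")
        if self.stride_px < 1:
            raise ValueError("stride_px must be >= 1")
        if self.eos_min_area_px < 0 or self.bz_min_area_px < 0:
            raise ValueError("minimum areas must be non-negative")
        if not 0.0 <= self.tissue_fraction_gate <= 1.0:
            raise ValueError("tissue_fraction_gate must lie in [0, 1]")
        if self.connectivity not in (1, 2):
            raise ValueError("connectivity must be 1 or 2")
        if self.count_mode not in ("components", "area_over_disk"):
            raise ValueError("count_mode must be 'components' or 'area_over_disk'")
        # The HPF must admit a uniform sub-patch tiling; raises otherwise.
        plan_tiling(self.hpf_side_px, self.subpatch_side_px)

    def tile_grid(self):
        """The sub-patch tiling of one HPF."""
        return plan_tiling(self.hpf_side_px, self.subpatch_side_px)

    def replace(self, **changes: Any) -> "ScanConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ScanConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown ScanConfig keys: {sorted(unknown)}")
        return cls(**data)
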