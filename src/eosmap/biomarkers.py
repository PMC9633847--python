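"""Whole-slide biomarkers reduced from the two per-HPF score maps.

Four scores summarise a slide:

- **PEC** (peak eosinophil count): maximum intact-eosinophil count over all
  tissue HPFs — the clinical activity score, cutoff >= 15.
- **SEC** (spatial eosinophil count): fraction of tissue HPFs whose count
  is >= 15.
- **PBZ** (peak basal zone): maximum per-HPF basal-zone area fraction.
- **SBZ** (spatial basal zone): fraction of tissue HPFs whose basal-zone
  fraction is >= 15%.

All thresholds are inclusive (>=).  Spatial scores use the number of
tissue-valid HPFs as their denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .wsi_scoring import ScoreMap

__all__ = ["BiomarkerSet", "NoTissueError", "extract_biomarkers", "activity_label"]


class NoTissueError(ValueError):
    """Raised when a slide has no tissue-valid HPF to score."""


@dataclass(frozen=True)
class BiomarkerSet:
    """The four whole-slide scores of one slide."""

    pec: int
    sec: float
    pbz: float
    sbz: float
    n_tissue_hpfs: int

    def __post_init__(self) -> None:
        if self.pec < 0:
            raise ValueError("pec must be non-negative")
        for name in ("sec", "pbz", "sbz"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} must lie in [0, 1]")
        if self.n_tissue_hpfs < 1:
            raise ValueError("n_tissue_hpfs must be positive")

    def as_dict(self) -> dict:
        return {
            "pec": self.pec,
            "sec": self.sec,
            "pbz": self.pbz,
            "sbz": self.sbz,
            "n_tissue_hpfs": self.n_tissue_hpfs,
        }


def extract_biomarkers(
    eos_map: ScoreMap,
    bz_map: ScoreMap,
    sec_threshold: float = 15,
    sbz_threshold: float = 0.15,
) -> BiomarkerSet:
    """Reduce the two score maps of one slide to a :class:`BiomarkerSet`.

    Only tissue-valid cells enter the maxima and the spatial-score
    numerators; the denominator of SEC and SBZ is the tissue-valid cell
    count.  Raises :class:`NoTissueError` when no cell is tissue-valid
    (never divides by zero).
    """
    if eos_map.shape != bz_map.shape:
        raise ValueError("score maps must share shape")
    if not np.array_equal(eos_map.tissue_valid, bz_map.tissue_valid):
        raise ValueError("score maps must share tissue-validity flags")
    valid = eos_map.tissue_valid
    n_tissue = int(np.count_nonzero(valid))
    if n_tissue == 0:
        raise NoTissueError("no tissue-valid HPF in the score maps")
    eos = np.asarray(eos_map.grid)[valid]
    bz = np.asarray(bz_map.grid)[valid]
    return BiomarkerSet(
        pec=int(eos.max()),
        sec=float(np.count_nonzero(eos >= sec_threshold)) / n_tissue,
        pbz=float(bz.max()),
        sbz=float(np.count_nonzero(bz >= sbz_threshold)) / n_tissue,
        n_tissue_hpfs=n_tissue,
    )


def activity_label(b: BiomarkerSet, cutoff: int = 15) -> bool:
    """Clinical activity: active disease iff PEC >= cutoff (default 15)."""
    return b.pec >= cutoff
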