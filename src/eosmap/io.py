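"""Reading and writing the pipeline's artifacts.

Masks are single-channel PNG/TIFF with 0/255 coding; slides are RGB
PNG/TIFF.  Score maps serialize as a CSV grid plus a JSON sidecar holding
the geometry (anchors, stride, HPF side, feature) and the tissue-validity
flags; integers round-trip bit-exactly and reals value-exactly.  Cohort
tables are CSV with reals at 6 significant digits; biomarker and metrics
JSON carries full precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .biomarkers import BiomarkerSet
from .wsi_scoring import ScoreMap

__all__ = [
    "read_image",
    "write_image",
    "read_mask",
    "write_mask",
    "write_score_map",
    "read_score_map",
    "write_biomarkers",
    "read_biomarkers",
    "write_cohort",
    "read_cohort",
    "render_score_map",
]

#: Significant digits for reals in CSV artifacts.
CSV_FLOAT_FORMAT = "%.6g"


def read_image(path: str | Path) -> np.ndarray:
    """Read an RGB slide raster (PNG/TIFF)."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def write_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_mask(path: str | Path) -> np.ndarray:
    """Read a single-channel 0/255 mask as boolean."""
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) >= 128


def write_mask(path: str | Path, mask: np.ndarray) -> None:
    arr = (np.asarray(mask, dtype=bool).astype(np.uint8)) * 255
    Image.fromarray(arr, mode="L").save(path)


def write_score_map(score_map: ScoreMap, stem: str | Path) -> tuple[Path, Path]:
    """Write a score map as ``<stem>.csv`` (grid) + ``<stem>.meta.json``.

    The CSV holds the grid only; the sidecar carries feature, stride, HPF
    side, the anchor arrays and the tissue-validity flags.
    """
    stem = Path(stem)
    csv_path = stem.parent / f"{stem.name}.csv"
    meta_path = stem.parent / f"{stem.name}.meta.json"
    fmt = "%d" if score_map.feature == "eos_count" else "%.17g"
    np.savetxt(csv_path, np.atleast_2d(score_map.grid), fmt=fmt, delimiter=",")
    meta = {
        "feature": score_map.feature,
        "stride_px": int(score_map.stride_px),
        "hpf_side_px": int(score_map.hpf_side_px),
        "row_anchors": [int(v) for v in score_map.row_anchors],
        "col_anchors": [int(v) for v in score_map.col_anchors],
        "tissue_valid": np.asarray(score_map.tissue_valid, dtype=int).tolist(),
    }
    meta_path.write_text(json.dumps(meta, indent=2))
    return csv_path, meta_path


def read_score_map(stem: str | Path) -> ScoreMap:
    """Read a score map written by :func:`write_score_map`."""
    stem = Path(stem)
    meta = json.loads((stem.parent / f"{stem.name}.meta.json").read_text())
    dtype = int if meta["feature"] == "eos_count" else float
    grid = np.loadtxt(stem.parent / f"{stem.name}.csv", delimiter=",", dtype=dtype, ndmin=2)
    return ScoreMap(
        grid=grid,
        tissue_valid=np.asarray(meta["tissue_valid"], dtype=bool),
        row_anchors=np.asarray(meta["row_anchors"], dtype=int),
        col_anchors=np.asarray(meta["col_anchors"], dtype=int),
        stride_px=meta["stride_px"],
        hpf_side_px=meta["hpf_side_px"],
        feature=meta["feature"],
    )


def write_biomarkers(b: BiomarkerSet, path: str | Path) -> None:
    Path(path).write_text(json.dumps(b.as_dict(), indent=2))


def read_biomarkers(path: str | Path) -> BiomarkerSet:
    return BiomarkerSet(**json.loads(Path(path).read_text()))


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    """Write a cohort table as CSV, reals at 6 significant digits."""
    df.to_csv(path, index=False, float_format=CSV_FLOAT_FORMAT)


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def render_score_map(score_map: ScoreMap, path: str | Path, cmap: str | None = None) -> None:
    """Render a score map as a PNG heatmap with a color scale.

    Non-tissue cells are masked out.  Eosinophil maps default to a hot
    colormap, basal-zone maps to viridis.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if cmap is None:
        cmap = "hot" if score_map.feature == "eos_count" else "viridis"
    data = np.ma.masked_where(~score_map.tissue_valid, np.asarray(score_map.grid, float))
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(data, cmap=cmap, interpolation="nearest")
    fig.colorbar(im, ax=ax, label=score_map.feature)
    ax.set_title(f"{score_map.feature} score map")
    ax.set_xlabel("HPF column")
    ax.set_ylabel("HPF row")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
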