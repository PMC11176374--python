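"""File exports for the analysis stages.

Quality masks go out as 8-bit PNG (0/255) with a CSV score grid and a JSON
parameter sidecar; tessellations and hypo-reflective region sets as CSV
tables plus JSON geometry (µm vertex lists) and optional RGB overlay PNGs
(Voronoi edges / region contours drawn over the image).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from skimage.draw import polygon_perimeter as draw_perimeter

from .hypo import HypoRegionSet
from .quality import QualityMask
from .synth import MosaicImage
from .tessellation import MosaicSummary, Tessellation

__all__ = [
    "write_quality_mask",
    "write_tessellation",
    "write_hypo_regions",
    "overlay_png",
]


def write_quality_mask(qmask: QualityMask, prefix: str | Path) -> list[Path]:
    """Write ``<prefix>.mask.png``, ``<prefix>.scores.csv`` and
    ``<prefix>.quality.json`` for one image's quality assessment."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mask_path = prefix.with_suffix(".mask.png")
    Image.fromarray((qmask.mask.astype(np.uint8)) * 255, mode="L").save(mask_path)
    scores_path = prefix.with_suffix(".scores.csv")
    np.savetxt(scores_path, qmask.scores, delimiter=",", fmt="%.6f")
    sidecar_path = prefix.with_suffix(".quality.json")
    sidecar_path.write_text(
        json.dumps(
            {
                "tile_size_px": qmask.tile_size,
                "threshold": qmask.threshold,
                "non_masked_portion": qmask.non_masked_portion,
            },
            indent=2,
        )
    )
    return [mask_path, scores_path, sidecar_path]


def write_tessellation(
    tess: Tessellation, summary: MosaicSummary, pixel_size: float, prefix: str | Path
) -> list[Path]:
    """Write the per-cell table (CSV), per-image summary (CSV) and the
    clipped polygon geometry in µm (JSON)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    cells_path = prefix.with_suffix(".cells.csv")
    summary.per_cell.to_csv(cells_path, index_label="cell_index")
    summary_path = prefix.with_suffix(".summary.csv")
    pd.DataFrame(
        [
            {
                **summary.summary,
                "density_cells_mm2": summary.density_cells_mm2,
                "non_masked_portion_pct": 100.0 * summary.non_masked_portion,
                "n_cells": summary.n_cells,
                # conventions recorded with the numbers they qualify
                "sd_definition": "sample SD (ddof=1)",
                "neighbor_definition": "degree in full detected graph (incl. border-filtered cells)",
            }
        ]
    ).to_csv(summary_path, index=False)
    geometry_path = prefix.with_suffix(".tessellation.json")
    geometry_path.write_text(
        json.dumps(
            {
                "pixel_size_um": pixel_size,
                "centers_um": (tess.centers * pixel_size).tolist(),
                "polygons_um": [(p * pixel_size).tolist() for p in tess.polygons],
                "kept": tess.kept.astype(int).tolist(),
            }
        )
    )
    return [cells_path, summary_path, geometry_path]


def write_hypo_regions(hset: HypoRegionSet, prefix: str | Path) -> list[Path]:
    """Write the per-region table (CSV) and contour geometry in µm (JSON)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    table_path = prefix.with_suffix(".regions.csv")
    hset.per_region.to_csv(table_path, index_label="region_index")
    contours_path = prefix.with_suffix(".contours.json")
    contours_path.write_text(
        json.dumps(
            {
                "circularity_definition": "4*pi*A/P^2 (isoperimetric, same-perimeter circle)",
                "contours_um": [c.tolist() for c in hset.contours],
            }
        )
    )
    return [table_path, contours_path]


def overlay_png(
    image: MosaicImage | np.ndarray,
    polygons_px: list[np.ndarray],
    path: str | Path,
    color: tuple[int, int, int] = (255, 64, 64),
) -> Path:
    """Save an RGB PNG of the image with polygon outlines drawn over it."""
    data = image.data if isinstance(image, MosaicImage) else np.asarray(image, dtype=float)
    lo, hi = float(data.min()), float(data.max())
    gray = ((data - lo) / (hi - lo) * 255).astype(np.uint8) if hi > lo else np.zeros_like(data, np.uint8)
    rgb = np.stack([gray] * 3, axis=-1)
    h, w = gray.shape
    for poly in polygons_px:
        if len(poly) < 3:
            continue
        rr, cc = draw_perimeter(
            np.clip(poly[:, 1], 0, h - 1), np.clip(poly[:, 0], 0, w - 1), shape=(h, w)
        )
        rgb[rr, cc] = color
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(rgb, mode="RGB").save(path)
    return path
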