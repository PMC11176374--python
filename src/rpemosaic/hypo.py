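"""Segmentation of intracellular hypo-reflective areas and shape descriptors.

Hypo-reflective blobs inside RPE cells (pigment granule clusters) are
darker than both the cell interior and the bright cell edges, but the
overall reflectance varies smoothly across the field, so a single global
threshold does not work. Pixels are therefore labeled by a locally adaptive
(non-uniform) threshold, local mean minus k x local SD over a sliding
window, restricted to the analyzable mask. Connected components within a
size window are kept and their half-pixel boundary contours extracted.

Shape descriptors follow the standard definitions: solidity = area /
convex-hull area; circularity = 4*pi*area / perimeter² — the
isoperimetric form, i.e. the region's area relative to that of the circle
with the same perimeter, which is the convention bounded by 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure

from ._geometry import polygon_area, polygon_perimeter
from .errors import ParameterError
from .quality import QualityMask
from .synth import MosaicImage

__all__ = ["HypoRegionSet", "segment_hyporeflective", "shape_descriptors", "assign_regions_to_cells"]

logger = logging.getLogger(__name__)


@dataclass
class HypoRegionSet:
    """Segmented hypo-reflective contours with per-region shape descriptors."""

    contours: list[np.ndarray]  # closed polygons, µm
    per_region: pd.DataFrame  # area_um2, perimeter_um, solidity, circularity
    summary: dict  # {metric}_mean / {metric}_sd
    density_mm2: float
    non_masked_portion: float
    n_dropped_degenerate: int = 0


def segment_hyporeflective(
    image: MosaicImage | np.ndarray,
    mask: np.ndarray | QualityMask | None = None,
    k: float = 0.8,
    window_px: int = 96,
    min_area_px: float = 4.0,
    max_area_px: float | None = None,
    cell_spacing_um: float = 14.0,
    smooth_window: int = 3,
) -> list[np.ndarray]:
    """Label pixels below a locally adaptive threshold and extract contours.

    The threshold at each pixel is ``local_mean - k * local_SD`` computed
    over a ``window_px`` square window (reflection padding). Components
    outside [``min_area_px``, ``max_area_px``] are discarded;
    ``max_area_px`` defaults to the area of one cell at the expected
    spacing. Contours are traced at the 0.5 iso-level (half-pixel
    boundaries), lightly regularized with a closed moving average of
    ``smooth_window`` vertices (the raw marching-squares staircase biases
    perimeters ~5% high, which would depress every circularity), and
    returned in *pixel* coordinates (x, y); convert to µm via
    :func:`shape_descriptors`.
    """
    data, pix = _as_array(image)
    m = _mask_array(mask)
    if m is not None and not m.any():
        raise ParameterError("unmasked area must be > 0")
    if max_area_px is None:
        spacing_px = cell_spacing_um / pix
        max_area_px = (np.sqrt(3.0) / 2.0) * spacing_px**2

    mu = ndimage.uniform_filter(data, window_px, mode="reflect")
    sq = ndimage.uniform_filter(data**2, window_px, mode="reflect")
    sd = np.sqrt(np.maximum(sq - mu**2, 0.0))
    # the 1e-6 guard absorbs filter rounding error on structureless areas
    below = data < (mu - k * sd - 1e-6)
    if m is not None:
        below &= m

    labeled, n = ndimage.label(below)
    contours: list[np.ndarray] = []
    if n == 0:
        return contours
    objects = ndimage.find_objects(labeled)
    for idx, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        comp = labeled[sl] == idx
        area = int(comp.sum())
        if area < min_area_px or area > max_area_px:
            continue
        padded = np.pad(comp.astype(float), 1)
        traces = measure.find_contours(padded, 0.5)
        if not traces:
            continue
        trace = max(traces, key=len)
        rows = trace[:, 0] - 1 + sl[0].start
        cols = trace[:, 1] - 1 + sl[1].start
        contour = np.column_stack([cols, rows])  # (x, y) px
        if np.allclose(contour[0], contour[-1]):
            contour = contour[:-1]
        if smooth_window > 1 and len(contour) > smooth_window:
            contour = _smooth_closed(contour, smooth_window)
        contours.append(contour)
    return contours


def _smooth_closed(contour: np.ndarray, window: int) -> np.ndarray:
    kernel = np.ones(window) / window
    half = window // 2
    ext = np.vstack([contour[-half:], contour, contour[:half]])
    return np.column_stack(
        [np.convolve(ext[:, 0], kernel, "valid"), np.convolve(ext[:, 1], kernel, "valid")]
    )


def shape_descriptors(
    contours: list[np.ndarray],
    pixel_size: float = 1.0,
    unmasked_area_mm2: float | None = None,
    non_masked_portion: float = float("nan"),
) -> HypoRegionSet:
    """Shape descriptors and per-image summary for a set of closed contours.

    ``contours`` are (x, y) vertex lists in pixel units (pass
    ``pixel_size=1`` for contours already in µm). Area is the shoelace
    area, perimeter the polygon edge length, solidity area/hull-area and
    circularity 4*pi*A/P². Degenerate (zero-area) contours are dropped and
    counted. SDs are sample SDs; density is region count per mm² of
    unmasked area when that area is provided.
    """
    rows = []
    kept: list[np.ndarray] = []
    dropped = 0
    for contour in contours:
        c = np.asarray(contour, dtype=float) * pixel_size
        area = polygon_area(c)
        if area <= 0 or len(c) < 3:
            dropped += 1
            continue
        perim = polygon_perimeter(c)
        hull = Polygon(c).convex_hull
        solidity = area / hull.area if hull.area > 0 else float("nan")
        rows.append(
            {
                "area_um2": area,
                "perimeter_um": perim,
                "solidity": solidity,
                "circularity": 4.0 * np.pi * area / perim**2,
            }
        )
        kept.append(c)
    if dropped:
        logger.info("shape_descriptors: dropped %d degenerate contour(s)", dropped)
    per_region = pd.DataFrame(rows, columns=["area_um2", "perimeter_um", "solidity", "circularity"])
    summary: dict[str, float] = {}
    for col in per_region.columns:
        vals = per_region[col].to_numpy(dtype=float)
        if len(vals) == 0:
            summary[f"{col}_mean"] = float("nan")
            summary[f"{col}_sd"] = float("nan")
        else:
            summary[f"{col}_mean"] = float(vals.mean())
            summary[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    density = (
        len(per_region) / unmasked_area_mm2 if unmasked_area_mm2 and unmasked_area_mm2 > 0 else float("nan")
    )
    return HypoRegionSet(
        contours=kept,
        per_region=per_region,
        summary=summary,
        density_mm2=density,
        non_masked_portion=non_masked_portion,
        n_dropped_degenerate=dropped,
    )


def assign_regions_to_cells(contours: list[np.ndarray], centers: np.ndarray) -> np.ndarray:
    """Index of the nearest cell center for each region (debug output).

    Regions are matched by centroid; per-image statistics never use this
    assignment — it exists to audit which cell a region was drawn from.
    Units of ``contours`` and ``centers`` must match.
    """
    from scipy.spatial import cKDTree

    if len(contours) == 0:
        return np.empty(0, dtype=int)
    centroids = np.array([np.asarray(c, dtype=float).mean(axis=0) for c in contours])
    return cKDTree(np.asarray(centers, dtype=float)).query(centroids)[1]


def _as_array(image) -> tuple[np.ndarray, float]:
    if isinstance(image, MosaicImage):
        return np.asarray(image.data, dtype=float), image.pixel_size
    return np.asarray(image, dtype=float), 1.0


def _mask_array(mask) -> np.ndarray | None:
    if mask is None:
        return None
    if isinstance(mask, QualityMask):
        return mask.mask
    return np.asarray(mask, dtype=bool)
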