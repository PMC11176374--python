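"""Cell-center detection, clipped Voronoi partition and mosaic morphometrics.

Cell boundaries are approximated by the Voronoi partition of detected cell
centers; cells bordering masked areas or the image boundary are post-filtered
(and their pixels added to the masked set) so that clipped, partially seen
cells do not bias the per-image statistics. Per-cell metrics are area (µm²),
perimeter (µm), equivalent diameter (µm) and number of edge-sharing
neighbors; per-image summaries are their mean and sample SD plus cell
density (cells/mm²) and the non-masked portion.

Coordinates: origin at the top-left pixel center, x rightward (columns),
y downward (rows), 0-based; physical position (µm) = pixel index × pixel
size. Detection assumes the dark-field polarity of the RPE mosaic (dark
cell interiors, bright edges); on inverted-contrast input it returns
ridge-crossing points instead of cell centers without failing.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.draw import polygon as draw_polygon
from skimage.feature import peak_local_max

from ._geometry import clipped_voronoi, polygon_area, polygon_perimeter
from .errors import DegenerateGeometryError, ParameterError
from .quality import QualityMask
from .synth import MosaicImage

__all__ = [
    "Tessellation",
    "MosaicSummary",
    "detect_centers",
    "voronoi_partition",
    "filter_border_cells",
    "mosaic_metrics",
]


@dataclass
class Tessellation:
    """Voronoi partition of detected cell centers, clipped to the field.

    ``centers`` and ``polygons`` are in pixel units; ``neighbors[i]`` holds
    the indices of cells sharing a finite Voronoi edge with cell i (edges
    not longer than 1 px, e.g. point contacts, excluded). ``border_flags``
    marks cells touching the image boundary or a masked pixel;
    ``kept`` starts all-True and is updated by :func:`filter_border_cells`.
    """

    centers: np.ndarray
    polygons: list[np.ndarray]
    neighbors: list[set[int]]
    border_flags: np.ndarray
    kept: np.ndarray
    bounds: tuple[float, float, float, float]

    @property
    def n_cells(self) -> int:
        return len(self.centers)

    @property
    def n_kept(self) -> int:
        return int(self.kept.sum())


@dataclass
class MosaicSummary:
    """Per-cell table and per-image summary of the mosaic morphometrics."""

    per_cell: pd.DataFrame  # columns: area_um2, perimeter_um, eq_diameter_um, n_neighbors
    summary: dict  # {metric}_mean / {metric}_sd for each per-cell metric
    density_cells_mm2: float
    non_masked_portion: float
    n_cells: int


def detect_centers(
    image: MosaicImage | np.ndarray,
    mask: np.ndarray | QualityMask | None = None,
    cell_spacing_um: float = 14.0,
    min_distance_factor: float = 0.45,
) -> np.ndarray:
    """Detect cell centers as local minima of the band-passed image.

    A difference-of-Gaussians filter (sigmas 0.25 x and 1.0 x the expected
    spacing) isolates the mosaic's spatial frequency; dark cell interiors
    become pronounced minima, picked with non-maximum suppression at
    ``min_distance_factor`` x spacing (0.45 by default: wide enough to
    suppress duplicate minima inside one cell, narrow enough not to merge
    adjacent jittered cells) and restricted to the analyzable mask. Weak
    minima (above -0.2 x the in-mask response SD) are rejected.

    Returns an (n, 2) array of (x, y) in pixel units; empty if nothing found.
    """
    data, pix = _as_array(image)
    m = _mask_array(mask, data.shape)
    if m is not None and not m.any():
        return np.empty((0, 2))
    spacing_px = cell_spacing_um / pix
    dog = ndimage.gaussian_filter(data, 0.25 * spacing_px, mode="reflect") - ndimage.gaussian_filter(
        data, spacing_px, mode="reflect"
    )
    response = -dog  # maxima at dark interiors
    sd = response[m].std() if m is not None else response.std()
    labels = m.astype(int) if m is not None else None
    coords = peak_local_max(
        response,
        min_distance=max(int(round(min_distance_factor * spacing_px)), 1),
        threshold_abs=0.2 * sd,
        exclude_border=False,
        labels=labels,
    )
    if len(coords) == 0:
        return np.empty((0, 2))
    return np.column_stack([coords[:, 1], coords[:, 0]]).astype(float)


def voronoi_partition(
    centers: np.ndarray,
    mask: np.ndarray | QualityMask | None = None,
    bounds: tuple[float, float, float, float] | None = None,
    min_edge_length: float = 1.0,
) -> Tessellation:
    """Clipped Voronoi partition and neighbor graph of the given centers.

    ``bounds`` defaults to the mask's pixel extent. Cells whose polygon
    touches the field boundary, or that contain a masked pixel, are flagged
    for the border filter. Cocircular degeneracies are broken by a
    deterministic jitter of 1e-6 units.

    Raises :class:`DegenerateGeometryError` for < 3 or collinear centers.
    """
    centers = np.asarray(centers, dtype=float)
    if len(centers) < 3:
        raise DegenerateGeometryError("need at least 3 centers")
    sv = np.linalg.svd(centers - centers.mean(axis=0), compute_uv=False)
    if sv[-1] < 1e-9 * max(sv[0], 1.0):  # before the tie-break jitter
        raise DegenerateGeometryError("centers are collinear")
    m = _mask_array(mask, None)
    if bounds is None:
        if m is None:
            raise ParameterError("either mask or bounds must be given")
        h, w = m.shape
        bounds = (0.0, 0.0, float(w - 1), float(h - 1))

    jittered = centers + _deterministic_jitter(len(centers))
    polygons, neighbors = clipped_voronoi(jittered, bounds, min_edge_length=min_edge_length)

    flags = np.zeros(len(centers), dtype=bool)
    xmin, ymin, xmax, ymax = bounds
    tol = 1e-9 * max(xmax - xmin, ymax - ymin)
    for i, poly in enumerate(polygons):
        if len(poly) < 3:
            flags[i] = True
            continue
        if (
            (poly[:, 0] <= xmin + tol).any()
            or (poly[:, 0] >= xmax - tol).any()
            or (poly[:, 1] <= ymin + tol).any()
            or (poly[:, 1] >= ymax - tol).any()
        ):
            flags[i] = True
    if m is not None and (~m).any():
        # a cell touches the masked area iff it owns a masked pixel
        from scipy.spatial import cKDTree

        rows, cols = np.nonzero(~m)
        owners = cKDTree(jittered).query(np.column_stack([cols, rows]).astype(float))[1]
        flags[np.unique(owners)] = True

    return Tessellation(
        centers=centers,
        polygons=polygons,
        neighbors=neighbors,
        border_flags=flags,
        kept=np.ones(len(centers), dtype=bool),
        bounds=bounds,
    )


def filter_border_cells(
    tess: Tessellation, qmask: QualityMask | np.ndarray
) -> tuple[Tessellation, np.ndarray]:
    """Drop cells bordering masked areas or the field edge; mask their pixels.

    Returns the filtered tessellation and the updated analyzable-pixel mask
    (the quality mask minus the dropped cells' polygons). The flagged set is
    defined against the *quality* mask, so re-running the filter with the
    same quality mask removes nothing further.
    """
    m = _mask_array(qmask, None)
    kept = ~tess.border_flags
    updated = m.copy()
    h, w = updated.shape
    for i in np.nonzero(tess.border_flags)[0]:
        poly = tess.polygons[i]
        if len(poly) < 3:
            continue
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(h, w))
        updated[rr, cc] = False
    return dataclasses.replace(tess, kept=kept), updated


def mosaic_metrics(
    tess: Tessellation,
    pixel_size: float,
    mask: np.ndarray | None = None,
) -> MosaicSummary:
    """Per-cell and per-image mosaic morphometrics in physical units.

    Areas use the shoelace formula on the clipped polygons, equivalent
    diameter is 2*sqrt(area/pi). The neighbor count of a kept cell is its
    degree in the *full* detected neighbor graph (border-filtered cells
    still count as neighbors): dropping them from the count would bias the
    outermost kept cells downward, which is exactly the clipping bias the
    border filter exists to remove. SDs are sample SDs (ddof = 1). Density divides the kept-cell
    count by the unmasked area (from ``mask`` if given, otherwise the summed
    kept-polygon area) in mm². Zero kept cells yield an empty sentinel.
    """
    kept_idx = np.nonzero(tess.kept)[0]
    if len(kept_idx) == 0:
        empty = pd.DataFrame(columns=["area_um2", "perimeter_um", "eq_diameter_um", "n_neighbors"])
        return MosaicSummary(per_cell=empty, summary={}, density_cells_mm2=float("nan"),
                             non_masked_portion=float("nan"), n_cells=0)
    rows = []
    for i in kept_idx:
        poly = tess.polygons[i]
        area = polygon_area(poly) * pixel_size**2
        perim = polygon_perimeter(poly) * pixel_size
        rows.append(
            {
                "area_um2": area,
                "perimeter_um": perim,
                "eq_diameter_um": 2.0 * np.sqrt(area / np.pi),
                "n_neighbors": len(tess.neighbors[i]),
            }
        )
    per_cell = pd.DataFrame(rows, index=kept_idx)

    summary: dict[str, float] = {}
    for col in per_cell.columns:
        vals = per_cell[col].to_numpy(dtype=float)
        summary[f"{col}_mean"] = float(vals.mean())
        summary[f"{col}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    if mask is not None:
        unmasked_um2 = float(mask.sum()) * pixel_size**2
        non_masked_portion = float(mask.sum()) / mask.size
    else:
        unmasked_um2 = float(per_cell["area_um2"].sum())
        xmin, ymin, xmax, ymax = tess.bounds
        non_masked_portion = unmasked_um2 / (((xmax - xmin) * (ymax - ymin)) * pixel_size**2)
    density = len(kept_idx) / (unmasked_um2 / 1e6) if unmasked_um2 > 0 else float("nan")
    return MosaicSummary(
        per_cell=per_cell,
        summary=summary,
        density_cells_mm2=density,
        non_masked_portion=non_masked_portion,
        n_cells=len(kept_idx),
    )


def _deterministic_jitter(n: int) -> np.ndarray:
    # reproducible sub-µm jitter to break cocircular Voronoi degeneracies
    i = np.arange(n, dtype=float)
    jx = np.modf(np.sin(i * 12.9898 + 78.233) * 43758.5453)[0] - 0.5
    jy = np.modf(np.sin(i * 39.3468 + 11.135) * 24634.6345)[0] - 0.5
    return 2e-6 * np.column_stack([jx, jy])


def _as_array(image) -> tuple[np.ndarray, float]:
    if isinstance(image, MosaicImage):
        return np.asarray(image.data, dtype=float), image.pixel_size
    return np.asarray(image, dtype=float), 1.0


def _mask_array(mask, shape) -> np.ndarray | None:
    if mask is None:
        return None
    if isinstance(mask, QualityMask):
        return mask.mask
    return np.asarray(mask, dtype=bool)
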