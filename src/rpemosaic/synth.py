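"""Synthetic RPE-mosaic image generator with ground truth.

The healthy retinal pigment epithelium seen in dark-field adaptive-optics
images is a honeycomb of polygonal cells: hypo-reflective interiors, bright
edges, and intracellular hypo-reflective blobs (pigment granule clusters),
over a mixed-reflectance background. The generator reproduces that contrast
structure from a jittered hexagonal lattice so that every downstream stage
(quality masking, tessellation, blob segmentation, group statistics) can be
verified against known geometry.

Disease-like heterogeneity is emulated by raising the lattice ``disorder``
(more dispersed neighbor counts) and the blob ``blob_roughness`` (lower
solidity/circularity, higher dispersion of both), matching the direction of
the morphometric differences reported between CSCR and healthy eyes.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, Polygon
from skimage.draw import polygon as draw_polygon

from ._geometry import clipped_voronoi
from .errors import ParameterError

__all__ = [
    "MosaicParams",
    "GroundTruth",
    "MosaicImage",
    "EffectSpec",
    "generate_centers",
    "generate_blob_contour",
    "render_mosaic",
    "generate_cohort",
]


@dataclass(frozen=True)
class MosaicParams:
    """Parameters of one synthetic mosaic image.

    Lengths are in micrometres; intensities in [0, 1] before quantization.
    ``disorder`` is the SD of the isotropic Gaussian jitter applied to each
    lattice site, as a fraction of ``lattice_spacing``; ``blob_roughness``
    in [0, 1] scales the radial perturbation of blob boundaries (0 gives
    digitized discs). ``lowq_fraction`` is the area fraction of the image
    degraded (blurred + contrast-flattened) to sub-threshold quality.
    """

    lattice_spacing: float = 14.0
    disorder: float = 0.08
    image_size: tuple[int, int] = (256, 256)  # (height, width) px
    pixel_size: float = 1.0  # µm/px
    edge_brightness: float = 0.85
    interior_brightness: float = 0.40
    background_mix: float = 0.06
    blobs_per_cell: int = 2
    blob_radius: float = 2.2
    blob_roughness: float = 0.10
    noise_sd: float = 0.02
    lowq_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lattice_spacing <= 0:
            raise ParameterError("lattice_spacing must be > 0")
        if self.disorder < 0:
            raise ParameterError("disorder must be >= 0")
        if not (0.0 <= self.blob_roughness <= 1.0):
            raise ParameterError("blob_roughness must be in [0, 1]")
        if not (0.0 <= self.lowq_fraction <= 1.0):
            raise ParameterError("lowq_fraction must be in [0, 1]")
        for name in ("edge_brightness", "interior_brightness", "background_mix"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.blobs_per_cell < 0:
            raise ParameterError("blobs_per_cell must be >= 0")
        if self.blobs_per_cell > 0 and self.blob_radius >= self.lattice_spacing / 2:
            raise ParameterError(
                "blob_radius must be < lattice_spacing/2 (blobs would merge across cells)"
            )
        h, w = self.image_size
        if min(h, w) * self.pixel_size < 3 * self.lattice_spacing:
            raise ParameterError("image too small for a 3x3 lattice")

    @property
    def field_size_um(self) -> tuple[float, float]:
        """(width, height) of the imaged field in µm."""
        h, w = self.image_size
        return w * self.pixel_size, h * self.pixel_size


@dataclass
class GroundTruth:
    """Geometry actually drawn into a synthetic image (µm coordinates)."""

    centers: np.ndarray  # (n, 2) x, y µm
    cell_polygons: list[np.ndarray]  # one per center, clipped to the field
    blob_contours: list[np.ndarray]  # closed vertex lists, µm
    blob_cell_index: list[int]  # parent cell of each blob
    degraded_region_mask: np.ndarray  # bool, True where quality was degraded


@dataclass
class MosaicImage:
    """A grayscale retinal image with its physical pixel size and metadata."""

    data: np.ndarray  # float in [0, 1], shape (H, W)
    pixel_size: float  # µm/px
    meta: dict = field(default_factory=dict)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class EffectSpec:
    """Parameter overrides applied to the disease-like ("CSCR") group.

    Defaults encode the direction reported clinically: a more disordered
    lattice (greater neighbor-count dispersion) and rougher blob boundaries
    (lower circularity/solidity with greater dispersion).
    """

    disorder: float | None = 0.20
    blob_roughness: float | None = 0.30

    @classmethod
    def zero(cls) -> "EffectSpec":
        """No group difference (null-hypothesis cohorts)."""
        return cls(disorder=None, blob_roughness=None)

    def apply(self, params: MosaicParams) -> MosaicParams:
        changes = {}
        if self.disorder is not None:
            changes["disorder"] = self.disorder
        if self.blob_roughness is not None:
            changes["blob_roughness"] = self.blob_roughness
        return dataclasses.replace(params, **changes) if changes else params


def generate_centers(params: MosaicParams, rng: np.random.Generator | None = None) -> np.ndarray:
    """Jittered hexagonal lattice of cell centers covering the field.

    Sites form a hexagonal lattice with spacing ``lattice_spacing``; each is
    independently displaced by an isotropic Gaussian with SD
    ``disorder * lattice_spacing``. Centers falling outside the field after
    jitter are dropped. Deterministic given ``params.seed`` (or an explicit
    ``rng``).

    Returns an (n, 2) array of (x, y) in µm.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    s = params.lattice_spacing
    w, h = params.field_size_um
    row_step = s * np.sqrt(3.0) / 2.0
    rows = np.arange(-1, int(np.ceil(h / row_step)) + 2)
    cols = np.arange(-1, int(np.ceil(w / s)) + 2)
    jj, ii = np.meshgrid(rows, cols, indexing="ij")
    x = (ii + 0.5 * (jj % 2)) * s + 0.5 * s
    y = jj * row_step + 0.5 * row_step
    sites = np.column_stack([x.ravel(), y.ravel()])
    if params.disorder > 0:
        sites = sites + rng.normal(0.0, params.disorder * s, size=sites.shape)
    else:
        # keep the stream position identical so downstream draws line up
        rng.normal(0.0, 1.0, size=sites.shape)
    inside = (
        (sites[:, 0] >= 0) & (sites[:, 0] < w) & (sites[:, 1] >= 0) & (sites[:, 1] < h)
    )
    return sites[inside]


def generate_blob_contour(
    radius: float,
    roughness: float,
    rng: np.random.Generator,
    center: tuple[float, float] = (0.0, 0.0),
    n_vertices: int = 64,
) -> np.ndarray:
    """Closed contour of one hypo-reflective blob.

    The boundary is a disc of the given radius whose radial profile is
    perturbed by a random band-limited harmonic series (orders 2-6),
    normalized so that ``roughness`` is the peak relative amplitude:
    r(theta) = R * (1 + roughness * g(theta)), max|g| = 1. roughness = 0
    yields a regular ``n_vertices``-gon approximating a disc.
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    orders = np.arange(2, 7)
    amp = rng.normal(size=5) / orders  # damp high orders
    phase = rng.uniform(0.0, 2.0 * np.pi, size=5)
    g = (amp[:, None] * np.cos(orders[:, None] * theta[None, :] + phase[:, None])).sum(axis=0)
    peak = np.abs(g).max()
    if peak > 0:
        g /= peak
    r = radius * (1.0 + roughness * g)
    r = np.maximum(r, 0.05 * radius)
    cx, cy = center
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def _background_field(shape: tuple[int, int], amplitude: float, rng: np.random.Generator) -> np.ndarray:
    if amplitude <= 0:
        rng.normal(size=(8, 8))
        return np.zeros(shape)
    coarse = rng.normal(size=(8, 8))
    fieldimg = ndimage.zoom(coarse, (shape[0] / 8.0, shape[1] / 8.0), order=3)
    fieldimg = fieldimg[: shape[0], : shape[1]]
    peak = np.abs(fieldimg).max()
    if peak > 0:
        fieldimg /= peak
    return amplitude * fieldimg


def render_mosaic(
    centers: np.ndarray, params: MosaicParams, rng: np.random.Generator | None = None
) -> tuple[MosaicImage, GroundTruth]:
    """Render the mosaic image for the given centers, with full ground truth.

    Bright ridges are drawn along Voronoi edges, interiors are darker, each
    cell receives ``blobs_per_cell`` hypo-reflective rough-boundary blobs
    placed strictly inside the cell, then a smooth background mixture field
    and Gaussian noise are added. If ``lowq_fraction`` > 0, a vertical band
    of that area fraction is blurred and contrast-flattened and reported in
    ``degraded_region_mask``.
    """
    centers = np.asarray(centers, dtype=float)
    if len(centers) == 0:
        raise ParameterError("centers must be non-empty")
    if params.blobs_per_cell > 0 and params.blob_radius >= params.lattice_spacing / 2:
        raise ParameterError("blob_radius must be < lattice_spacing/2")
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence([params.seed, 1]))

    h, w = params.image_size
    pix = params.pixel_size
    wum, hum = params.field_size_um

    polygons, _ = clipped_voronoi(centers, (0.0, 0.0, wum, hum))

    # nearest-center label image -> ridge pixels where the label changes
    yy, xx = np.mgrid[0:h, 0:w]
    from scipy.spatial import cKDTree

    labels = cKDTree(centers).query(np.column_stack([xx.ravel() * pix, yy.ravel() * pix]))[1]
    labels = labels.reshape(h, w)
    edge = np.zeros((h, w), dtype=bool)
    edge[:, :-1] |= labels[:, :-1] != labels[:, 1:]
    edge[:, 1:] |= labels[:, :-1] != labels[:, 1:]
    edge[:-1, :] |= labels[:-1, :] != labels[1:, :]
    edge[1:, :] |= labels[:-1, :] != labels[1:, :]

    img = np.full((h, w), params.interior_brightness, dtype=float)
    img[edge] = params.edge_brightness

    blob_contours: list[np.ndarray] = []
    blob_cells: list[int] = []
    if params.blobs_per_cell > 0:
        blob_level = 0.3 * params.interior_brightness
        rmax = params.blob_radius * (1.0 + params.blob_roughness)
        for ci, poly in enumerate(polygons):
            if len(poly) < 3:
                continue
            shp = Polygon(poly).buffer(-(rmax + 0.75))
            if shp.is_empty:
                continue
            minx, miny, maxx, maxy = shp.bounds
            placed: list[tuple[float, float]] = []
            min_sep = 2.0 * rmax + 0.5  # blobs must not merge within a cell
            for _ in range(params.blobs_per_cell):
                for _attempt in range(24):
                    px = rng.uniform(minx, maxx)
                    py = rng.uniform(miny, maxy)
                    if shp.contains(Point(px, py)) and all(
                        np.hypot(px - qx, py - qy) >= min_sep for qx, qy in placed
                    ):
                        break
                else:
                    continue
                placed.append((px, py))
                contour = generate_blob_contour(
                    params.blob_radius, params.blob_roughness, rng, center=(px, py)
                )
                rr, cc = draw_polygon(contour[:, 1] / pix, contour[:, 0] / pix, shape=(h, w))
                img[rr, cc] = blob_level
                blob_contours.append(contour)
                blob_cells.append(ci)

    img = img + _background_field((h, w), params.background_mix, rng)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=(h, w))
    else:
        rng.normal(0.0, 1.0, size=(h, w))

    degraded = np.zeros((h, w), dtype=bool)
    if params.lowq_fraction > 0:
        band = int(round(params.lowq_fraction * w))
        degraded[:, :band] = True
        sigma = params.lattice_spacing / pix
        blurred = ndimage.gaussian_filter(img, sigma, mode="reflect")
        flat = blurred.mean() + 0.15 * (blurred - blurred.mean())
        # feathered transition on the sharp side: an abrupt defocus edge
        # would itself be a sharp (broadband) structure
        ramp = min(8, w - band)
        weight = np.zeros(w)
        weight[:band] = 1.0
        if ramp > 0:
            weight[band : band + ramp] = 0.5 * (1.0 + np.cos(np.pi * np.arange(ramp) / ramp))
        img = weight[None, :] * flat + (1.0 - weight[None, :]) * img

    img = np.clip(img, 0.0, 1.0)
    gt = GroundTruth(
        centers=centers,
        cell_polygons=polygons,
        blob_contours=blob_contours,
        blob_cell_index=blob_cells,
        degraded_region_mask=degraded,
    )
    meta = {"lattice_spacing": params.lattice_spacing, "seed": params.seed}
    return MosaicImage(data=img, pixel_size=pix, meta=meta), gt


# ---------------------------------------------------------------------------
# cohorts

_ZONES = ("Z1", "Z2", "Z3", "Z4")


def generate_cohort(
    n_eyes_per_group: int,
    images_per_eye: int,
    healthy_params: MosaicParams,
    effect: EffectSpec,
    seed: int,
) -> tuple[pd.DataFrame, dict[str, MosaicParams]]:
    """Synthesize a two-group study cohort (metadata + per-image parameters).

    One group ("healthy") uses ``healthy_params``; the other ("CSCR") uses
    the same parameters with the ``effect`` overrides. Per-eye metadata is
    sampled as age ~ N(40, 10) years, axial length AL ~ N(23.5, 0.8) mm and
    refraction spherical equivalent RE ~ N(-0.5, 1.5) D truncated to the
    inclusion window (-6, +5) D. Perifoveal zones Z1-Z4 are assigned
    cyclically. Everything is reproducible from ``seed`` via per-image
    child seeds split from one root ``numpy.random.SeedSequence``.

    Returns
    -------
    metadata : DataFrame
        Columns: image_id, eye_id, participant_id, group, age, AL_mm, RE_D,
        zone, seed. Row count = n_eyes_per_group * 2 * images_per_eye.
    image_params : dict
        image_id -> MosaicParams for rendering that image.
    """
    if n_eyes_per_group < 1 or images_per_eye < 1:
        raise ParameterError("n_eyes_per_group and images_per_eye must be >= 1")
    root = np.random.SeedSequence(seed)
    meta_seed, image_root = root.spawn(2)
    meta_rng = np.random.default_rng(meta_seed)
    image_seeds = iter(image_root.spawn(2 * n_eyes_per_group * images_per_eye))

    rows = []
    image_params: dict[str, MosaicParams] = {}
    for group in ("healthy", "CSCR"):
        base = healthy_params if group == "healthy" else effect.apply(healthy_params)
        for e in range(n_eyes_per_group):
            eye_id = f"{group}_e{e + 1:02d}"
            age = float(meta_rng.normal(40.0, 10.0))
            al = float(meta_rng.normal(23.5, 0.8))
            re = float(meta_rng.normal(-0.5, 1.5))
            while not (-6.0 < re < 5.0):
                re = float(meta_rng.normal(-0.5, 1.5))
            for k in range(images_per_eye):
                zone = _ZONES[k % len(_ZONES)]
                image_id = f"{eye_id}_{zone}_{k + 1}"
                child = next(image_seeds)
                img_seed = int(child.generate_state(1)[0] % (2**31))
                image_params[image_id] = dataclasses.replace(base, seed=img_seed)
                rows.append(
                    {
                        "image_id": image_id,
                        "eye_id": eye_id,
                        "participant_id": eye_id,
                        "group": group,
                        "age": age,
                        "AL_mm": al,
                        "RE_D": re,
                        "zone": zone,
                        "seed": img_seed,
                    }
                )
    return pd.DataFrame(rows), image_params
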