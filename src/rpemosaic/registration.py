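"""Physical scaling, landmark similarity registration, warping and stitching.

The adaptive-optics montage lives in its own pixel grid; to correlate it
with the infrared (IR) fundus frame it is (1) scaled physically with the
eye-specific pixel-size equation ``a*RE + b*(AL - 23.5) + c`` (RE =
refraction spherical equivalent in diopters, AL = axial length in mm),
(2) registered with a least-squares similarity transform (rotation, one
scale, translation) estimated from >= 4 manually placed vessel landmarks,
and (3) exported both at the IR pixel size (20 µm/px by default) and at
native resolution. A translation-only stitcher with cross-correlation
refinement assembles the per-zone images into a montage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform
from skimage.registration import phase_cross_correlation

from .errors import DegenerateGeometryError, ParameterError, ScalingError
from .synth import MosaicImage

__all__ = [
    "ScalingModel",
    "SimilarityTransform",
    "WarpResult",
    "Montage",
    "pixel_size",
    "estimate_similarity",
    "warp_montage",
    "stitch_translation",
]


@dataclass(frozen=True)
class ScalingModel:
    """Coefficients of the pixel-size equation, all in µm/px.

    ``a`` per diopter of RE, ``b`` per mm of axial-length deviation from
    the 23.5 mm reference, ``c`` the pixel size of the reference eye.
    The defaults are placeholders with plausible magnitudes; the device
    calibration constants are not public and must be configured.
    """

    a: float = 0.02
    b: float = 0.5
    c: float = 0.7
    AL_ref: float = 23.5

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ParameterError("c (reference pixel size) must be > 0")


def pixel_size(RE: float, AL: float, model: ScalingModel = ScalingModel()) -> float:
    """Eye-specific physical pixel size, µm/px: a*RE + b*(AL - AL_ref) + c."""
    if not (20.0 < AL < 30.0):
        raise ParameterError("AL must be in (20, 30) mm")
    if not (-10.0 < RE < 10.0):
        raise ParameterError("RE must be in (-10, +10) D")
    value = model.a * RE + model.b * (AL - model.AL_ref) + model.c
    if value <= 0:
        raise ScalingError(f"pixel size {value:.4g} µm/px is non-positive; check coefficients")
    return value


@dataclass
class SimilarityTransform:
    """Rotation + uniform scale + translation, y = s*R(theta)*x + t."""

    scale: float
    rotation: float  # radians
    translation: tuple[float, float]
    residual_rms: float | None = None

    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        m = np.array(
            [
                [self.scale * c, -self.scale * s, self.translation[0]],
                [self.scale * s, self.scale * c, self.translation[1]],
                [0.0, 0.0, 1.0],
            ]
        )
        return m

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        hom = np.column_stack([pts, np.ones(len(pts))])
        return (self.matrix() @ hom.T).T[:, :2]

    def inverse(self) -> "SimilarityTransform":
        inv = np.linalg.inv(self.matrix())
        return _from_matrix(inv)

    def compose(self, other: "SimilarityTransform") -> "SimilarityTransform":
        """Transform applying ``other`` first, then ``self``."""
        return _from_matrix(self.matrix() @ other.matrix())


def _from_matrix(m: np.ndarray) -> SimilarityTransform:
    scale = float(np.hypot(m[0, 0], m[1, 0]))
    rotation = float(np.arctan2(m[1, 0], m[0, 0]))
    return SimilarityTransform(scale=scale, rotation=rotation, translation=(float(m[0, 2]), float(m[1, 2])))


def estimate_similarity(src: np.ndarray, dst: np.ndarray) -> SimilarityTransform:
    """Least-squares similarity transform from >= 4 landmark pairs.

    Minimizes the sum of squared target-frame residuals (Umeyama /
    Procrustes solution); the residual RMS (per landmark, target units) is
    attached to the result. Landmark sets whose principal-axis spread ratio
    is below 0.05 (nearly collinear vessels) raise
    :class:`DegenerateGeometryError`.
    """
    src = np.asarray(src, dtype=float)
    dst = np.asarray(dst, dtype=float)
    if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
        raise ParameterError("src and dst must be (n, 2) arrays of equal length")
    if len(src) < 4:
        raise ParameterError("at least 4 landmark pairs are required")
    sv = np.linalg.svd(src - src.mean(axis=0), compute_uv=False)
    if sv[0] <= 0 or sv[1] / sv[0] < 0.05:
        raise DegenerateGeometryError("landmarks are (nearly) collinear; spread ratio < 0.05")
    if hasattr(sktransform.SimilarityTransform, "from_estimate"):
        est = sktransform.SimilarityTransform.from_estimate(src, dst)
        if not est:
            raise DegenerateGeometryError("similarity estimation failed")
    else:  # older scikit-image
        est = sktransform.SimilarityTransform()
        if not est.estimate(src, dst):
            raise DegenerateGeometryError("similarity estimation failed")
    result = _from_matrix(est.params)
    residuals = result.apply(src) - dst
    result.residual_rms = float(np.sqrt(np.mean(np.sum(residuals**2, axis=1))))
    return result


@dataclass
class WarpResult:
    """Low- and high-resolution warped exports with validity masks."""

    low_res: MosaicImage
    low_mask: np.ndarray
    high_res: MosaicImage
    high_mask: np.ndarray


def warp_montage(
    montage: MosaicImage,
    transformation: SimilarityTransform,
    target_pixel_size: float = 20.0,
    target_shape: tuple[int, int] | None = None,
) -> WarpResult:
    """Warp a montage into the target (IR-fundus) frame.

    ``transformation`` maps source physical coordinates (µm) to target
    physical coordinates (µm). Two exports are produced: the target frame
    sampled at ``target_pixel_size`` (20 µm/px default) and the same frame
    at the montage's native pixel size. Bilinear interpolation;
    out-of-field pixels are 0 and marked invalid in the masks. The output
    canvas covers the transformed footprint unless ``target_shape`` (rows,
    cols) is given.
    """
    low, low_mask = _warp_once(montage, transformation, target_pixel_size, target_shape)
    high, high_mask = _warp_once(montage, transformation, montage.pixel_size, None)
    return WarpResult(low_res=low, low_mask=low_mask, high_res=high, high_mask=high_mask)


def _warp_once(montage, transformation, out_pix, target_shape):
    h, w = montage.data.shape
    src_pix = montage.pixel_size
    # full map: src px -> src µm -> target µm -> target px
    m = np.diag([1.0 / out_pix, 1.0 / out_pix, 1.0]) @ transformation.matrix() @ np.diag([src_pix, src_pix, 1.0])
    if target_shape is None:
        corners = np.array([[0, 0], [w - 1, 0], [0, h - 1], [w - 1, h - 1]], dtype=float)
        out_corners = (m @ np.column_stack([corners, np.ones(4)]).T).T[:, :2]
        out_w = int(np.ceil(out_corners[:, 0].max())) + 1
        out_h = int(np.ceil(out_corners[:, 1].max())) + 1
        target_shape = (max(out_h, 1), max(out_w, 1))
    inv = np.linalg.inv(m)
    warped = sktransform.warp(
        montage.data, inverse_map=inv, output_shape=target_shape, order=1, cval=0.0, preserve_range=True
    )
    valid = sktransform.warp(
        np.ones((h, w)), inverse_map=inv, output_shape=target_shape, order=1, cval=0.0, preserve_range=True
    )
    mask = valid > 0.999
    return MosaicImage(data=warped, pixel_size=out_pix, meta=dict(montage.meta)), mask


@dataclass
class Montage:
    """Stitched montage with per-tile offsets (row, col) in montage pixels."""

    image: np.ndarray
    offsets: list[tuple[float, float]]
    refined: list[bool]


def stitch_translation(
    images: list[np.ndarray | MosaicImage],
    nominal_offsets: list[tuple[float, float]],
    min_overlap_px: int = 16,
    refine: bool = True,
) -> Montage:
    """Translation-only stitcher with cross-correlation refinement.

    Each tile is placed at its nominal (row, col) offset, refined by phase
    correlation against the already-placed tile with the largest nominal
    overlap. Tiles without sufficient overlap fall back to their nominal
    offset with a warning. Overlaps are blended with linear
    (distance-to-edge) feathering.
    """
    arrays = [a.data if isinstance(a, MosaicImage) else np.asarray(a, dtype=float) for a in images]
    if len(arrays) != len(nominal_offsets):
        raise ParameterError("one nominal offset per tile is required")
    if len(arrays) == 1:
        return Montage(image=arrays[0].copy(), offsets=[tuple(map(float, nominal_offsets[0]))], refined=[True])

    offsets = [np.asarray(o, dtype=float) for o in nominal_offsets]
    final: list[np.ndarray] = [offsets[0]]
    refined_flags = [True]
    for i in range(1, len(arrays)):
        best_j, best_area = None, 0.0
        for j in range(i):
            area = _overlap_area(arrays[i].shape, offsets[i], arrays[j].shape, offsets[j])
            if area > best_area:
                best_j, best_area = j, area
        correction = np.zeros(2)
        ok = False
        if refine and best_j is not None:
            # overlap computed in the pair's nominal coordinates
            crop_i, crop_j = _overlap_crops(arrays[i], offsets[i], arrays[best_j], offsets[best_j], min_overlap_px)
            if crop_i is not None:
                shift = phase_cross_correlation(crop_j, crop_i)[0]
                correction = (final[best_j] - offsets[best_j]) + np.asarray(shift)
                ok = True
        if not ok:
            warnings.warn(f"tile {i}: no usable overlap, using nominal offset", stacklevel=2)
        final.append(offsets[i] + correction)
        refined_flags.append(ok)

    shift0 = np.floor(np.min(np.array(final), axis=0))
    final = [o - shift0 for o in final]
    hs = [a.shape[0] for a in arrays]
    ws = [a.shape[1] for a in arrays]
    H = int(np.ceil(max(o[0] + h for o, h in zip(final, hs))))
    W = int(np.ceil(max(o[1] + w for o, w in zip(final, ws))))
    acc = np.zeros((H, W))
    wacc = np.zeros((H, W))
    for arr, off in zip(arrays, final):
        r0, c0 = int(round(off[0])), int(round(off[1]))
        h, w = arr.shape
        wt = _feather_weights(h, w)
        acc[r0 : r0 + h, c0 : c0 + w] += arr * wt
        wacc[r0 : r0 + h, c0 : c0 + w] += wt
    with np.errstate(invalid="ignore"):
        out = np.where(wacc > 0, acc / np.maximum(wacc, 1e-12), 0.0)
    return Montage(image=out, offsets=[tuple(o) for o in final], refined=refined_flags)


def _feather_weights(h: int, w: int) -> np.ndarray:
    ry = np.minimum(np.arange(h), np.arange(h)[::-1]) + 1.0
    rx = np.minimum(np.arange(w), np.arange(w)[::-1]) + 1.0
    return np.minimum.outer(ry, rx)


def _overlap_area(shape_a, off_a, shape_b, off_b) -> float:
    r0 = max(off_a[0], off_b[0])
    c0 = max(off_a[1], off_b[1])
    r1 = min(off_a[0] + shape_a[0], off_b[0] + shape_b[0])
    c1 = min(off_a[1] + shape_a[1], off_b[1] + shape_b[1])
    return max(r1 - r0, 0.0) * max(c1 - c0, 0.0)


def _overlap_crops(a, off_a, b, off_b, min_px):
    r0 = max(off_a[0], off_b[0])
    c0 = max(off_a[1], off_b[1])
    r1 = min(off_a[0] + a.shape[0], off_b[0] + b.shape[0])
    c1 = min(off_a[1] + a.shape[1], off_b[1] + b.shape[1])
    if (r1 - r0) < min_px or (c1 - c0) < min_px:
        return None, None
    ra0, ca0 = int(round(r0 - off_a[0])), int(round(c0 - off_a[1]))
    rb0, cb0 = int(round(r0 - off_b[0])), int(round(c0 - off_b[1]))
    hh, ww = int(r1 - r0), int(c1 - c0)
    return a[ra0 : ra0 + hh, ca0 : ca0 + ww], b[rb0 : rb0 + hh, cb0 : cb0 + ww]
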