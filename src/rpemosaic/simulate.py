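"""Cohort-level simulation studies: effect recovery (power) and type-I error.

These run the package's own measurement operators on generator output at
the statistic level — per eye, a simulated perifoveal field is tessellated
for the neighbor-count dispersion, and a set of generated blob contours is
measured for the hypo-reflective shape descriptors — then per-eye feature
means are compared with Welch's t-test, exactly as the image pipeline
does. Skipping the pixel rendering (whose fidelity is validated separately
by the ground-truth detection and segmentation tests) is what makes
hundreds of replicate cohorts tractable.

Group sizes default to 12 disease vs 33 healthy eyes, the scale of a
typical single-center AO-TFI cohort.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .stats import welch_t
from .synth import EffectSpec, MosaicParams, generate_blob_contour, generate_centers
from .hypo import shape_descriptors
from .tessellation import mosaic_metrics, voronoi_partition

__all__ = [
    "measure_eye_neighbor_sd",
    "measure_eye_blob_features",
    "simulate_power",
    "simulate_type1_error",
    "BLOB_FEATURES",
]

# blob-shape features the disease effect shifts, with the expected
# direction of (disease - healthy)
BLOB_FEATURES = {
    "circularity_mean": -1,
    "solidity_mean": -1,
    "solidity_sd": +1,
    "perimeter_um_sd": +1,
}


def measure_eye_neighbor_sd(params: MosaicParams, seed: int) -> float:
    """SD of the Voronoi neighbor count in one simulated field of one eye."""
    p = dataclasses.replace(params, seed=seed)
    centers = generate_centers(p)
    h, w = p.image_size
    tess = voronoi_partition(centers, bounds=(0.0, 0.0, float(w - 1), float(h - 1)))
    tess = dataclasses.replace(tess, kept=~tess.border_flags)
    return mosaic_metrics(tess, p.pixel_size).summary["n_neighbors_sd"]


def measure_eye_blob_features(params: MosaicParams, seed: int, n_blobs: int = 40) -> dict[str, float]:
    """Shape-descriptor summary of one eye's generated blob contours."""
    rng = np.random.default_rng(seed)
    contours = [
        generate_blob_contour(params.blob_radius, params.blob_roughness, rng) for _ in range(n_blobs)
    ]
    summary = shape_descriptors(contours).summary
    return {k: summary[k] for k in BLOB_FEATURES}


def _group_seeds(ss: np.random.SeedSequence, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(n)]


def simulate_power(
    healthy_params: MosaicParams,
    effect: EffectSpec,
    n_disease: int = 12,
    n_healthy: int = 33,
    n_cohorts: int = 100,
    seed: int = 0,
    field_px: int = 160,
) -> dict[str, float]:
    """Fraction of replicate cohorts detecting each effect in its direction.

    For every cohort, per-eye features are measured for both groups and
    compared with Welch's t-test; a cohort counts as a detection for a
    feature if p < 0.05 AND the group difference has the direction the
    disease effect induces (higher neighbor-count SD; lower mean
    circularity/solidity; higher solidity/perimeter SD).

    Returns {feature: detection fraction} for ``n_neighbors_sd`` plus the
    blob-shape features.
    """
    base = dataclasses.replace(
        healthy_params, image_size=(field_px, field_px), noise_sd=0.0, blobs_per_cell=0, background_mix=0.0
    )
    disease = effect.apply(base)
    root = np.random.SeedSequence(seed)
    hits = {"n_neighbors_sd": 0, **{k: 0 for k in BLOB_FEATURES}}
    for cohort_ss in root.spawn(n_cohorts):
        d_ss, h_ss = cohort_ss.spawn(2)
        d_seeds = _group_seeds(d_ss, n_disease)
        h_seeds = _group_seeds(h_ss, n_healthy)

        a = [measure_eye_neighbor_sd(disease, s) for s in d_seeds]
        b = [measure_eye_neighbor_sd(base, s) for s in h_seeds]
        r = welch_t(a, b)
        if r.p < 0.05 and r.mean_a > r.mean_b:
            hits["n_neighbors_sd"] += 1

        da = [measure_eye_blob_features(disease, s) for s in d_seeds]
        hb = [measure_eye_blob_features(base, s) for s in h_seeds]
        for feat, direction in BLOB_FEATURES.items():
            r = welch_t([d[feat] for d in da], [h[feat] for h in hb])
            if r.p < 0.05 and np.sign(r.mean_a - r.mean_b) == direction:
                hits[feat] += 1
    return {k: v / n_cohorts for k, v in hits.items()}


def simulate_type1_error(
    healthy_params: MosaicParams,
    n_disease: int = 12,
    n_healthy: int = 33,
    n_cohorts: int = 1000,
    seed: int = 0,
    feature: str = "circularity_mean",
) -> float:
    """Rejection rate of the Welch test over zero-effect replicate cohorts.

    Both groups are drawn from identical parameters, so rejections at
    p < 0.05 estimate the test's type-I error (nominally 5%).
    """
    root = np.random.SeedSequence(seed)
    rejections = 0
    for cohort_ss in root.spawn(n_cohorts):
        d_ss, h_ss = cohort_ss.spawn(2)
        a = [
            measure_eye_blob_features(healthy_params, s)[feature]
            for s in _group_seeds(d_ss, n_disease)
        ]
        b = [
            measure_eye_blob_features(healthy_params, s)[feature]
            for s in _group_seeds(h_ss, n_healthy)
        ]
        if welch_t(a, b).p < 0.05:
            rejections += 1
    return rejections / n_cohorts
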