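import numpy as np
import pytest

import rpemosaic as rm


@pytest.fixture(scope="session")
def healthy_params() -> rm.MosaicParams:
    """Default healthy-mosaic parameters used across fixtures."""
    return rm.MosaicParams(seed=3, disorder=0.10)


@pytest.fixture(scope="session")
def rendered(healthy_params):
    """One rendered healthy mosaic with ground truth (shared, read-only)."""
    centers = rm.generate_centers(healthy_params)
    img, gt = rm.render_mosaic(centers, healthy_params)
    return img, gt


@pytest.fixture(scope="session")
def lowq_rendered():
    """Mosaic with a 30% degraded (blurred, low-contrast) band."""
    params = rm.MosaicParams(seed=3, disorder=0.10, lowq_fraction=0.3, image_size=(320, 320))
    centers = rm.generate_centers(params)
    img, gt = rm.render_mosaic(centers, params)
    return img, gt, params


@pytest.fixture(scope="session")
def perfect_lattice_summary():
    """Metrics of an unjittered hexagonal lattice (interior cells only)."""
    import dataclasses

    params = rm.MosaicParams(seed=1, disorder=0.0, noise_sd=0.0, blobs_per_cell=0, background_mix=0.0)
    centers = rm.generate_centers(params)
    tess = rm.voronoi_partition(centers, bounds=(0.0, 0.0, 256.0, 256.0))
    tess = dataclasses.replace(tess, kept=~tess.border_flags)
    return rm.mosaic_metrics(tess, params.pixel_size), params


def brute_force_voronoi_areas(centers: np.ndarray, bounds, n_grid: int) -> np.ndarray:
    """Independent oracle: nearest-center labeling on an n_grid x n_grid
    point lattice, counting label occupancy (explicit distance argmin, no
    Voronoi construction)."""
    xmin, ymin, xmax, ymax = bounds
    xs = xmin + (np.arange(n_grid) + 0.5) * (xmax - xmin) / n_grid
    ys = ymin + (np.arange(n_grid) + 0.5) * (ymax - ymin) / n_grid
    sample_area = ((xmax - xmin) / n_grid) * ((ymax - ymin) / n_grid)
    counts = np.zeros(len(centers), dtype=np.int64)
    chunk = max(1, 2**22 // n_grid)
    for start in range(0, n_grid, chunk):
        yy = ys[start : start + chunk]
        d2 = (
            (xs[None, :, None] - centers[None, None, :, 0]) ** 2
            + (yy[:, None, None] - centers[None, None, :, 1]) ** 2
        )
        labels = np.argmin(d2, axis=2).ravel()
        counts += np.bincount(labels, minlength=len(centers))
    return counts * sample_area
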