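from datetime import datetime, timedelta

import numpy as np
import pytest

from rewildscape.raster import Raster
from rewildscape.rem import CameraSpec, Deployment
from rewildscape.synthetic_data import LandscapeBundle, TrueDensityField


@pytest.fixture
def small_grid() -> Raster:
    """50 x 50 grid, 100 m cells, 5 x 5 km extent."""
    return Raster(data=np.zeros((50, 50)), xmin=0.0, ymax=5000.0, resolution=100.0)


@pytest.fixture
def uniform_field(small_grid) -> TrueDensityField:
    """Uniform true density of 10 ind/km^2 over the whole small grid."""
    surface = small_grid.like(np.full(small_grid.shape, 10.0))
    n = 10.0 * small_grid.cell_area_km2 * surface.data.size
    return TrueDensityField(species="roe_deer", surface=surface, total_abundance=n)


def make_deployments(n_cameras=4, trap_days=100.0, cell_id="A", r_m=20.0, theta=0.87):
    start = datetime(2021, 4, 1)
    end = start + timedelta(days=trap_days)
    spec = CameraSpec("test-cam", r_m, theta)
    return [
        Deployment(
            camera_id=f"{cell_id}{k}",
            spec=spec,
            location=(1000.0 + 500.0 * k, 1000.0),
            cell_id=cell_id,
            start=start,
            end=end,
        )
        for k in range(n_cameras)
    ]


@pytest.fixture
def four_cameras():
    return make_deployments()


def make_bundle(grid: Raster, suitability: np.ndarray | None = None,
                release=(2500.0, 2500.0)) -> LandscapeBundle:
    if suitability is None:
        suitability = np.ones(grid.shape)
    suit = grid.like(np.asarray(suitability, dtype=float))
    return LandscapeBundle(
        landcover_epoch1=grid.like(np.full(grid.shape, 321)),
        elevation=grid.like(np.full(grid.shape, 500.0)),
        suitability={"roe_deer": suit, "red_deer": suit, "livestock": suit},
        release_point=release,
        resolution=grid.resolution,
    )
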