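"""Shared fixtures: calibrated mitosis model and two benchmark movies.

The heavy fixtures are session-scoped; the clean growth movie feeds the
detection-quality and life-time-bias checks, the error-injected movie the
validation/purity checks.  Everything is generated at run time from fixed
seeds — no stored image data.
"""

from __future__ import annotations

import numpy as np
import pytest

from validtrack.evaluate import frame_correspondences
from validtrack.pipeline import TrackingParams, calibrate_mitosis_model, run_pipeline
from validtrack.simulate import SimulationConfig, simulate_movie


@pytest.fixture(scope="session")
def mitosis_model():
    return calibrate_mitosis_model(seed=11)


@pytest.fixture(scope="session")
def params():
    return TrackingParams()


#: clean growth movie: no injected errors, several hundred complete cell lives
CLEAN_CONFIG = SimulationConfig(
    width=950,
    height=950,
    n_frames=100,
    initial_cells=25,
    mean_lifetime_min=300.0,
    sd_lifetime_min=60.0,
    gradient_amplitude=12.0,
    seed=33,
)

#: error-injected movie: ~50 starting cells, 150 frames, all four error
#: scenarios seeded (merges, dropouts, border crossings, debris)
ERROR_CONFIG = SimulationConfig(
    width=900,
    height=900,
    n_frames=150,
    initial_cells=50,
    mean_lifetime_min=600.0,
    sd_lifetime_min=120.0,
    gradient_amplitude=12.0,
    border_mode="open",
    drift=(0.12, 0.08),
    n_merges=10,
    n_dropouts=8,
    n_debris=6,
    n_border_entries=5,
    seed=42,
)


@pytest.fixture(scope="session")
def clean_run(mitosis_model, params):
    model, t_mit = mitosis_model
    frames, truth = simulate_movie(CLEAN_CONFIG)
    result = run_pipeline(frames, params, model, t_mit)
    maps = frame_correspondences(result.masks, truth, params.overlap_floor)
    return {"truth": truth, "result": result, "maps": maps, "config": CLEAN_CONFIG}


@pytest.fixture(scope="session")
def error_run(mitosis_model, params):
    model, t_mit = mitosis_model
    frames, truth = simulate_movie(ERROR_CONFIG)
    result = run_pipeline(frames, params, model, t_mit)
    maps = frame_correspondences(result.masks, truth, params.overlap_floor)
    return {"truth": truth, "result": result, "maps": maps, "config": ERROR_CONFIG}


def disk_mask(radius: int, pad: int = 3) -> np.ndarray:
    """Rasterized filled disk, label 1, on an otherwise empty frame."""
    size = 2 * radius + 2 * pad + 1
    yy, xx = np.mgrid[:size, :size]
    c = radius + pad
    return (((xx - c) ** 2 + (yy - c) ** 2) <= radius**2).astype(np.uint16)
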