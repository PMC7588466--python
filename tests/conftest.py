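"""Shared fixtures: synthetic movies are generated once per session."""

import numpy as np
import pytest

from blebflow import segment_movie
from blebflow.synthetic import (BlebSpec, SimulationParams,
                                simulate_cell_movie)


@pytest.fixture(scope="session")
def plain_movie():
    """Bleb-free default-condition movie with segmentation products."""
    params = SimulationParams(n_frames=40, seed=7, store_flow=True)
    movie, truth = simulate_cell_movie(params)
    contours, masks = segment_movie(movie.membrane,
                                    pixel_size=params.pixel_size_um)
    return params, movie, truth, contours, masks


@pytest.fixture(scope="session")
def bleb_movie():
    """Movie with three well-separated scheduled blebs."""
    schedule = (BlebSpec(10.0, 20.0, 2.0, 6.0),
                BlebSpec(30.0, 90.0, 2.0, 6.0),
                BlebSpec(50.0, 170.0, 2.0, 6.0))
    params = SimulationParams(n_frames=130, seed=3, bleb_schedule=schedule,
                              store_flow=False)
    movie, truth = simulate_cell_movie(params)
    contours, masks = segment_movie(movie.membrane,
                                    pixel_size=params.pixel_size_um)
    return params, movie, truth, contours, masks


@pytest.fixture(scope="session")
def friction_pooled():
    """Condition-level decay fits: control vs friction-halved (doubled
    retrograde speed, doubled ground-truth decay length), eight cells
    per condition at the standard 490-frame acquisition."""
    from blebflow.pipeline import measure_decay_length

    def condition(lam, v, seeds):
        return measure_decay_length([
            SimulationParams(n_frames=490, seed=s, store_flow=False,
                             actin_decay_length_um=lam,
                             retrograde_speed_um_min=v)
            for s in seeds])

    fit_wt = condition(7.0, 6.0, range(8))
    fit_kd = condition(14.0, 12.0, range(500, 508))
    return fit_wt, fit_kd


@pytest.fixture
def ring_phantom():
    """Ideal noiseless membrane ring, radius 35 px centred at (64, 64)."""
    img = np.zeros((128, 128))
    th = np.linspace(0, 2 * np.pi, 3000)
    rr = np.clip(np.round(64 + 35 * np.sin(th)).astype(int), 0, 127)
    cc = np.clip(np.round(64 + 35 * np.cos(th)).astype(int), 0, 127)
    img[rr, cc] = 100.0
    return img
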