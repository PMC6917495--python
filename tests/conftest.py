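import numpy as np
import pytest

from t5model.model import simulate
from t5model.stimuli import DisplayGeometry, make_bar_flash, make_moving_bar
from t5model.synth import ground_truth_cell


@pytest.fixture(scope="session")
def geometry():
    return DisplayGeometry()


@pytest.fixture(scope="session")
def ei_cell():
    """A fixed trailing-inhibition ground-truth cell."""
    return ground_truth_cell("ei_trailing_inhibition", rng_seed=1)


@pytest.fixture(scope="session")
def epem_cell():
    return ground_truth_cell("epem", rng_seed=1)


@pytest.fixture(scope="session")
def width2_flash_dataset(ei_cell):
    """Noiseless width-2 flash training set from the EI ground truth:
    positions -4..4, both flash durations."""
    dataset = []
    for dur in (40.0, 160.0):
        for pos in range(-4, 5):
            movie = make_bar_flash(pos, 2, dur)
            v, _ = simulate(ei_cell, movie)
            dataset.append((movie, v.v_mV))
    return dataset


@pytest.fixture(scope="session")
def moving_bar_pair():
    """Width-2, 80 ms-step moving bars in both directions over -4..4."""
    return (make_moving_bar(-4, 4, 2, 80.0), make_moving_bar(4, -4, 2, 80.0))


def model_dsi(params, bar_pd, bar_nd):
    """DSI of a model on a PD/ND moving-bar pair (robust peak in the
    stimulus window)."""
    from t5model.metrics import dsi

    vp, _ = simulate(params, bar_pd)
    vn, _ = simulate(params, bar_nd)
    i0 = int(round(bar_pd.stim_onset_ms / bar_pd.dt_ms))
    i1 = int(round(bar_pd.stim_offset_ms / bar_pd.dt_ms))
    return dsi(vp.v_mV, vn.v_mV, slice(i0, i1))
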