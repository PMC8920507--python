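"""Shared fixtures: synthetic display, fundamentals, and simulated sessions."""

import numpy as np
import pytest

from v1iso import receptive_field as rf
from v1iso.display import gaussian_cone_fundamentals, gaussian_phosphor_display
from v1iso.neurons import make_neuron, simulate_white_noise
from v1iso.stimulus import hyperpixel_white_noise, pixel_white_noise


@pytest.fixture(scope="session")
def display():
    return gaussian_phosphor_display()


@pytest.fixture(scope="session")
def fundamentals():
    return gaussian_cone_fundamentals()


@pytest.fixture(scope="session")
def do_linear_neuron(display, fundamentals):
    return make_neuron("do_linear", display=display, fundamentals=fundamentals)


@pytest.fixture(scope="session")
def phase2_session(display, do_linear_neuron):
    """One simulated hyperpixel white-noise session for a linear DO cell."""
    neuron = do_linear_neuron
    movie = hyperpixel_white_noise(20_000, display, neuron.hmap, seed=11)
    spikes = simulate_white_noise(neuron, movie, seed=12)
    hsta = rf.compute_hyperpixel_sta(movie, spikes, neuron.hmap, display)
    return {"neuron": neuron, "movie": movie, "spikes": spikes, "hsta": hsta}


@pytest.fixture(scope="session")
def phase1_session(display, do_linear_neuron):
    """One simulated pixel white-noise session for the same cell."""
    neuron = do_linear_neuron
    movie = pixel_white_noise(30_000, display, seed=21)
    spikes = simulate_white_noise(neuron, movie, seed=22)
    sta = rf.compute_sta(movie, spikes, display)
    return {"neuron": neuron, "movie": movie, "spikes": spikes, "sta": sta}
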