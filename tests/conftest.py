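import numpy as np
import pytest

from ornmotif import population
from ornmotif.stimuli import square_pulse


@pytest.fixture(scope="session")
def pulse_1s():
    """1 s odor pulse with 1 s pre- and post-stimulus epochs."""
    return square_pulse(1.0, 1.0, 3.0)


@pytest.fixture(scope="session")
def surrogate_table():
    """Small template+noise surrogate recording set (1 s pulses)."""
    templates = population.motif_rate_templates(duration=3.0, onset=1.0, width=1.0)
    return population.surrogate_recordings(templates, n_pairs=120, trials=5,
                                           rate_jitter=0.15, seed=11)


@pytest.fixture(scope="session")
def surrogate_binned(surrogate_table):
    return population.bin_spikes(surrogate_table)
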