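import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from gapmech import synthetic

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from gapmech.peaks import PeakTable
from gapmech.pre import RelaxationParameters


def make_peak_table(rows):
    """rows: (residue, atom, dH, dX, nucleus, intensity, snr)"""
    return PeakTable(
        pd.DataFrame(
            rows,
            columns=["residue", "atom", "dH_ppm", "dX_ppm", "nucleus", "intensity", "snr"],
        )
    )


@pytest.fixture(scope="session")
def default_params():
    return RelaxationParameters()


@pytest.fixture(scope="session")
def toy_structures():
    return synthetic.gen_toy_structures(seed=0)


@pytest.fixture(scope="session")
def two_state(default_params):
    """Reference two-pose synthetic ensemble mixture (dominant weight 0.9)."""
    return synthetic.gen_two_state_ensemble(seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
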