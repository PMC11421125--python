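import numpy as np
import pandas as pd
import pytest

from movestate import LandscapeSpec, SimTruth, make_landscape
from movestate.synthetic_data import _sample_lengths


@pytest.fixture(scope="session")
def landscape():
    """Small shared landscape (2.5 km, 25 m cells)."""
    return make_landscape(LandscapeSpec(extent=2500.0, resolution=25.0, seed=42))


@pytest.fixture(scope="session")
def truth():
    return SimTruth()


def simulate_emission_steps(truth, n, seed, transition_matrix=None):
    """Markov-switching draws straight from the emission distributions.

    Returns (steps DataFrame with l/phi, true state array). Independent of
    the track simulator: no landscape, no selection.
    """
    rng = np.random.default_rng(seed)
    G = truth.transition_matrix if transition_matrix is None else transition_matrix
    s = 0
    states = np.empty(n, dtype=int)
    l = np.empty(n)
    phi = np.empty(n)
    for t in range(n):
        s = int(rng.random() < G[s, 1])
        states[t] = s
        sp = truth.state_params[s]
        l[t] = _sample_lengths(rng, sp, 1)[0]
        phi[t] = rng.vonmises(sp.vm_mean, max(sp.vm_conc, 1e-12))
    steps = pd.DataFrame({"l": l, "phi": phi})
    steps.loc[0, "phi"] = np.nan
    return steps, states
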