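import numpy as np
import pytest

from fretkin import bursts, h2mm, synth


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated measurement shared across tests."""
    cfg = synth.SimConfig(n_bursts=500, seed=42, burst_duration_mean=3e-4)
    ds = synth.simulate_dataset(cfg)
    table = bursts.find_bursts(ds.stream)
    photons = bursts.extract_burst_photons(ds, table)
    return cfg, ds, table, photons


@pytest.fixture(scope="session")
def fitted_small(small_sim):
    """Two-state fit of the shared dataset (from a good initial model)."""
    cfg, ds, table, photons = small_sim
    init = h2mm.H2MMModel(np.array([0.3, 0.7]), np.array([[-1e4, 1e4], [1e4, -1e4]]))
    model, record = h2mm.em_fit(init, photons, ds.clock_period, tol=1e-6)
    return model, record


def true_states_for_bursts(ds, table):
    """Per-photon generator states for the donor-excitation photons of each burst."""
    out = []
    for i0, i1 in zip(table["i0"].astype(int), table["i1"].astype(int)):
        sl = slice(i0, i1 + 1)
        exc = ds.stream.excitation[sl]
        out.append(ds.truth.state[sl][exc == 0])
    return out
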