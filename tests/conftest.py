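import numpy as np
import pytest

from oxtrsim import calibration, metrics as M, network as N


@pytest.fixture(scope="session")
def stim():
    return N.StimulusProtocol()


@pytest.fixture(scope="session")
def cfg():
    return N.SimulationConfig()


@pytest.fixture(scope="session")
def wt_net():
    return N.build_network("WT")


@pytest.fixture(scope="session")
def wt_traj(wt_net, stim, cfg):
    return N.simulate(wt_net, stim, cfg)


@pytest.fixture(scope="session")
def wt_metrics(wt_traj):
    return M.compute_metrics(N.extract_ca_trace(wt_traj))


@pytest.fixture(scope="session")
def comparison(stim, cfg):
    """WT vs A218T under the shipped default parameter table."""
    return calibration.compare_variants(None, stim, cfg)


def toy_binding_network(kf=1e-3, kr=0.05, a0=80.0, b0=120.0):
    """A + B <-> AB in a single compartment, plus an inert clamped ligand."""
    species = [
        N.Species("L", "extracellular", 0.0),
        N.Species("A", "cytosol", a0),
        N.Species("B", "cytosol", b0),
        N.Species("AB", "cytosol", 0.0),
    ]
    params = [N.RateParameter("kf", kf), N.RateParameter("kr", kr)]
    rxns = [N.Reaction("bind", {"A": 1, "B": 1}, {"AB": 1}, "mass_action",
                       "kf", "kr")]
    return N.ReactionNetwork(species=species, reactions=rxns, parameters=params,
                             variant="WT", ligand="L", ca_cyt_species="A")


def random_smooth_trace(rng, n=400, dt=0.5, t_stim=60.0):
    """A seeded single-transient trace with smooth shape variation."""
    from oxtrsim.synth import pulse_kernel

    t = np.arange(n) * dt
    base = rng.uniform(0.5, 1.5)
    amp = rng.uniform(0.2, 2.0)
    rise = rng.uniform(1.0, 8.0)
    decay = rise + rng.uniform(5.0, 40.0)
    sig = base + amp * pulse_kernel(t - t_stim, rise, decay)
    return M.CaTrace(time=t, signal=sig, cell_id="r", t_stim=t_stim)
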