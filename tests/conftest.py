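import numpy as np
import pytest

from electrosolv.bd import SimulationConfig, initialize_ensemble, run
from electrosolv.constants import kBT
from electrosolv.scenarios import get_scenario, resolve_potential
from electrosolv.synth import SizeDistribution


@pytest.fixture(scope="session")
def kT():
    return kBT()


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test so results don't depend on
    # execution order
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def silica_cluster_traj():
    """Long attractive BD run of the silica-in-water preset (desk scale).

    Shared by the cluster-structure and stationarity checks; N ~ 115 in a
    120 um box at the experimental density, run well past the onset of
    cluster formation.
    """
    sc = get_scenario("silica_water")
    params, _ = resolve_potential(sc)
    cfg = SimulationConfig(box=(120e-6, 120e-6), density=0.008e12,
                           total_time=1200.0, sample_interval=2.0,
                           temperature=sc.conditions.T,
                           viscosity=sc.conditions.eta, seed=2,
                           placement_buffer=3.0 / params.kappa1)
    dist = SizeDistribution(sc.diameter_mean, sc.diameter_cv)
    ens = initialize_ensemble(cfg, dist, seed=2)
    traj = run(ens, params, cfg)
    return sc, params, traj
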