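import numpy as np
import pandas as pd
import pytest

import rtmra
from rtmra.simulate import SimulationConfig, simulate_rt_genome, simulate_tumor


@pytest.fixture(scope="session")
def sim_config():
    return SimulationConfig(seed=101)


@pytest.fixture(scope="session")
def genome(sim_config):
    rng = np.random.default_rng(101)
    track, constitutive, chromatin = simulate_rt_genome(sim_config, rng)
    return track, constitutive, chromatin


@pytest.fixture(scope="session")
def rt_binning(genome):
    track, _, _ = genome
    return rtmra.make_rt_bins(track, 4)


@pytest.fixture(scope="session")
def chromatin_binning(genome):
    _, _, chromatin = genome
    return rtmra.make_chromatin_bins(chromatin)


def simulate_profiles(config, binning, rhos, n_mutations, seed, project="P"):
    """Simulate one tumor per planted rho and count it on ``binning``."""
    rng = np.random.default_rng(seed)
    profiles = []
    for i, rho in enumerate(rhos):
        muts = simulate_tumor(config, binning, rho, rng,
                              n_mutations=n_mutations)
        profiles.append(
            rtmra.count_by_bins(muts, binning, tumor_id=f"{project}_T{i:04d}",
                                project_id=project)
        )
    return profiles


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A small but complete synthetic cohort on disk."""
    cfg = SimulationConfig(seed=7, n_projects=2, tumors_per_project=12)
    cfg.expression.n_genes = 400
    cfg.expression.n_de_genes = 40
    out = tmp_path_factory.mktemp("cohort")
    rtmra.simulate_cohort(cfg, str(out), force=True)
    return str(out)
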