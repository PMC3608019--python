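import numpy as np
import pytest

from refugia.grid import GridSpec
from refugia.pipeline import RunConfig, simulate
from refugia import synthetic as syn


@pytest.fixture(scope="session")
def default_config() -> RunConfig:
    cfg = RunConfig(seed=1)
    cfg.tree["bootstrap_replicates"] = 20
    cfg.nulltest["n_null"] = 99
    return cfg


@pytest.fixture(scope="session")
def bundle(tmp_path_factory, default_config):
    """A full synthetic input bundle on disk, shared across tests."""
    out = tmp_path_factory.mktemp("bundle")
    truth = simulate(default_config, out)
    return out, truth, default_config


@pytest.fixture(scope="session")
def small_system():
    """In-memory two-species system with sequences, for unit tests."""
    spec = GridSpec(60, 60)
    cfg = RunConfig(seed=3)
    cur, gla = syn.generate_climate_stack(spec, seed=3, **cfg.climate)
    truth = syn.generate_species_system((cur, gla), seed=4, **cfg.species)
    aln_df, pops_df = syn.simulate_sequences(truth, seed=5, **cfg.sequences)
    return truth, aln_df, pops_df, (cur, gla)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
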