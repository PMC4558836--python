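import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from psmopt import SearchParams, digest_proteome
from psmopt.synthetic_data import SimConfig, generate_proteome, simulate_dataset

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_sim():
    """The default 1,000-spectrum simulation with its candidate index."""
    cfg = SimConfig()
    rng = np.random.default_rng(cfg.seed)
    proteome = generate_proteome(cfg, rng)
    spectra, truth, planted = simulate_dataset(proteome, cfg, rng)
    index = digest_proteome(proteome)
    return {
        "cfg": cfg,
        "proteome": proteome,
        "spectra": spectra,
        "truth": truth,
        "planted_rt": planted,
        "index": index,
    }


@pytest.fixture(scope="session")
def small_sim():
    """A reduced simulation for exhaustive (grid/brute-force) checks."""
    cfg = SimConfig(n_proteins=8, protein_length=250, n_spectra=200, seed=11)
    rng = np.random.default_rng(cfg.seed)
    proteome = generate_proteome(cfg, rng)
    spectra, truth, planted = simulate_dataset(proteome, cfg, rng)
    index = digest_proteome(proteome)
    return {
        "cfg": cfg,
        "proteome": proteome,
        "spectra": spectra,
        "truth": truth,
        "planted_rt": planted,
        "index": index,
    }


@pytest.fixture
def base_params():
    return SearchParams()
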