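import numpy as np
import pytest

from pmap import phenotyping, synth


@pytest.fixture(scope="session")
def small_config() -> synth.SynthConfig:
    """Compact but fully structured synthetic scenario (tails of 15)."""
    return synth.SynthConfig(
        n_genes=300,
        n_samples_per_condition=36,
        n_planted_pdegs_per_class=15,
        ppi_n_nodes=450,
        n_planted_n1=2,
        planted_n1_min_pdeg_links=4,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_scenario(small_config):
    """Ground truth, EC50 table, assignments, expression and PPI edges."""
    truth = synth.plant_truth(small_config)
    ec50 = synth.generate_ec50(small_config)
    assignments = phenotyping.assign_phenotypes(ec50, k=small_config.k)
    expr, truth = synth.generate_expression(small_config, assignments, truth)
    edges = synth.generate_ppi(small_config, truth)
    return {
        "config": small_config,
        "truth": truth,
        "ec50": ec50,
        "assignments": assignments,
        "expr": expr,
        "edges": edges,
    }


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
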