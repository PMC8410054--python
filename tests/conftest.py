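import numpy as np
import pytest

from fcgsig import (SimConfig, default_effects, hyperoxia_contrasts,
                    simulate_cohort, simulate_murine_counts)


@pytest.fixture(scope="session")
def planted_cfg():
    return SimConfig(n_genes=1200, seed=5)


@pytest.fixture(scope="session")
def planted_effects(planted_cfg):
    return default_effects(planted_cfg)


@pytest.fixture(scope="session")
def planted_study(planted_cfg, planted_effects):
    return simulate_murine_counts(planted_cfg, planted_effects)


@pytest.fixture(scope="session")
def p5_contrasts(planted_study):
    return hyperoxia_contrasts(planted_study, "P5")


@pytest.fixture(scope="session")
def planted_cohort(planted_cfg, p5_contrasts):
    sig = p5_contrasts["XXF"].signature
    return simulate_cohort(planted_cfg, sig, loading=2.0, sex_specific=True,
                           n_per_sex=60, seed=17)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
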