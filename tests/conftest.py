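import numpy as np
import pytest

import cricketsize as cs

# reduced sampler protocol for tests; the package default follows the full
# two-chain 10k/10k protocol
FAST = dict(chains=2, burn_in=800, samples=800)
MEDIUM = dict(chains=2, burn_in=1500, samples=1500)


@pytest.fixture(scope="session")
def study_design():
    return cs.default_study_design()


@pytest.fixture(scope="session")
def study_effects():
    return cs.default_study_effects()


@pytest.fixture(scope="session")
def records(study_design, study_effects):
    """One synthetic dataset with the full study structure (seed frozen)."""
    return cs.simulate_individuals(study_design, study_effects, seed=11)


@pytest.fixture(scope="session")
def pairs(records, study_effects):
    return cs.simulate_dual_measurements(records, study_effects, n_pairs=48,
                                         seed=12)


@pytest.fixture(scope="session")
def conversions(pairs):
    return cs.fit_all_conversions(pairs)


@pytest.fixture(scope="session")
def femur_fit(records, conversions):
    model = cs.TraitModel(records, "femur", conversion=conversions["femur"])
    return model.fit(seed=13, **MEDIUM)


@pytest.fixture(scope="session")
def digital_records(study_design, study_effects):
    """Same study layout but every cohort measured digitally."""
    import dataclasses
    design = dataclasses.replace(study_design, calliper_cells=frozenset())
    return cs.simulate_individuals(design, study_effects, seed=21)
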