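"""Shared fixtures: small simulated experiments reused across modules.

The expensive objects (cohorts, simulated responses) are module- or
session-scoped so the suite stays fast; sizes are reduced relative to
the full study (fewer cells, fewer gap conditions) where the property
under test does not need the full design.
"""

import numpy as np
import pandas as pd
import pytest

from shepadapt.cohort import (CohortConfig, NoiseConfig, emulate_recorded_cohort,
                              simulate_experiment)
from shepadapt.dynamic_model import ModelConfig, make_population, preferred_tone_response
from shepadapt.stimuli import PairConfig, TuningConfig, generate_biased_pair_set


@pytest.fixture(scope="session")
def pair_sequences():
    return generate_biased_pair_set(PairConfig(), seed=7)


@pytest.fixture(scope="session")
def small_cohort():
    """240-cell heterogeneous cohort with the default dynamic model."""
    pop, meta = emulate_recorded_cohort(CohortConfig(n=240), ModelConfig(), seed=11)
    return pop, meta


@pytest.fixture(scope="session")
def cohort_response(pair_sequences, small_cohort):
    """Noisy trial-resolved responses of the small cohort to the full
    biased-pair design (10 Poisson repetitions)."""
    pop, meta = small_cohort
    return simulate_experiment(pair_sequences, pop, NoiseConfig(), seed=13,
                               neuron_meta=meta)


@pytest.fixture(scope="session")
def symmetric_population():
    """The symmetric 500-cell thirds model population, rate-calibrated."""
    pop = make_population(ModelConfig(n_cortical=500, directional_fraction=2 / 3))
    pref = preferred_tone_response(pop)
    pop.rate_gain = 20.0 / np.where(pref > 0, pref, 1.0)
    return pop


@pytest.fixture(scope="session")
def symmetric_response(pair_sequences, symmetric_population):
    return simulate_experiment(pair_sequences, symmetric_population,
                               NoiseConfig(tail=0.5), seed=17)
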