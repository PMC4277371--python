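import numpy as np
import pytest

from emrec import pipeline, synthetic


@pytest.fixture(scope="session")
def default_pop():
    return synthetic.PopulationParams()


@pytest.fixture(scope="session")
def default_design():
    return synthetic.StudyDesign()


@pytest.fixture(scope="session")
def identifiability_design():
    """Low-noise validation design: balanced nu 1-4, no censoring/quantization.

    Used for machinery-validation checks where the heavy censoring of the
    operating-point design would confound estimator correctness with
    sampling noise.
    """
    return synthetic.StudyDesign(
        nu_weights={1: 23, 2: 23, 3: 22, 4: 22},
        time_limit=1e9,
        quantization=0.0,
        decision_surplus=0.0,
        rt_trial_jitter_sd=0.0,
    )


@pytest.fixture(scope="session")
def default_study(default_pop, default_design):
    """One operating-point study (91 x 90, censored, shared common mode)."""
    return synthetic.simulate_er_study(default_pop, default_design, rng_seed=1)


@pytest.fixture(scope="session")
def identifiability_study(default_pop, identifiability_design):
    return synthetic.simulate_er_study(
        default_pop, identifiability_design, rng_seed=3, common_mode="paired"
    )


@pytest.fixture(scope="session")
def identifiability_results(identifiability_study):
    return pipeline.analyze_er_study(identifiability_study, corrected=True, delta=0.0)


def true_nu(trials):
    return trials.drop_duplicates("image_id").set_index("image_id")["nu"]


def true_z(trials):
    return trials.drop_duplicates("subject_id").set_index("subject_id")["true_Z"]
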