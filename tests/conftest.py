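import numpy as np
import pandas as pd
import pytest

import cordmeth as cm
from cordmeth.synthetic import DEFAULT_CELL_TYPES, SimulationConfig


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Default-size cohort with noise 0 and a planted -2 wk deceleration."""
    config = SimulationConfig(noise_sd=0.0, deceleration_delta_weeks=-2.0, seed=3)
    clock = cm.make_toy_clock(config.n_clock_probes, seed=3)
    reference = cm.make_cell_reference(
        config.n_cell_types, config.n_background_probes, seed=3,
        cell_types=DEFAULT_CELL_TYPES,
    )
    es_models = cm.default_es_models(seed=3)
    beta, cohort, detp, annot, truth = cm.simulate_cohort(
        config, clock, reference, es_models
    )
    return {
        "config": config,
        "clock": clock,
        "reference": reference,
        "es_models": es_models,
        "beta": beta,
        "cohort": cohort,
        "detection_p": detp,
        "annotation": annot,
        "truth": truth,
    }


@pytest.fixture(scope="session")
def noisy_cohort():
    """Default study conditions (noise, planted deceleration and ES shifts)."""
    config = SimulationConfig(seed=7)
    clock = cm.make_toy_clock(config.n_clock_probes, seed=7)
    reference = cm.make_cell_reference(
        config.n_cell_types, config.n_background_probes, seed=7,
        cell_types=DEFAULT_CELL_TYPES,
    )
    es_models = cm.default_es_models(seed=7)
    beta, cohort, detp, annot, truth = cm.simulate_cohort(
        config, clock, reference, es_models
    )
    return {
        "config": config,
        "clock": clock,
        "reference": reference,
        "es_models": es_models,
        "beta": beta,
        "cohort": cohort,
        "detection_p": detp,
        "annotation": annot,
        "truth": truth,
    }


@pytest.fixture()
def toy_beta():
    return pd.DataFrame(
        np.array([[0.1, 0.2], [0.2, 0.3], [0.3, 0.4]]),
        index=["cg1", "cg2", "cg3"],
        columns=["s1", "s2"],
    )
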