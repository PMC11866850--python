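import numpy as np
import pandas as pd
import pytest

from actifrail import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 4,000-participant cohort with a boosted event rate.

    The baseline rate is raised fourfold over the study-scale default so
    every joint group carries events at this reduced sample size; the
    injected hazard ratios and all structural features are unchanged.
    """
    cfg = GeneratorConfig(
        n_participants=4_000,
        seed=424,
        n_epoch_participants=0,
        gompertz_rate_at_50=4.1e-3,
    )
    cohort, _, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def epoch_sample():
    """A 60-participant cohort with full epoch emission."""
    cfg = GeneratorConfig(n_participants=60, seed=77, n_epoch_participants=60)
    cohort, epochs, truth = generate_cohort(cfg)
    return cfg, cohort, epochs, truth
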