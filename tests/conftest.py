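import numpy as np
import pandas as pd
import pytest

from confclust.synth import (
    CohortSpec,
    ErpComponentSpec,
    ErpTemplateSpec,
    NoiseSpec,
    ObserverSpec,
    simulate_behavior,
    simulate_epochs,
)

SMALL_CHANNELS = ["Fz", "FCz", "FC1", "FC2", "Cz", "C1", "C2", "Pz", "POz", "Oz"]


@pytest.fixture(scope="session")
def small_trials() -> pd.DataFrame:
    cohort = CohortSpec(n_group_a=4, n_group_b=4, trials_per_participant=80, seed=7)
    obs = ObserverSpec()
    trials = simulate_behavior(cohort, obs, obs, rng=np.random.default_rng(7))
    return trials[trials["true_exclusion"] == "none"].reset_index(drop=True)


@pytest.fixture(scope="session")
def small_epochs(small_trials):
    # deliberately strong effect: this fixture backs power/recovery tests on a
    # small cohort; study-scale SNR is exercised in the acceptance suite
    comp = ErpComponentSpec(
        name="correctness_central",
        topography={"Cz": 1.0, "C1": 0.95, "C2": 0.95},
        peak_latency=0.266, width=0.055, modulator="correctness", gain=-1.2,
    )
    templates = ErpTemplateSpec(components=(comp,))
    noise = NoiseSpec(pink_sd=0.8, white_sd=0.6, intercept_sd=0.5)
    return simulate_epochs(
        small_trials, templates, noise, SMALL_CHANNELS,
        window=(-0.75, 0.8), rng=np.random.default_rng(11),
    )
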