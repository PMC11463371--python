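import numpy as np
import pytest

from reachkdi.config import CoreConfig, PreprocessConfig
from reachkdi.preprocessing import preprocess_trial
from reachkdi.synthetic import PerturbationSpec, generate_trial, subject_template

# analysis configuration for the single-pellet task: the pellet is a
# static landmark, so only the digit markers enter X_i
REACH_PREPROCESS = PreprocessConfig(exclude_markers=["pellet"])


@pytest.fixture(scope="session")
def template():
    return subject_template(np.random.default_rng(7))


@pytest.fixture(scope="session")
def baseline_trials(template):
    """Ten preprocessed baseline-success trials from one animal."""
    out = []
    for i in range(10):
        raw = generate_trial(
            template, endpoint="success", perturbation=PerturbationSpec("none"),
            noise_sd=1.5, duration_jitter=0.15, seed=1000 + i,
            trial_id=f"b{i}", animal_id="a1",
        )
        out.append(preprocess_trial(raw, REACH_PREPROCESS)[0])
    return out


def make_normalized(template, perturbation, seed, preprocess=REACH_PREPROCESS,
                    endpoint="unknown", trial_id=None, noise_sd=1.5,
                    duration_jitter=0.15):
    raw = generate_trial(
        template, endpoint=endpoint, perturbation=perturbation,
        noise_sd=noise_sd, duration_jitter=duration_jitter, seed=seed,
        trial_id=trial_id or f"t{seed}", animal_id="a1",
    )
    return preprocess_trial(raw, preprocess)[0]


@pytest.fixture(scope="session")
def core_config():
    return CoreConfig()
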