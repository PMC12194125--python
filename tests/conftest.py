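import warnings

import numpy as np
import pytest

from trmkin import (
    McmcSettings,
    StudyDesign,
    default_truths,
    fit_model,
    generate_dataset,
)
from trmkin.recovery import config_for_truth

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", message=".*Pareto.*")


@pytest.fixture(scope="session")
def truths():
    return default_truths()


@pytest.fixture(scope="session")
def small_design():
    """Reduced cohort for fast fits in unit tests."""
    return StudyDesign(n_mice_ki67divn=9, n_mice_cd4fr=9)


@pytest.fixture(scope="session")
def small_skin_data(truths, small_design):
    return generate_dataset(truths["skin_trm"], small_design, seed=42)


@pytest.fixture(scope="session")
def short_mcmc():
    return McmcSettings(seed=5, walkers=28, steps=400, warmup=250, thin=3)


@pytest.fixture(scope="session")
def skin_fit_full_design(truths):
    """Full-design skin fit shared by the acceptance checks."""
    truth = truths["skin_trm"]
    data = generate_dataset(truth, StudyDesign(), seed=1)
    return truth, fit_model(data, config_for_truth(truth, McmcSettings(seed=11)))


@pytest.fixture(scope="session")
def lp_fit_full_design(truths):
    truth = truths["lp_trm"]
    data = generate_dataset(truth, StudyDesign(), seed=2)
    return truth, fit_model(data, config_for_truth(truth, McmcSettings(seed=12)))
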