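import numpy as np
import pytest

from lossaver.choice_model import ProspectParams, simulate_choices
from lossaver.cleaning import clean_cohort
from lossaver.choice_model import frame_to_cohort
from lossaver.synthetic_data import GeneratorConfig, generate_cohort
from lossaver.task_design import generate_design


@pytest.fixture(scope="session")
def design128():
    return generate_design(128, seed=42)


@pytest.fixture(scope="session")
def typical_params():
    return ProspectParams(lam=1.58, rho=0.60, tau=3.07)


@pytest.fixture(scope="session")
def simulated_subject(design128, typical_params):
    return simulate_choices(design128, typical_params, seed=7, subject_id="sub01")


@pytest.fixture(scope="session")
def recovery_cohort():
    """40 x 128-trial cohort around group lambda 1.6 (no age structure)."""
    cfg = GeneratorConfig(
        n_subjects=40,
        lambda_mean=1.6,
        lambda_sd=0.3,
        age_beta1=0.0,
        age_beta2=0.0,
        mediated_fraction=0.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def recovery_fit(recovery_cohort):
    """Converged hierarchical fit of the recovery cohort (shared; ~4 min)."""
    import warnings

    from lossaver.hbayes_fit import MCMCConfig, fit_hierarchical

    kept, _ = clean_cohort(frame_to_cohort(recovery_cohort.trials))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        post = fit_hierarchical(
            kept, MCMCConfig(n_chains=4, n_warmup=1200, n_draws=2000, seed=1)
        )
    return kept, post


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
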