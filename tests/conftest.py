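import numpy as np
import pytest

from burdenssm import SyntheticConfig, simulate_study
from burdenssm.ssm_core import CovariateSet, PriorConfig, SSMDataset, SSMParameters


@pytest.fixture(scope="session")
def prior():
    return PriorConfig()


@pytest.fixture(scope="session")
def true_params():
    from burdenssm import DEFAULT_TRUE_PARAMS

    return DEFAULT_TRUE_PARAMS


@pytest.fixture(scope="session")
def study_t10():
    """Small complete synthetic study (T=10) shared by oracle tests."""
    cfg = SyntheticConfig(T=10, seed=2)
    dataset, latent, panel = simulate_study(cfg)
    return cfg, dataset, latent


@pytest.fixture(scope="session")
def study_t28():
    """Reference-size study (T=28) with MCAR-masked utilization indicators."""
    cfg = SyntheticConfig(T=28, seed=3)
    dataset, latent, panel = simulate_study(cfg, missing_indicators=True)
    return cfg, dataset, latent


@pytest.fixture()
def tiny_dataset():
    """Hand-built T=5 dataset with standard-normal covariates/indicators."""
    rng = np.random.default_rng(7)
    T = 5
    cov = CovariateSet(*[rng.standard_normal(T) for _ in range(7)])
    return SSMDataset(
        years=np.arange(2000, 2000 + T),
        covariates=cov,
        y1=rng.standard_normal(T),
        y2=rng.standard_normal(T),
        y3=rng.standard_normal(T),
    )


def mask_all(dataset: SSMDataset) -> SSMDataset:
    """Copy of a dataset with every indicator cell masked."""
    T = len(dataset)
    nan = np.full(T, np.nan)
    return SSMDataset(
        years=dataset.years,
        covariates=dataset.covariates,
        y1=nan.copy(),
        y2=nan.copy(),
        y3=nan.copy(),
    )
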