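import numpy as np
import pytest

from salmon_lcm import synthdata as sd
from salmon_lcm.envsim import ClimateScenario, CovarianceModel, simulate_detrended
from salmon_lcm.lifecycle import LifecycleParams
from salmon_lcm.stage_models import (
    GompertzStageParams,
    MainstemTable,
    MaturationParams,
    SarParams,
    UpstreamParams,
)


@pytest.fixture(scope="session")
def world():
    """Small two-population synthetic world shared across tests."""
    return sd.default_world(11, populations=("sulphur_creek", "camas_creek"))


@pytest.fixture(scope="session")
def cov_truth():
    return sd.default_covariance_model()


@pytest.fixture(scope="session")
def detrended_scenario(cov_truth):
    draws = simulate_detrended(cov_truth, 75, 60, seed=21, start_year=2015)
    return ClimateScenario(draws)


def flat_mainstem_table(survival=0.6, p_transport=0.4):
    """Single-bin, single-record table: mainstem passage with no climate path."""
    return MainstemTable(
        temp_edges=np.array([-100.0, 100.0]),
        flow_edges=np.array([-100.0, 100.0]),
        temp=np.array([0.0]), flow=np.array([0.0]),
        survival=np.array([survival]),
        arrival_shift=np.array([0.0]),
        p_transport=np.array([p_transport]),
    )


def climate_free_params(sigma_proc=0.0, day_sd=0.0, mainstem_survival=0.6,
                        a1=5.0, b1=-0.3, a2=2.5, b2=-0.4, sar_intercept=-3.0,
                        maturation=None, prespawn=0.9, upstream_intercept=2.0):
    """Lifecycle parameters with every climate pathway switched off."""
    return LifecycleParams(
        g1=GompertzStageParams(a=a1, b=b1, c={}, sigma_proc=sigma_proc),
        g2=GompertzStageParams(a=a2, b=b2, c={}, sigma_proc=sigma_proc),
        mainstem=flat_mainstem_table(survival=mainstem_survival),
        sar_in_river=SarParams(sar_intercept, {}, day_sd=day_sd, day_rho=0.5,
                               variant="in_river"),
        sar_transported=SarParams(sar_intercept, {}, day_sd=day_sd, day_rho=0.5,
                                  variant="transported"),
        maturation=maturation or MaturationParams(S0=0.7, b3=0.1, b4=0.6, F5=1.1),
        upstream=UpstreamParams(intercept=upstream_intercept, betas={}),
        prespawn=prespawn,
    )
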