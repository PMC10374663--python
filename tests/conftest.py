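import numpy as np
import pytest
from hypothesis import settings

from proteoturn import simdata

settings.register_profile("repro", derandomize=True)
settings.load_profile("repro")


@pytest.fixture
def small_config():
    """Small default simulation config for fast tests."""
    return simdata.SimConfig(seed=11, n_proteins=40, n_replicates=2)


@pytest.fixture
def noiseless_config():
    """Noise-free, degradation-free config: pure dilution decay."""
    return simdata.SimConfig(
        seed=7,
        n_proteins=25,
        ratio_noise_sd=0.0,
        melt_noise_sd=0.0,
        kdeg_logmean=np.log(1e-12),
        kdeg_logsd=1e-12,
        kdil_per_strain={"WT": 0.3648},
    )
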