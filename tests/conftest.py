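import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from scoliogen.synthetic import SimConfig


@pytest.fixture
def small_cfg() -> SimConfig:
    """A small deterministic simulation: 10 genes, 8 SNPs, 50+200 cohort."""
    return SimConfig(
        seed=7, n_genes=10, n_snps=8, ld_block_size=2,
        n_cases=50, n_controls=200, target_or=4.0,
        baseline_carrier_rate=0.05, causal_gene="G0001",
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
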