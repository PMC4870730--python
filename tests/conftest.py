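import numpy as np
import pytest

import copd_epistasis as ce


@pytest.fixture(scope="session")
def small_panel():
    """Six SNPs in two blocks, moderate LD."""
    return ce.make_panel(6, n_blocks=2, maf=0.3)


@pytest.fixture(scope="session")
def tiny_cohort():
    """A 60-case / 40-control cohort on a 12-SNP panel (session-wide)."""
    config = ce.CohortConfig(
        panel=ce.make_panel(12, n_blocks=3, maf=0.25),
        n_cases=60,
        n_controls=40,
    )
    return ce.simulate_cohort(config, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
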