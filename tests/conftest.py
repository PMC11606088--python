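import numpy as np
import pandas as pd
import pytest

from gxagechange.designs import ukb_trait_designs
from gxagechange.simulate import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def designs():
    """The eight packaged UKB-like trait designs."""
    return ukb_trait_designs()


@pytest.fixture(scope="session")
def small_cohort():
    """A modest cohort with one causal interaction variant and two null ones."""
    cfg = SimConfig(
        n_individuals=20_000,
        n_variants=3,
        beta_g=0.1,
        beta_age=0.02,
        beta_gxage=0.012,
        sd_y=1.0,
        r_y1y2=0.91,
        followup_fraction=0.25,
        seed=202,
    )
    return simulate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_records(**cols) -> pd.DataFrame:
    """Small helper for association-record frames in tests."""
    n = max(len(v) for v in cols.values())
    base = {
        "variant": [f"v{i}" for i in range(n)],
        "chrom": ["1"] * n,
        "pos": list(range(100_000, 100_000 + n * 10_000, 10_000)),
        "ea": ["A"] * n,
        "oa": ["G"] * n,
        "eaf": [0.3] * n,
    }
    base.update(cols)
    return pd.DataFrame(base)
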