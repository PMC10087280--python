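import numpy as np
import pytest

from brgdgt import CultureGridConfig, EffectModel, generate_culture_dataset
from brgdgt.pipeline import culture_index_table
from brgdgt.samples import BrgdgtProfile


@pytest.fixture(scope="session")
def default_dataset():
    """Default synthetic culture grid (seed 42) with paired OD curves."""
    samples, curves = generate_culture_dataset(CultureGridConfig(), seed=42)
    return samples, curves


@pytest.fixture(scope="session")
def default_table(default_dataset):
    samples, _ = default_dataset
    return culture_index_table(samples)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240817)


def make_profile(sample_id="s1", **abundances):
    totals = {k: abundances.pop(k) for k in ("fa_total", "mage_total", "dage_total")
              if k in abundances}
    return BrgdgtProfile(sample_id=sample_id, abundance=abundances, **totals)
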