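import numpy as np
import pytest

from esnacchip.signal_model import RatioProfile
from esnacchip.synthetic_data import SimConfig


def small_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """A fast, fully featured miniature of the default study conditions."""
    base = dict(
        n_chromosomes=2,
        chromosome_length=200_000,
        n_genes=60,
        n_planted_sites=6,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def null_sim_config(seed: int = 0, **overrides) -> SimConfig:
    """No planted sites, ~5,000 probes: the null-calibration condition."""
    base = dict(
        n_chromosomes=2,
        chromosome_length=700_000,
        n_genes=333,
        n_planted_sites=0,
        seed=seed,
    )
    base.update(overrides)
    return SimConfig(**base)


def make_profile(values, spacing=100, chrom="chr1", scaled=True, **kw) -> RatioProfile:
    values = np.asarray(values, dtype=float)
    return RatioProfile(
        chroms=np.array([chrom] * values.size, dtype=object),
        positions=np.arange(values.size, dtype=np.int64) * spacing,
        values=values,
        replicate_id=kw.pop("replicate_id", "rep1"),
        scaled=scaled,
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
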