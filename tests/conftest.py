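import numpy as np
import pytest

from myoshift.csa_shift import CSASample
from myoshift.synthetic import CSAGenConfig, gen_csa_samples


@pytest.fixture
def lognormal_sample() -> CSASample:
    """A plain lognormal fiber sample (median 500 um^2, sigma 0.5, n=200)."""
    rng = np.random.default_rng(42)
    return CSASample(500.0 * np.exp(0.5 * rng.standard_normal(200)),
                     group="control", muscle="GAS")


@pytest.fixture
def paired_multiplicative_pair():
    """Noise-free paired pair with a true multiplicative factor K = 1.72."""
    cfg = CSAGenConfig(
        effect_kind="multiplicative", effect_value=1.72, noise_frac=0.0,
        paired=True, seed=7,
    )
    return gen_csa_samples(cfg)


@pytest.fixture
def paired_additive_pair():
    """Noise-free paired pair with a true additive shift S = 140 um^2."""
    cfg = CSAGenConfig(
        median_um2=700.0, effect_kind="additive", effect_value=140.0,
        noise_frac=0.0, paired=True, seed=7,
    )
    return gen_csa_samples(cfg)
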