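import numpy as np
import pytest

from rna2state.exchange import ExchangeParams
from rna2state.synthetic import gen_exchange_dataset, scenario


@pytest.fixture
def u24_params() -> ExchangeParams:
    """U24-like reporter: k_ex = 20.89 s^-1 split 60/40 by detailed balance."""
    return ExchangeParams(k_f=20.89 * 0.4, k_b=20.89 * 0.6, r1_a=2.5, r1_b=2.5)


@pytest.fixture
def asymmetric_params() -> ExchangeParams:
    return ExchangeParams(k_f=8.356, k_b=12.534, r1_a=2.0, r1_b=3.0)


@pytest.fixture
def u24_datasets(u24_params):
    """One noisy four-channel dataset at SNR 100 and the standard 11 mixing times."""
    from dataclasses import replace

    cfg = scenario("paper_apo", seed=7)
    cfg = replace(cfg, residues=(cfg.residues[0],))
    return gen_exchange_dataset(cfg)


def random_valid_params(rng: np.random.Generator) -> ExchangeParams:
    k_f, k_b = rng.uniform(0.0, 30.0, 2)
    r1_a, r1_b = rng.uniform(0.2, 6.0, 2)
    return ExchangeParams(k_f, k_b, r1_a, r1_b)
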