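import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))   # make oracles importable

from loopex import ExchangeModel


@pytest.fixture
def slow_model() -> ExchangeModel:
    """Slow-exchange condition: two resolved lines, EXSY-visible rates."""
    return ExchangeModel(p_E=0.26, k_ex=35.0, omega_G=0.0, omega_E=940.0,
                         R1_G=0.8, R1_E=0.8, R2_G=120.0, R2_E=120.0)


@pytest.fixture
def fast_model() -> ExchangeModel:
    """Fast-exchange condition: one averaged line, CPMG-visible rates."""
    return ExchangeModel(p_E=0.05, k_ex=5800.0, omega_G=0.0, omega_E=940.0,
                         R1_G=1.0, R1_E=1.0, R2_G=105.0, R2_E=105.0)


def random_models(n: int, seed: int = 1234) -> list[ExchangeModel]:
    """Seeded random two-site models spanning slow to fast exchange."""
    rng = np.random.default_rng(seed)
    models = []
    for _ in range(n):
        models.append(ExchangeModel(
            p_E=rng.uniform(0.03, 0.45),
            k_ex=10 ** rng.uniform(1.0, 3.7),
            omega_G=rng.uniform(-300.0, 300.0),
            omega_E=rng.uniform(400.0, 1500.0),
            R1_G=rng.uniform(0.5, 2.0), R1_E=rng.uniform(0.5, 2.0),
            R2_G=rng.uniform(40.0, 200.0), R2_E=rng.uniform(40.0, 200.0),
            Gamma1_G=rng.uniform(0.0, 2.0), Gamma1_E=rng.uniform(0.0, 10.0),
            Gamma2_G=rng.uniform(0.0, 50.0), Gamma2_E=rng.uniform(0.0, 200.0),
        ))
    return models
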