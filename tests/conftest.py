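import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import feedeff as fe

settings.register_profile(
    "ci", derandomize=True, max_examples=50, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def reduced_study():
    """One small synthetic study (~190 cows × 10 weeks) shared across tests."""
    return fe.simulate_study(fe.SimConfig.reduced(seed=3))


@pytest.fixture(scope="session")
def reduced_ainv(reduced_study):
    return fe.a_inverse(reduced_study.pedigree)


@pytest.fixture
def trio():
    """Sire (1), dam (2) and their offspring (3), all non-inbred."""
    return fe.Pedigree.from_frame(
        pd.DataFrame(
            {
                "animal": [1, 2, 3],
                "sire": [0, 0, 1],
                "dam": [0, 0, 2],
                "birth_year": [2000, 2000, 2002],
            }
        )
    )


def random_pedigree(seed: int, n_target: int = 50) -> fe.Pedigree:
    """A random multi-generation pedigree of roughly n_target animals."""
    cfg = fe.SimConfig(
        n_founders=max(4, n_target // 5),
        n_generations=3,
        offspring_per_mating=2,
        seed=seed,
    )
    ped, _ = fe.simulate_pedigree(cfg)
    return ped
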