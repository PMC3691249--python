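import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import earlymet as em

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cfg() -> em.SimulationConfig:
    return em.SimulationConfig(
        n_features=400,
        n_informative=12,
        n_cases=45,
        n_ned=35,
        n_psa=35,
        effect_size=1.2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    expr, feats, annot = em.simulate.generate_cohort(small_cfg)
    return expr, feats, annot


@pytest.fixture(scope="session")
def small_tech(small_cfg, small_cohort):
    _, feats, _ = small_cohort
    return em.simulate.generate_technical_replicates(small_cfg, feats)


def toy_annotation(svi_counts=None, n=40, seed=0) -> pd.DataFrame:
    """Minimal clinical annotation; only SVI varies unless svi_counts is None.

    svi_counts = (a, b, c, d): SVI+ cases, SVI+ controls, SVI- cases,
    SVI- controls.
    """
    if svi_counts is None:
        svi_counts = (12, 6, 8, 14)
    a, b, c, d = svi_counts
    n = a + b + c + d
    is_case = np.array([True] * a + [False] * b + [True] * c + [False] * d)
    svi = np.array([True] * (a + b) + [False] * (c + d))
    return pd.DataFrame(
        {
            "is_case": is_case,
            "gleason": 7,
            "ppsa": 10.0,
            "svi": svi,
            "sm_pos": False,
            "ece": False,
            "node_pos": False,
        },
        index=[f"S{i:03d}" for i in range(n)],
    )
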