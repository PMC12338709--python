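import numpy as np
import pandas as pd
import pytest

import segquant as sq


@pytest.fixture(scope="session")
def quant_cfg():
    return sq.default_quant_config()


@pytest.fixture(scope="session")
def default_att(quant_cfg):
    att, acq, k = sq.attenuation_from_config(quant_cfg)
    return att, acq, k


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


def make_balanced_table(
    n_participants: int,
    rng: np.random.Generator,
    method_effects=(0.0, 0.0, 0.0),
    session_effect: float = 0.0,
    participant_sd: float = 1.0,
    noise_sd: float = 0.5,
    base: float = 10.0,
) -> pd.DataFrame:
    """Small balanced participant x method x session table for ANOVA tests."""
    methods = [f"M{j}" for j in range(len(method_effects))]
    u = rng.normal(0, participant_sd, n_participants)
    rows = []
    for i in range(n_participants):
        for j, meth in enumerate(methods):
            for s, sess in enumerate((1, 2)):
                rows.append({
                    "participant": f"P{i:02d}",
                    "method": meth,
                    "session": sess,
                    "y": base + method_effects[j] + session_effect * s
                         + u[i] + rng.normal(0, noise_sd),
                })
    return pd.DataFrame(rows)


@pytest.fixture
def balanced_table(rng):
    return make_balanced_table(5, rng, method_effects=(0.0, 0.5, 1.0))
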