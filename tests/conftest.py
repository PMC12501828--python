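import numpy as np
import pandas as pd
import pytest

from erncancel import synthetic
from erncancel.containers import EpochSet


def make_trials(outcomes, participant=0, block=0, rts=None, rds=None):
    """Build a minimal trial log from an outcome letter string.

    C = correct, E = commission error, O = omission, M = miscellaneous.
    """
    names = {"C": "correct", "E": "commission_error", "O": "omission",
             "M": "miscellaneous"}
    n = len(outcomes)
    out = [names[c] for c in outcomes]
    if rts is None:
        rts = [400.0 + 10 * i for i in range(n)]
    if rds is None:
        rds = [140.0] * n
    return pd.DataFrame({
        "participant": participant,
        "block": block,
        "trial": np.arange(n),
        "stimulus": "left",
        "response": ["" if o == "omission" else "left" for o in out],
        "outcome": out,
        "rt": [np.nan if o == "omission" else r for o, r in zip(out, rts)],
        "rd": [np.nan if o == "omission" else r for o, r in zip(out, rds)],
    })


@pytest.fixture(scope="session")
def small_cohort():
    """A reduced synthetic cohort shared across tests (8 participants)."""
    cfg = synthetic.GenConfig(n_participants=8, n_blocks=6, seed=11)
    return cfg, synthetic.gen_behavior(cfg)


@pytest.fixture()
def flat_epochs():
    """Tiny constant epochs for arithmetic checks."""
    times = np.arange(-100.0, 200.0, 2.0)
    data = np.full((4, 2, times.size), 5.0)
    return EpochSet(data, times, ["FCz", "Cz"], 500.0, "response_onset",
                    pd.DataFrame({"rd": [120.0, 130, 140, 150]}))
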