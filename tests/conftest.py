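import numpy as np
import pandas as pd
import pytest

from unseen.observer import CohortSpec, simulate_cohort
from unseen.trials import TRIAL_COLUMNS


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """Six synthetic participants on the full factorial design (default
    study-condition effects); shared across pipeline tests."""
    return simulate_cohort(6, CohortSpec(), seed=20240501)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(99)


def make_trials(rows: list[dict]) -> pd.DataFrame:
    """Build a minimal valid trial table from sparse row dicts."""
    defaults = dict(
        participant_id="P01",
        block_index=1,
        tms_mode="sham",
        tms_time="BIP_only",
        stimulus="absent",
        resp_arrow="no",
        resp_something="no",
        resp_direction="left",
        question_order=1,
        blink=False,
    )
    return pd.DataFrame([{**defaults, **r} for r in rows], columns=list(TRIAL_COLUMNS))
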