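import numpy as np
import pandas as pd
import pytest

from engagetraj import pipeline, preprocess, synth


@pytest.fixture(scope="session")
def icq_run():
    """Full pipeline on the three-group preset arm at its published size."""
    records, result = pipeline.run_preset_pipeline("icanquit-like", 1069, seed=1)
    return records, result


@pytest.fixture(scope="session")
def qg_run():
    """Full pipeline on the two-group preset arm at its published size."""
    records, result = pipeline.run_preset_pipeline("quitguide-like", 1064, seed=1)
    return records, result


def participant_table(records, matrix: preprocess.DailyEngagementMatrix) -> pd.DataFrame:
    """Participant table rows aligned with the retained matrix rows."""
    df = synth.participant_frame(records).set_index("participant_id")
    return df.loc[matrix.participant_ids].reset_index()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
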