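import numpy as np
import pytest

from turnover import PeptideObservation


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def make_obs(
    protein="P1",
    peptide="AAAK",
    t=0.0,
    ar=1.0,
    profile=0.95,
    regression=0.95,
):
    return PeptideObservation(
        protein_id=protein,
        peptide_seq=peptide,
        timepoint=t,
        area_ratio=ar,
        profile_score=profile,
        regression_score=regression,
    )


@pytest.fixture
def obs_factory():
    return make_obs
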