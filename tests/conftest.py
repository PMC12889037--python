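import numpy as np
import pytest

from wmkdiv.ensemble_stats import sample_frames
from wmkdiv.synthdata import make_family

FAMILY_SEED = 11  # the study family used across recovery tests


@pytest.fixture(scope="session")
def family():
    """Default synthetic family: reference + 5 type-I + 2 distant homologs."""
    return make_family(seed=FAMILY_SEED)


@pytest.fixture(scope="session")
def sampled_conformations(family):
    """Eight sampled conformations per homolog, flattened with labels."""
    confs, cids = [], []
    for rec in family.homolog_set:
        s = sample_frames(rec.ensemble)
        for fr in s.frames:
            confs.append(fr)
            cids.append(rec.id)
    return confs, cids


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
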