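import os
import sys

import numpy as np
import pytest

sys.path.insert(0, os.path.dirname(__file__))  # makes `import oracles` work

from mrfalign.msa_io import MSA
from mrfalign.node_potential import ScoreBundle
from mrfalign._dp import make_transitions


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_msa():
    return MSA(
        sequences=["ACDEF", "ACDEF", "ACDFF"],
        ids=["a", "b", "c"],
    )


def random_bundle(nT, nS, rng, trans_scale=0.0):
    """Random finite node scores for DP tests."""
    bias = rng.normal(0.0, trans_scale, size=(3, 3)) if trans_scale else None
    return ScoreBundle(
        match=rng.normal(0.0, 1.0, size=(nT, nS)),
        ins_t=rng.normal(0.0, 1.0, size=nT),
        ins_s=rng.normal(0.0, 1.0, size=nS),
        trans=make_transitions(bias),
    )


@pytest.fixture
def make_bundle():
    return random_bundle
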