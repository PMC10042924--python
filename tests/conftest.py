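"""Shared fixtures: deterministic noiseless synthetic talkers and word pairs."""

import numpy as np
import pytest

from clearspeech.synthetic import WORDS, make_talker, synth_trajectory
from clearspeech.trajectory import CLEAR, PLAIN


def noiseless_talker(index=0, seed=1, **overrides):
    """A talker with zero landmark jitter and exact (un-jittered) gains."""
    overrides.setdefault("jitter_sigma", 0.0)
    return make_talker(index, seed, idiosyncrasy_sd=0.0, **overrides)


@pytest.fixture
def talker():
    return noiseless_talker()


@pytest.fixture
def pair(talker):
    """Noiseless plain/clear trajectory pair for the word 'cod'."""
    plain = synth_trajectory(talker, "cod", PLAIN)
    clear = synth_trajectory(talker, "cod", CLEAR)
    return plain, clear


@pytest.fixture
def rng():
    return np.random.default_rng(20240601)


@pytest.fixture
def word_specs():
    return WORDS
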