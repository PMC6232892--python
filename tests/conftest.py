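"""Shared fixtures: canonical vocabularies and small simulated sessions."""

import numpy as np
import pytest

from myotrain.classify import fit_lda
from myotrain.core import build_standard_sets
from myotrain.signal import FeatureConfig, apply_filter, extract_features
from myotrain.simulate import SimConfig, default_profile, synth_session


@pytest.fixture(scope="session")
def standard_sets():
    return build_standard_sets()


@pytest.fixture(scope="session")
def basic_set(standard_sets):
    return standard_sets["BASIC"]


@pytest.fixture(scope="session")
def passive_set(standard_sets):
    return standard_sets["PASSIVE11"]


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def basic_session():
    """One well-separated active training session on the Basic set."""
    sets = build_standard_sets()
    profile = default_profile(6, 8, separation=3.0, seed=1)
    cfg = SimConfig(profile, seed=2)
    rec, labels, schedule = synth_session(cfg, sets["BASIC"])
    return cfg, rec, labels, schedule


@pytest.fixture(scope="session")
def basic_model(basic_session):
    """LDA decoder trained on the well-separated Basic session."""
    _, rec, _, schedule = basic_session
    feats = extract_features(apply_filter(rec), schedule, FeatureConfig())
    return fit_lda(feats)
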