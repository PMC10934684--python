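"""Shared fixtures: small synthetic recordings generated at test time."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from gaitwave.synthetic_data import (ArtifactModel, EffectSpec, GaitModel,
                                     generate_subject)

warnings.filterwarnings("ignore", message=".*ICA may be unstable.*")


@pytest.fixture(scope="session")
def short_subject():
    """A 60 s walking recording with all artifact sources, ~35 strides."""
    gait = GaitModel(stride_rate=105.0 / 180.0, stride_cv=0.02, duration=60.0)
    return generate_subject(gait, ArtifactModel(), EffectSpec.null(),
                            "TsSC", seed=11)


@pytest.fixture(scope="session")
def clean_subject():
    """A noise-free, artifact-free 60 s recording (gait component only)."""
    gait = GaitModel(stride_rate=1.0, stride_cv=0.0, duration=60.0)
    return generate_subject(gait, ArtifactModel.silent(), EffectSpec.null(),
                            "OsSC", seed=5, background_noise_sd=0.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
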