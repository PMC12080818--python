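"""Shared fixtures."""

from __future__ import annotations

import numpy as np
import pytest

from fhcdsr import SceneSpec, generate_scene


@pytest.fixture(scope="session")
def standard_scene():
    """The package's standard benchmark scene (fixed seed)."""
    return generate_scene(SceneSpec())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
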