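"""Shared fixtures: small synthetic scans reused across test modules.

Everything is generated at test time from the simulator; session scope
keeps the more expensive preprocessing runs to one apiece.
"""

from __future__ import annotations

import numpy as np
import pytest

from thzburn.pipeline import (
    PipelineConfig,
    build_study,
    burn_records,
    preprocess_study,
    tiny_config,
)
from thzburn.simulate import (
    BurnSite,
    DebyeParams,
    PhantomSpec,
    ScanConfig,
    WindowSpec,
    synth_scan,
)


@pytest.fixture(scope="session")
def window():
    return WindowSpec()


@pytest.fixture(scope="session")
def debye():
    return DebyeParams()


@pytest.fixture(scope="session")
def noiseless_cube(window, debye):
    """3x3 noiseless, jitter-free scan of uniform mid-severity skin."""
    cfg = ScanConfig(nx=3, ny=3, noise_rms=0.0, scatter_jitter=0.0)
    phantom = PhantomSpec(burn_sites=(BurnSite((1.5, 1.5), 3.0, 50.0),))
    return synth_scan(phantom, cfg, window, debye)


@pytest.fixture(scope="session")
def noisy_cube(window, debye):
    """2x2 scan with the default 20-average noise model, fixed seed."""
    cfg = ScanConfig(nx=2, ny=2, seed=7)
    phantom = PhantomSpec(burn_sites=(BurnSite((1.0, 1.0), 1.5, 50.0),))
    return synth_scan(phantom, cfg, window, debye)


@pytest.fixture(scope="session")
def tiny_burns():
    """The tiny study (three 9x9 single-burn scans) preprocessed into
    classifier-stage records, plus its pipeline config."""
    cfg = tiny_config()
    cubes = build_study(cfg)
    pairs = preprocess_study(cubes, cfg)
    recs = burn_records(cubes, [sp for _, sp in pairs], cfg)
    return cfg, cubes, recs
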