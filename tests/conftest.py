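"""Shared fixtures: seeded generators and small noiseless datasets."""

import dataclasses

import numpy as np
import pytest

import polyhybrid as ph


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture(scope="session")
def noiseless_maize():
    """Deterministic selfing-series table (theory means, zero noise)."""
    design = dataclasses.replace(ph.MaizeDesign(), noise_sd=0.0)
    return ph.gen_maize_dataset(design)


@pytest.fixture(scope="session")
def noiseless_rye():
    """Deterministic two-ploidy panel (theory means, all 141 classes)."""
    design = dataclasses.replace(
        ph.RyeDesign(), noise_sd=0.0, drop_missing_f1=False
    )
    return ph.gen_rye_dataset(design)


@pytest.fixture(scope="session")
def noisy_maize():
    """One simulated selfing-series dataset at the default conditions."""
    return ph.gen_maize_dataset(seed=1234)


@pytest.fixture(scope="session")
def noisy_rye():
    """One simulated panel dataset at the default conditions."""
    return ph.gen_rye_dataset(seed=1234)
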