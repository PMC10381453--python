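"""Shared fixtures: synthetic studies at the reference design, preprocessed
block sets, and a small random-matrix helper.  All randomness is seeded."""

import numpy as np
import pytest

import cartifuse as cf


@pytest.fixture(scope="session")
def strong_study():
    """Reference-size study with a large planted class effect (seed 1)."""
    return cf.generate_study(cf.strong_config(seed=1))


@pytest.fixture(scope="session")
def null_study():
    """Reference-size study with no class effect anywhere (seed 1)."""
    return cf.generate_study(cf.null_config(seed=1))


@pytest.fixture(scope="session")
def strong_prepared(strong_study):
    return cf.prepare_blocks(
        strong_study.blocks, strong_study.design, cf.REFERENCE_SPECS
    )


@pytest.fixture(scope="session")
def null_prepared(null_study):
    return cf.prepare_blocks(null_study.blocks, null_study.design, cf.REFERENCE_SPECS)


@pytest.fixture(scope="session")
def small_config():
    """Tiny but structurally complete study for fast orchestration tests."""
    return cf.SynthConfig(
        n_joints=4,
        samples_per_joint_per_class=5,
        replicates_per_sample=2,
        rng_seed=7,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_block(mat, axis=None, modality="X"):
    mat = np.atleast_2d(np.asarray(mat, float))
    axis = np.arange(mat.shape[1], dtype=float) if axis is None else np.asarray(axis, float)
    keys = [(f"s{i}", 0) for i in range(mat.shape[0])]
    return cf.SpectralBlock(modality=modality, axis=axis, intensities=mat, row_keys=keys)
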