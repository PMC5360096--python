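"""Shared fixtures: a space config and small cached datasets.

Datasets and trained models used by several test modules are generated
once per session at reduced size so the whole suite stays fast.
"""

import numpy as np
import pytest

from gainfields import SpaceConfig, generate_dataset


@pytest.fixture(scope="session")
def cfg():
    return SpaceConfig()


@pytest.fixture(scope="session")
def tiny_dataset(cfg):
    """Very small balanced dataset (task A) for fast training tests."""
    return generate_dataset(cfg, task="no_transformation", seed=7,
                            train_size=600, test_size=300,
                            patterns_per_target=40)


@pytest.fixture(scope="session")
def tiny_dataset_b(cfg):
    """Very small task-B dataset (motor program in the input)."""
    return generate_dataset(cfg, task="with_transformation", seed=7,
                            train_size=600, test_size=300,
                            patterns_per_target=40)
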