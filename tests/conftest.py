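"""Shared fixtures: the five example configurations, synthesized once.

Tests that mutate a dataset must work on ``dataset.copy()``; the session
fixtures are shared.
"""
from dataclasses import replace

import pytest

from aslbids import EXAMPLE_NAMES, build_field_registry, example_plan, synthesize_dataset


@pytest.fixture(scope="session")
def registry():
    return build_field_registry()


@pytest.fixture(scope="session")
def fixtures():
    """name -> (dataset, ground_truth) for the five example plans (default noise)."""
    return {name: synthesize_dataset(example_plan(name)) for name in EXAMPLE_NAMES}


@pytest.fixture(scope="session")
def noise_free():
    """name -> (dataset, ground_truth) with noise switched off."""
    return {
        name: synthesize_dataset(replace(example_plan(name), noise_sd=0.0))
        for name in EXAMPLE_NAMES
    }
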