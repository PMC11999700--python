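"""Shared fixtures: session-scoped synthetic tissues so expensive generation
and windowing run once."""

import numpy as np
import pytest

from insulitis import islets as isl
from insulitis import synthetic as syn


def small_config(**kw):
    """A compact tissue (one donor per group, ~800x800 µm) for fast tests."""
    kw.setdefault("tissue_size", (900.0, 900.0))
    kw.setdefault("islets_per_donor", 2)
    kw.setdefault("n_lobules", 4)
    kw.setdefault("islet_radius_log_mean", np.log(40.0))
    kw.setdefault("aggregates_per_donor", 1)
    kw.setdefault("far_patches_per_donor", 1)
    kw.setdefault("rng_seed", 5)
    return syn.SyntheticConfig(**kw)


@pytest.fixture(scope="session")
def small_tissue():
    return syn.generate_tissue(small_config())


@pytest.fixture(scope="session")
def default_tissue():
    return syn.generate_tissue(syn.SyntheticConfig(rng_seed=11))


@pytest.fixture(scope="session")
def default_windows(default_tissue):
    table, _ = default_tissue
    return isl.compute_windows(table)


@pytest.fixture(scope="session")
def default_islets(default_tissue, default_windows):
    table, _ = default_tissue
    region = isl.detect_islet_region(default_windows, seed=0)
    return isl.extract_islets(table, region)
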