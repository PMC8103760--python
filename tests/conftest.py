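"""Shared fixtures: a small synthetic run reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from umivar.pileup import load_reference_codes
from umivar.pipeline import run_pipeline
from umivar.synth import SynthConfig, generate_library, generate_reference


SMALL_CONFIG = dict(
    seed=11,
    n_genes=40,
    n_cells=60,
    n_ambient_barcodes=40,
    molecules_per_cell=40.0,
    n_hom_snvs=6,
    n_het_snvs=6,
    n_edit_clusters=1,
)


@pytest.fixture(scope="session")
def small_config():
    return SynthConfig(**SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_reference(small_config):
    return generate_reference(small_config)


@pytest.fixture(scope="session")
def small_library(small_config, small_reference):
    reads, truth = generate_library(small_reference, small_config)
    return reads, truth


@pytest.fixture(scope="session")
def small_index(small_reference):
    return small_reference.index()


@pytest.fixture(scope="session")
def small_codes(small_reference):
    return load_reference_codes(small_reference.contigs)


@pytest.fixture(scope="session")
def small_result(small_library, small_index, small_codes):
    reads, truth = small_library
    return run_pipeline(reads, small_index, small_codes, set(truth.whitelist))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
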