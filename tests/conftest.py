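"""Shared fixtures: synthetic datasets and pipeline runs reused across tests.

Session-scoped so the rendering and pipeline cost is paid once; tests
treat these as read-only.
"""

from __future__ import annotations

import numpy as np
import pytest

from chromatrace.config import load_config
from chromatrace.pipeline import run_pipeline
from chromatrace.simulator import (
    SimulationParams,
    build_ground_truth,
    simulate_dataset,
)


def _tune(config):
    # block sizes matched to the synthetic FOV (a few fiducials per block)
    config.registration.block_size_2d = 64
    config.registration.block_size_3d = (0, 64, 64)
    config.runtime.seed = 42
    return config


@pytest.fixture(scope="session")
def tiny_params():
    """A minimal but complete acquisition: 6 nuclei, 5 barcodes, 12 beads."""
    return SimulationParams(
        n_nuclei=6, n_barcodes=5, fov_shape=(20, 192, 192),
        n_fiducials=12, seed=3,
    )


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory, tiny_params):
    outdir = tmp_path_factory.mktemp("tiny_data")
    truth = simulate_dataset(tiny_params, outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def tiny_config(tiny_dataset):
    data_dir, _ = tiny_dataset
    return _tune(load_config(data_dir / "parameters.json"))


@pytest.fixture(scope="session")
def tiny_run3d(tiny_dataset, tiny_config, tmp_path_factory):
    data_dir, truth = tiny_dataset
    outdir = tmp_path_factory.mktemp("tiny_out3d")
    manifest = run_pipeline(tiny_config, data_dir, outdir, mode="3d", workers=1)
    return outdir, truth, manifest


@pytest.fixture(scope="session")
def small_params():
    """The reference acquisition: 20 traces, 10 barcodes, SNR well above 8."""
    return SimulationParams(seed=1)


@pytest.fixture(scope="session")
def small_truth(small_params):
    return build_ground_truth(small_params)


@pytest.fixture(scope="session")
def small_dataset(tmp_path_factory, small_params):
    outdir = tmp_path_factory.mktemp("small_data")
    truth = simulate_dataset(small_params, outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def small_config(small_dataset):
    data_dir, _ = small_dataset
    return _tune(load_config(data_dir / "parameters.json"))


@pytest.fixture(scope="session")
def small_run3d(small_dataset, small_config, tmp_path_factory):
    data_dir, truth = small_dataset
    outdir = tmp_path_factory.mktemp("small_out3d")
    manifest = run_pipeline(small_config, data_dir, outdir, mode="3d", workers=1)
    return outdir, truth, manifest


@pytest.fixture(scope="session")
def small_run2d(small_dataset, small_config, tmp_path_factory):
    data_dir, truth = small_dataset
    outdir = tmp_path_factory.mktemp("small_out2d")
    manifest = run_pipeline(small_config, data_dir, outdir, mode="2d", workers=1)
    return outdir, truth, manifest


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
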