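"""Shared fixtures: montage/timing singletons and one full default run.

The expensive artefacts (a full default cohort run and its spectra) are
session-scoped and shared across test modules; unit tests build their own
tiny inputs instead.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from rhythmtag.cohort import StimulusTiming, make_montage
from rhythmtag.io import read_dataset
from rhythmtag.pipeline import (
    RunConfig,
    cohort_spectra,
    preprocess_cohort,
    run_all,
)
from rhythmtag.preprocess import PreprocessConfig


@pytest.fixture(scope="session")
def montage():
    return make_montage()


@pytest.fixture(scope="session")
def timing():
    return StimulusTiming()


@pytest.fixture(scope="session")
def pre_config():
    return PreprocessConfig()


@pytest.fixture(scope="session")
def run_config():
    return RunConfig().with_seed(1)


@pytest.fixture(scope="session")
def default_run(run_config, tmp_path_factory):
    """One complete default run (seed 1): manifest plus output directory."""
    out_dir = tmp_path_factory.mktemp("default_run")
    manifest = run_all(run_config, out_dir)
    return manifest, out_dir


@pytest.fixture(scope="session")
def default_cohort(default_run):
    """The default cohort read back from the run's dataset container."""
    _, out_dir = default_run
    return read_dataset(out_dir / "dataset")


@pytest.fixture(scope="session")
def default_spectra(default_cohort, run_config):
    """Noise-subtracted spectra per subject x condition of the default run."""
    waveforms, epoch_means, _ = preprocess_cohort(
        default_cohort, run_config.preprocess
    )
    spectra = cohort_spectra(
        default_cohort, run_config.preprocess, run_config.spectral,
        waveforms=waveforms, epoch_means=epoch_means,
    )
    return spectra, waveforms


def read_run_csv(out_dir, name: str) -> pd.DataFrame:
    return pd.read_csv(out_dir / f"{name}.csv", comment="#")


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
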