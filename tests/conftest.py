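"""Shared fixtures: synthetic detectors and run files.

Two detector models are used throughout: the fixture-default 256×256
detector for end-to-end truth-recovery checks, and a small 32×32 variant
with the same noise structure for tests where frame size is irrelevant.
Expensive runs are generated once per session.
"""

import numpy as np
import pytest

from fxmon import (
    DetectorModel,
    RunRecipe,
    default_model,
    generate_dark_run,
    generate_diffraction_run,
)


@pytest.fixture(scope="session")
def model():
    """Fixture-default 256×256 detector."""
    return default_model()


@pytest.fixture(scope="session")
def small_model():
    """32×32 detector with the default noise structure (cheap tests)."""
    rng = np.random.default_rng(7)
    return DetectorModel(shape=(32, 32), pedestal=rng.uniform(90.0, 110.0, (32, 32)))


@pytest.fixture(scope="session")
def small_dark_run(small_model, tmp_path_factory):
    path = str(tmp_path_factory.mktemp("runs") / "dark_small.h5")
    generate_dark_run(small_model, RunRecipe(n_frames=60, seed=11), path)
    return path


@pytest.fixture(scope="session")
def small_diffraction_run(small_model, tmp_path_factory):
    """(path, truth) for a 32×32 diffraction run with 20% hits."""
    path = str(tmp_path_factory.mktemp("runs") / "diff_small.h5")
    recipe = RunRecipe(n_frames=50, hit_fraction=0.2, photons_per_hit_mean=40.0, seed=12)
    truth = generate_diffraction_run(small_model, recipe, path)
    return path, truth


@pytest.fixture(scope="session")
def small_dark_file(small_model, small_dark_run, tmp_path_factory):
    """Averaged dark image for the small model, via the dark pipeline."""
    from fxmon.backend import dark_pipeline_config, run_backend

    out = str(tmp_path_factory.mktemp("dark") / "dark_avg_small.h5")
    run_backend(dark_pipeline_config([small_dark_run], out), n_workers=1)
    return out


@pytest.fixture(scope="session")
def diffraction_run_1k(model, tmp_path_factory):
    """The standard end-to-end fixture: 1000 frames, 10% hits, seed 2."""
    path = str(tmp_path_factory.mktemp("runs") / "diff_1k.h5")
    recipe = RunRecipe(n_frames=1000, hit_fraction=0.1, seed=2)
    truth = generate_diffraction_run(model, recipe, path)
    return path, truth


@pytest.fixture(scope="session")
def dark_run_10k(model, tmp_path_factory):
    """10 000-frame dark run at fixture defaults, seed 1 (dark calibration)."""
    path = str(tmp_path_factory.mktemp("runs") / "dark_10k.h5")
    generate_dark_run(model, RunRecipe(n_frames=10000, seed=1), path)
    return path


@pytest.fixture(scope="session")
def dark_file_1k(model, tmp_path_factory):
    """Dark average from a 1000-frame default-model dark run (seed 21)."""
    from fxmon.backend import dark_pipeline_config, run_backend

    run = str(tmp_path_factory.mktemp("runs") / "dark_1k.h5")
    generate_dark_run(model, RunRecipe(n_frames=1000, seed=21), run)
    out = str(tmp_path_factory.mktemp("dark") / "dark_avg_1k.h5")
    run_backend(dark_pipeline_config([run], out), n_workers=1)
    return out
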