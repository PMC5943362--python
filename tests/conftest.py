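"""Shared fixtures: a tiny synthetic dataset and the desk-scale run.

The tiny dataset (small fields, few slices) keeps unit tests fast; the
desk-scale run executes the full pipeline (dataset generation, training,
evaluation, IQA baseline, closed-loop session) once per session and is
shared by the tests that check end-to-end behaviour.
"""

import numpy as np
import pytest

from zfocus.binning import make_bins
from zfocus.synth import DefocusModel, SceneConfig, generate_dataset
from zfocus.train import PRESETS, TrainConfig
from zfocus.zstack import split_dataset

#: small scene for fast tests: 128 px fields (~7.7 µm), 2-4 small cells
TINY_SCENE = SceneConfig(
    field_shape=(128, 128),
    n_cells_range=(2, 4),
    cell_radius_um=(1.2, 1.8),
    pillars=False,
    noise_sd=0.01,
)

#: matching fast training configuration (network input 25 px)
def tiny_train_config(**overrides):
    defaults = dict(
        batch_size=4,
        steps=30,
        crop=100,
        downsample_factor=4,
        seed=3,
        bins=make_bins(-4, 4, 1),
    )
    defaults.update(overrides)
    return TrainConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """Six 7-slice stacks (z = −3..+3 µm), split 80/20."""
    out = tmp_path_factory.mktemp("tiny_ds")
    manifest = generate_dataset(
        6, out, seed=42, scene_config=TINY_SCENE, n_slices=7, z_step_um=1.0
    )
    return split_dataset(manifest, 0.8, seed=7)


@pytest.fixture(scope="session")
def desk_run(tmp_path_factory):
    """The full desk-scale experiment (generation → training → eval → loop)."""
    from zfocus.experiments import run_desk_experiment

    work = tmp_path_factory.mktemp("desk")
    return run_desk_experiment(seed=11, work_dir=work)
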