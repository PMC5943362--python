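"""Desk-scale end-to-end experiment: the full pipeline on synthetic data.

The full-scale workflow (hundreds of real z-stacks, 100,000 optimization
steps) is GPU-scale; this module runs the same pipeline at a scale a single
CPU handles in minutes, using the synthetic generator as the data source:

1. generate 125 synthetic yeast-like stacks (31 slices, Δz = 1 µm,
   600×600 px fields) and split them 80/20 → 100 training / 25 test stacks;
2. train the CNN with the ``desk`` preset (256-px crops, 4× downsampling,
   41 bins over ±20 µm, batch 16, 2,000 Adam steps);
3. evaluate every slice of every test stack (775 held-out images);
4. build the global IQA profile from the training stacks and score the
   profile-inversion baseline on the same test slices (granting it the
   ground-truth side of focus and the per-stack maximum, the two external
   aids a profile method needs);
5. run a 500-tick closed-loop session in which the stage accumulates 40 µm
   of drift while the colony grows and the field slowly translates, with
   the trained CNN as the controller's estimator (deadband ±1 µm, gain 1).

Every stage derives its randomness from the single ``seed`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .binning import make_bins
from .control import (
    ControllerConfig,
    FocusLog,
    SceneSchedule,
    StageModel,
    simulate_session,
)
from .focus_metrics import build_global_profile, focus_score, infer_z_from_profile
from .infer_eval import CnnEstimator, ErrorStats, evaluate
from .model import Network
from .synth import SceneConfig, generate_dataset
from .train import PRESETS, TrainConfig, train_model
from .zstack import DatasetManifest, read_zstack, split_dataset

__all__ = ["DeskRun", "run_desk_experiment", "evaluate_iqa_baseline",
           "N_STACKS", "TRAIN_FRACTION", "SESSION_TICKS", "DRIFT_TOTAL_UM"]

N_STACKS = 125
TRAIN_FRACTION = 0.8
SESSION_TICKS = 500
DRIFT_TOTAL_UM = 40.0
WALK_SD_UM = 0.02


@dataclass
class DeskRun:
    manifest: DatasetManifest
    net: Network
    train_log: pd.DataFrame
    cnn_stats: ErrorStats
    cnn_errors_z: np.ndarray       # annotated z of each scored test slice
    iqa_stats: ErrorStats
    focus_log: FocusLog

    @property
    def max_post_correction_um(self) -> float:
        post = self.focus_log.corrections["post_estimate_um"].abs()
        return float(post.max()) if len(post) else 0.0


def evaluate_iqa_baseline(
    train_manifest: DatasetManifest,
    test_manifest: DatasetManifest,
    method: str = "iqa_detail",
) -> ErrorStats:
    """Profile-inversion error on a test split, with the two external aids.

    The global profile is built from the training stacks.  Per test stack
    the per-stack maximum score normalizes the profile lookup, and the side
    of focus is taken from ground truth; errors are measured relative to the
    stack's own IQA-estimated focal plane (its peak-score slice).
    """
    profile = build_global_profile(
        (read_zstack(p) for p in train_manifest.paths), method
    )
    errors = []
    for path in test_manifest.paths:
        stack = read_zstack(path)
        scores = np.array(
            [focus_score(stack.data[i], method) for i in range(stack.n_slices)]
        )
        stack_max = float(scores.max())
        z_peak = float(stack.z_positions[int(np.argmax(scores))])
        for i, z in enumerate(stack.z_positions):
            z_rel = float(z) - z_peak
            side = "above" if z_rel >= 0 else "below"
            est = infer_z_from_profile(
                stack.data[i], profile, side, stack_max
            )
            errors.append(est.z_um - z_rel)
    return ErrorStats(np.asarray(errors), (1.0, 2.0))


def run_desk_experiment(
    seed: int,
    work_dir,
    progress: bool = False,
) -> DeskRun:
    """Run the full desk-scale pipeline; reproducible from ``seed``."""
    work_dir = Path(work_dir)
    seeds = np.random.SeedSequence(seed).spawn(4)
    data_seed, split_seed, train_seed, session_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in seeds
    )

    manifest = generate_dataset(
        N_STACKS, work_dir / "stacks", seed=data_seed, scene_config=SceneConfig()
    )
    manifest = split_dataset(manifest, TRAIN_FRACTION, split_seed)

    bins = make_bins(-20, 20, 1)
    train_config = TrainConfig(seed=train_seed, bins=bins, **PRESETS["desk"])
    net, train_log = train_model(manifest, train_config, progress=progress)

    estimator = CnnEstimator(net)
    test_split = manifest.subset("test")
    cnn_stats = evaluate(estimator, test_split, (1.0, 2.0))
    z_annot = []
    for path in test_split.paths:
        z_annot.extend(read_zstack(path).z_positions)
    iqa_stats = evaluate_iqa_baseline(manifest.subset("train"), test_split)

    stage = StageModel.from_total_drift(DRIFT_TOTAL_UM, SESSION_TICKS, WALK_SD_UM)
    controller = ControllerConfig(setpoint_um=0.0, deadband_um=1.0, gain=1.0)
    schedule = SceneSchedule(n_cells_final=100, translate_px_per_tick=(0.05, 0.03))
    focus_log = simulate_session(
        stage, controller, estimator, SESSION_TICKS, seed=session_seed,
        schedule=schedule,
    )
    return DeskRun(
        manifest=manifest,
        net=net,
        train_log=train_log,
        cnn_stats=cnn_stats,
        cnn_errors_z=np.asarray(z_annot),
        iqa_stats=iqa_stats,
        focus_log=focus_log,
    )
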