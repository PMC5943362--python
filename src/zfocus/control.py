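"""Closed-loop focus maintenance on a simulated drifting stage.

The simulator abstracts a long acquisition into discrete ticks.  At each
tick the stage drifts (a deterministic trend plus a seeded random walk,
emulating thermal expansion), an image of the scene is rendered at the
current true defocus, an estimator (the CNN, an oracle, or a profile
baseline) produces a defocus estimate, and a deadband controller corrects
the objective only when the estimate leaves the tolerance band around the
user-locked setpoint:

    correction = −gain × (estimate − setpoint)   if |estimate − setpoint| > deadband

The default deadband is ±1 µm, the band the real-time controller maintains
around the locked focal position; the default gain of 1 moves the objective
by the full estimated error.  Everything is logged per tick, and the exact
bookkeeping identity

    final defocus = initial + Σ drift − Σ corrections

is asserted on every session.  An optional scene schedule grows the colony
and translates the field over the session, emulating a growth experiment in
which cells divide and drift through the frame.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .infer_eval import bimodal
from .synth import DefocusModel, SceneConfig, SceneRenderer, SceneSpec, generate_scene

__all__ = [
    "StageModel",
    "ControllerConfig",
    "SceneSchedule",
    "FocusLog",
    "step_stage",
    "control_step",
    "simulate_session",
]

LOG_COLUMNS = [
    "tick", "stage_position_um", "true_defocus_um", "estimate_um",
    "correction_um", "post_estimate_um", "bimodal",
]


@dataclass(frozen=True)
class StageModel:
    """Axial stage drift: linear trend plus a seeded random walk."""

    position_um: float = 0.0
    trend_um_per_tick: float = 0.0
    walk_sd_um: float = 0.0

    @classmethod
    def from_total_drift(cls, total_um: float, n_ticks: int,
                         walk_sd_um: float = 0.0) -> "StageModel":
        """Stage whose trend accumulates ``total_um`` over ``n_ticks``."""
        return cls(0.0, total_um / n_ticks, walk_sd_um)


def step_stage(stage: StageModel, rng: np.random.Generator) -> StageModel:
    """Advance the stage by one tick of drift."""
    inc = stage.trend_um_per_tick
    if stage.walk_sd_um > 0:
        inc += float(rng.normal(0.0, stage.walk_sd_um))
    return dataclasses.replace(stage, position_um=stage.position_um + inc)


@dataclass(frozen=True)
class ControllerConfig:
    setpoint_um: float = 0.0
    deadband_um: float = 1.0
    gain: float = 1.0
    update_period: int = 1   # ticks between estimates

    def __post_init__(self):
        if self.deadband_um <= 0:
            raise ValueError("deadband must be positive")
        if not 0 < self.gain <= 1:
            raise ValueError("gain must be in (0, 1]")


@dataclass(frozen=True)
class SceneSchedule:
    """Slow scene evolution over a session (growth + lateral drift)."""

    n_cells_final: int | None = None     # linear ramp from the initial count
    translate_px_per_tick: tuple[float, float] = (0.0, 0.0)


@dataclass
class _LoopState:
    stage: StageModel
    true_defocus_um: float
    drift_sum: float = 0.0
    correction_sum: float = 0.0


class FocusLog:
    """Per-tick session records with the drift/correction bookkeeping."""

    def __init__(self, table: pd.DataFrame, initial_defocus_um: float):
        self.table = table
        self.initial_defocus_um = initial_defocus_um

    def check_conservation(self, atol: float = 1e-9) -> None:
        """final defocus == initial + Σ drift − Σ corrections, exactly."""
        total_drift = self.table["_drift_increment_um"].sum()
        total_corr = self.table["correction_um"].sum()
        final = self.table["true_defocus_um"].iloc[-1]
        expected = self.initial_defocus_um + total_drift - total_corr
        if abs(final - expected) > atol:
            raise AssertionError(
                f"bookkeeping violated: final defocus {final} != {expected}"
            )

    @property
    def corrections(self) -> pd.DataFrame:
        return self.table[self.table["correction_um"] != 0.0]

    def save(self, path) -> None:
        cols = [c for c in self.table.columns if not c.startswith("_")]
        self.table[cols].to_csv(path, sep="\t", index=False)


def _estimate(estimator, image, true_z: float):
    """Run an estimator defensively; returns (estimate, probs, failed).

    Reference estimators declaring ``wants_true_z`` (oracles) receive the
    true defocus; real estimators only see the image.
    """
    try:
        if getattr(estimator, "wants_true_z", False):
            z = estimator(image, true_z)
        else:
            z = estimator(image)
    except Exception:
        return None, None, True
    probs = getattr(estimator, "last_probs", None)
    return float(z), probs, False


def control_step(
    state: _LoopState,
    controller: ControllerConfig,
    renderer: SceneRenderer,
    estimator,
    rng: np.random.Generator,
    tick: int,
    shift_px: tuple[float, float] = (0.0, 0.0),
) -> dict:
    """One tick: drift → render → estimate → (maybe) correct → log.

    A failed estimate produces no correction that tick (fail-safe hold).
    The post-correction estimate is re-measured from a freshly rendered
    image whenever a correction was applied.
    """
    new_stage = step_stage(state.stage, rng)
    drift_inc = new_stage.position_um - state.stage.position_um
    state.stage = new_stage
    state.true_defocus_um += drift_inc
    state.drift_sum += drift_inc

    image = renderer.render(state.true_defocus_um, rng, shift_px)
    estimate, probs, failed = _estimate(estimator, image, state.true_defocus_um)
    correction = 0.0
    post_estimate = np.nan
    flag = False
    if not failed:
        flag = bimodal(probs) if probs is not None else False
        error = estimate - controller.setpoint_um
        if abs(error) > controller.deadband_um:
            correction = controller.gain * error
            state.true_defocus_um -= correction
            state.correction_sum += correction
            post_image = renderer.render(state.true_defocus_um, rng, shift_px)
            post_z, _, post_failed = _estimate(
                estimator, post_image, state.true_defocus_um
            )
            post_estimate = np.nan if post_failed else post_z
    return {
        "tick": tick,
        "stage_position_um": state.stage.position_um,
        "true_defocus_um": state.true_defocus_um,
        "estimate_um": np.nan if failed else estimate,
        "correction_um": correction,
        "post_estimate_um": post_estimate,
        "bimodal": flag,
        "_drift_increment_um": drift_inc,
    }


def simulate_session(
    stage: StageModel,
    controller: ControllerConfig,
    estimator,
    duration_ticks: int,
    seed: int,
    scene_config: SceneConfig | None = None,
    scene: SceneSpec | None = None,
    defocus_model: DefocusModel | None = None,
    schedule: SceneSchedule | None = None,
    initial_defocus_um: float = 0.0,
) -> FocusLog:
    """Run a full closed-loop session; deterministic given ``seed``.

    The scene may be supplied directly or drawn from ``scene_config``; the
    optional schedule adds cells linearly up to ``n_cells_final`` and
    translates the field each tick.
    """
    if duration_ticks < 1:
        raise ValueError("duration must be >= 1 tick")
    seeds = np.random.SeedSequence(seed).spawn(3)
    scene_rng = np.random.default_rng(seeds[0])
    loop_rng = np.random.default_rng(seeds[1])
    growth_rng = np.random.default_rng(seeds[2])
    config = scene_config or SceneConfig()
    if scene is None:
        scene = generate_scene(config, scene_rng)
    # the loop must render whatever defocus the system reaches (a misbehaving
    # estimator can drive the stage far out), so lift the validated-range cap
    model = defocus_model or DefocusModel(z_range_um=float("inf"))
    renderer = SceneRenderer(scene, model)
    schedule = schedule or SceneSchedule()

    n0 = scene.n_cells
    n_final = schedule.n_cells_final or n0
    state = _LoopState(stage=stage, true_defocus_um=initial_defocus_um)
    rows = []
    shift = np.array([0.0, 0.0])
    for tick in range(duration_ticks):
        target_n = n0 + round((n_final - n0) * (tick + 1) / duration_ticks)
        if target_n > scene.n_cells:
            h, w = scene.field_shape
            n_new = target_n - scene.n_cells
            new_xy = np.column_stack(
                [growth_rng.uniform(0, w, n_new), growth_rng.uniform(0, h, n_new)]
            )
            new_r = growth_rng.uniform(*config.cell_radius_um, n_new)
            new_plane = (growth_rng.random(n_new) < config.ceiling_fraction)
            scene = scene.with_cells(
                np.vstack([scene.cells_xy, new_xy]),
                np.concatenate([scene.cells_radius_um, new_r]),
                np.concatenate([scene.cells_plane, new_plane.astype(int)]),
            )
            renderer = SceneRenderer(scene, model)
        shift += schedule.translate_px_per_tick
        rows.append(
            control_step(state, controller, renderer, estimator, loop_rng,
                         tick, tuple(shift))
        )
    log = FocusLog(pd.DataFrame(rows, columns=LOG_COLUMNS + ["_drift_increment_um"]),
                   initial_defocus_um)
    log.check_conservation()
    return log
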