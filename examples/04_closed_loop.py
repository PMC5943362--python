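"""Closed-loop focus maintenance on a drifting stage.

Runs a short simulated session in which the stage drifts axially while a
deadband controller, driven here by a perfect (oracle) estimator, corrects
the objective whenever the estimate leaves the ±1 µm band around the
setpoint.  Swap in a trained CNN via zfocus.infer_eval.CnnEstimator for the
full experiment (see zfocus.experiments.run_desk_experiment).
"""

from zfocus.control import ControllerConfig, StageModel, simulate_session
from zfocus.infer_eval import TrueZOracle
from zfocus.synth import SceneConfig

stage = StageModel.from_total_drift(total_um=8.0, n_ticks=80, walk_sd_um=0.02)
controller = ControllerConfig(setpoint_um=0.0, deadband_um=1.0, gain=1.0)
scene = SceneConfig(field_shape=(300, 300), n_cells_range=(8, 15))

log = simulate_session(stage, controller, TrueZOracle(), duration_ticks=80,
                       seed=4, scene_config=scene)

t = log.table
print(t[["tick", "stage_position_um", "true_defocus_um", "estimate_um",
         "correction_um"]].iloc[::10].to_string(index=False))
print(f"\n{len(log.corrections)} corrections, "
      f"total {log.corrections['correction_um'].sum():+.2f} µm "
      f"against {t['_drift_increment_um'].sum():+.2f} µm of drift")
print(f"max |true defocus| during session: "
      f"{t['true_defocus_um'].abs().max():.2f} µm")
# With gain 1 each correction cancels the estimated error exactly, so the
# true defocus never exceeds the deadband plus one tick of drift.
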