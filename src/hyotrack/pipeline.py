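"""End-to-end tracking pipeline: segment -> extract objects -> trajectory.

Mirrors the intended clinical flow: per-frame pixel classification by the
segmentation network, object-state extraction, the all-three-objects frame
filter, coin-calibrated kinematics, and (when ground-truth masks are given)
the evaluation suite.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np

from . import evaluation, extraction, io, kinematics, training


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        self.stage = stage
        super().__init__(f"[{stage}] {err}")


@dataclass
class PipelineResult:
    states: List[Dict[int, extraction.ObjectState]]
    trajectory: kinematics.Trajectory
    excursion: kinematics.ExcursionSummary
    metrics: Optional[dict] = None


def run_pipeline(model, frames: np.ndarray, truth_masks: Optional[np.ndarray] = None,
                 per_frame_scale: bool = False, largest_component: bool = False,
                 ) -> PipelineResult:
    """Run predict -> extract_states -> build_trajectory -> excursion.

    Errors propagate with the failing stage's name attached.
    """
    try:
        probs = training.predict(model, frames)
    except Exception as e:
        raise StageError("predict", e) from e
    try:
        states = extraction.extract_states(probs, largest_component=largest_component)
    except Exception as e:
        raise StageError("extract_states", e) from e
    try:
        traj = kinematics.build_trajectory(states, per_frame_scale=per_frame_scale)
        summary = kinematics.excursion(traj)
    except Exception as e:
        raise StageError("kinematics", e) from e

    metrics = None
    if truth_masks is not None:
        try:
            pred_masks = np.stack([extraction.classify_pixels(p) for p in probs])
            metrics = {"pixel": evaluation.pixel_metrics(pred_masks, truth_masks)}
            scores = 1.0 - probs[..., 0]  # any-object score per pixel
            positives = truth_masks > 0
            if positives.any() and not positives.all():
                metrics["roc_auc"] = evaluation.roc_auc(scores, positives)
        except Exception as e:
            raise StageError("evaluation", e) from e
    return PipelineResult(states=states, trajectory=traj, excursion=summary,
                          metrics=metrics)


def save_result(result: PipelineResult, out_dir, seed: Optional[int] = None,
                config_obj=None) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    io.write_trajectory_csv(result.trajectory, out_dir / "trajectory.csv",
                            seed=seed, config_obj=config_obj)
    io.write_states_csv(result.states, out_dir / "states.csv", seed=seed)
    payload = {"excursion": io.excursion_to_dict(result.excursion)}
    if result.metrics is not None:
        payload["metrics"] = result.metrics
    io.write_json(payload, out_dir / "summary.json", seed=seed, config_obj=config_obj)
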