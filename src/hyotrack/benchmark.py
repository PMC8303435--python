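"""Desk-scale end-to-end benchmark on the synthetic phantom.

Trains the reduced BiFPN-U-Net(T) profile (96x96 input, encoder widths
divided by four, batch 8, lr 0.003125 by the linear-scaling rule) on a small
set of easy phantom clips, then measures on a held-out clip everything the
full protocol measures: per-class Dice, pixel accuracy, ROC-AUC,
bounding-box mAP at IoU 0.5, the tracked excursion against the generator's
ground truth, trajectory RMSE, and hyoid detection under mandible occlusion.

All randomness derives from a single seed, so the benchmark is reproducible;
problem sizes (192 training frames, a 12-epoch budget) are the package's
CPU-scale defaults and are configurable upward.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Tuple

import numpy as np

from . import evaluation, extraction, kinematics, training
from .extraction import LABEL_COIN, LABEL_HYOID, LABEL_SPINE, OBJECT_CLASSES
from .model import NetworkConfig, build_network
from .phantom import PhantomSpec, make_phantom

#: study conditions for the easy desk-scale clips
DESK_FRAME_SIZE = (96, 96)
DESK_COIN_DIAMETER_PX = 22.0
DESK_CLIP_FRAMES = 48
DESK_TRAIN_CLIPS = 4  # 192 training frames
DESK_EPOCHS = 12


def desk_clip_spec(seed: int, **overrides) -> PhantomSpec:
    """An 'easy' phantom clip: low noise, mild jitter, full swallow cycle."""
    base = dict(frame_count=DESK_CLIP_FRAMES, frame_size=DESK_FRAME_SIZE,
                coin_diameter_px=DESK_COIN_DIAMETER_PX, motion_period_frames=36,
                jitter_px=0.3, noise_sd=0.01, seed=seed)
    base.update(overrides)
    return PhantomSpec(**base)


@dataclass
class DeskBenchmark:
    model: object
    history: object
    metrics: Dict[str, float]
    pixel_metrics: Dict[str, Dict[str, float]]


def _boxes_for_ap(states, truth_states):
    dets = {c: [] for c in OBJECT_CLASSES}
    truths = {c: [] for c in OBJECT_CLASSES}
    for t, (st, ts) in enumerate(zip(states, truth_states)):
        for c in OBJECT_CLASSES:
            if st[c].present:
                dets[c].append((t, st[c].bbox, st[c].confidence))
            if ts[c].present:
                truths[c].append((t, ts[c].bbox))
    return dets, truths


def train_desk_model(seed: int, epochs: int = DESK_EPOCHS):
    """Train the reduced profile on easy clips (one of them occluded).

    Returns (model, history, held-out clip (frames, truth)).
    """
    clips = []
    for i in range(DESK_TRAIN_CLIPS + 1):
        spec = desk_clip_spec(seed=1000 * (seed % 1024) + i,
                              occluder_on=(i == DESK_TRAIN_CLIPS - 1))
        clips.append(make_phantom(spec))
    train_clips, test_clip = clips[:DESK_TRAIN_CLIPS], clips[-1]
    x = np.concatenate([c[0] for c in train_clips])[:, None]
    y = np.concatenate([c[1].label_masks for c in train_clips])
    # a short validation slice from the held-out clip steers early stopping
    xv = test_clip[0][:8][:, None]
    yv = test_clip[1].label_masks[:8]
    cfg = NetworkConfig.desk_scale(seed=seed % (2 ** 31), max_epochs=epochs,
                                   patience=min(20, epochs - 1))
    model = build_network(cfg)
    model, history = training.train(model, (x, y), (xv, yv), cfg)
    return model, history, test_clip


def evaluate_desk_model(model, test_clip) -> Tuple[Dict[str, float], Dict]:
    frames, truth = test_clip
    probs = training.predict(model, frames)
    pred_masks = np.stack([extraction.classify_pixels(p) for p in probs])

    pm = evaluation.pixel_metrics(pred_masks, truth.label_masks)
    scores = 1.0 - probs[..., 0]
    auc = evaluation.roc_auc(scores, truth.label_masks > 0)

    states = extraction.extract_states(probs)
    truth_states = extraction.states_from_masks(truth.label_masks)
    dets, truths = _boxes_for_ap(states, truth_states)
    mean_ap, per_class_ap = evaluation.mean_average_precision(dets, truths)

    traj = kinematics.build_trajectory(states)
    ref = kinematics.trajectory_from_truth(truth)
    exc = kinematics.excursion(traj)
    exc_ref = kinematics.excursion(ref)
    rmse = evaluation.trajectory_rmse(traj, ref)

    coin_err = abs(np.median([s[LABEL_COIN].diameter_px for s in states
                              if s[LABEL_COIN].present]) - truth.coin_diameter_px)

    metrics = {
        "dice_hyoid": pm["hyoid"]["dice"],
        "dice_spine": pm["spine"]["dice"],
        "dice_coin": pm["coin"]["dice"],
        "pixel_accuracy": pm["pooled"]["accuracy"],
        "roc_auc": auc,
        "map_iou50": mean_ap,
        "ap_hyoid": per_class_ap["hyoid"],
        "max_diagonal_pred_mm": exc.max_diagonal_mm,
        "max_diagonal_true_mm": exc_ref.max_diagonal_mm,
        "excursion_rel_err": abs(exc.max_diagonal_mm - exc_ref.max_diagonal_mm)
                             / exc_ref.max_diagonal_mm,
        "rmse_diagonal_mm": rmse["diagonal"],
        "coin_diameter_err_px": coin_err,
        "n_retained_frames": len(traj),
    }
    return metrics, pm


def occlusion_detection_rate(model, seed: int) -> Dict[str, float]:
    """Fraction of peak-elevation frames in which the occluded hyoid is still
    detected (peak-elevation = true diagonal displacement >= 80% of maximum)."""
    spec = desk_clip_spec(seed=1000 * (seed % 1024) + 77, occluder_on=True)
    frames, truth = make_phantom(spec)
    probs = training.predict(model, frames)
    states = extraction.extract_states(probs)
    rel = truth.true_trajectory_mm - truth.true_trajectory_mm[0]
    diag = np.hypot(rel[:, 0], rel[:, 1])
    peak_frames = np.flatnonzero(diag >= 0.8 * diag.max())
    detected = sum(states[t][LABEL_HYOID].present for t in peak_frames)
    return {"occlusion_peak_frames": len(peak_frames),
            "occlusion_detection_rate": detected / len(peak_frames)}


def run_desk_benchmark(seed: int, epochs: int = DESK_EPOCHS) -> DeskBenchmark:
    model, history, test_clip = train_desk_model(seed, epochs=epochs)
    metrics, pm = evaluate_desk_model(model, test_clip)
    metrics.update(occlusion_detection_rate(model, seed))
    metrics["epochs_run"] = len(history)
    metrics["final_train_loss"] = float(history.train_loss.iloc[-1])
    return DeskBenchmark(model=model, history=history, metrics=metrics,
                         pixel_metrics=pm)
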