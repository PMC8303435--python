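"""From per-pixel class probabilities to per-frame object states.

The operating point of each structure is the arithmetic mean of the
coordinates of its detected pixels (the centroid over all pixels of the
class, not of a single connected component).  The coin's pixel diameter is
the major axis of its region, estimated from second central moments:
D = 4 * sqrt(lambda_max) with lambda_max the larger eigenvalue of the pixel
coordinate covariance — exact for a filled ellipse and rotation-invariant.

Conventions: x = column, y = row, origin top-left, pixel centres at integer
coordinates; bounding boxes are half-open [xmin, xmax) x [ymin, ymax).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.ndimage import label as cc_label
from scipy.spatial.distance import pdist

LABEL_BACKGROUND, LABEL_HYOID, LABEL_SPINE, LABEL_COIN = 0, 1, 2, 3
CLASS_NAMES = {LABEL_HYOID: "hyoid", LABEL_SPINE: "spine", LABEL_COIN: "coin"}
OBJECT_CLASSES = (LABEL_HYOID, LABEL_SPINE, LABEL_COIN)

#: minimum detected pixels for an object to count as present (speckle guard)
MIN_PIXELS = 5


@dataclass
class ObjectState:
    present: bool
    centroid: Optional[Tuple[float, float]] = None  # (x, y)
    bbox: Optional[Tuple[int, int, int, int]] = None  # half-open
    pixel_count: int = 0
    confidence: float = 0.0  # mean predicted probability over the object's pixels
    diameter_px: Optional[float] = None  # coin only: ellipse major axis


def classify_pixels(probs: np.ndarray) -> np.ndarray:
    """Argmax over the trailing class axis; ties go to the lower class index
    (background first)."""
    return np.argmax(probs, axis=-1).astype(np.uint8)


def _class_coords(mask: np.ndarray, class_id: int) -> np.ndarray:
    rc = np.argwhere(mask == class_id)
    return rc[:, ::-1]  # (x, y)


def centroid(mask: np.ndarray, class_id: int,
             min_pixels: int = MIN_PIXELS) -> Optional[Tuple[float, float]]:
    """Mean (x, y) of the class's pixels, or None below the presence threshold."""
    xy = _class_coords(mask, class_id)
    if len(xy) < min_pixels:
        return None
    cx, cy = xy.mean(axis=0)
    return (float(cx), float(cy))


def bounding_box(mask: np.ndarray, class_id: int,
                 min_pixels: int = MIN_PIXELS) -> Optional[Tuple[int, int, int, int]]:
    """Tight half-open box (xmin, ymin, xmax, ymax) over the class's pixels."""
    xy = _class_coords(mask, class_id)
    if len(xy) < min_pixels:
        return None
    xmin, ymin = xy.min(axis=0)
    xmax, ymax = xy.max(axis=0)
    return (int(xmin), int(ymin), int(xmax) + 1, int(ymax) + 1)


def coin_diameter_px(mask: np.ndarray,
                     min_pixels: int = MIN_PIXELS) -> Optional[float]:
    """Coin pixel diameter as the region's ellipse major axis.

    Moment estimate 4*sqrt(lambda_max); for fewer than 10 pixels the moment
    estimate is unstable and the maximum pairwise extent is used instead.
    """
    xy = _class_coords(mask, LABEL_COIN).astype(np.float64)
    if len(xy) < min_pixels:
        return None
    if len(xy) < 10:
        return float(pdist(xy).max()) if len(xy) > 1 else 1.0
    cov = np.cov(xy.T, bias=True)
    lam = np.linalg.eigvalsh(cov)[-1]
    return float(4.0 * np.sqrt(lam))


def _largest_component_only(mask: np.ndarray, class_id: int) -> np.ndarray:
    binary = mask == class_id
    lab, n = cc_label(binary)
    if n <= 1:
        return mask
    sizes = np.bincount(lab.ravel())[1:]
    keep = 1 + int(np.argmax(sizes))
    out = mask.copy()
    out[binary & (lab != keep)] = LABEL_BACKGROUND
    return out


def extract_states(probs_stack: np.ndarray, min_pixels: int = MIN_PIXELS,
                   largest_component: bool = False) -> List[Dict[int, ObjectState]]:
    """Per-frame object states from a (T, H, W, K) probability stack.

    ``largest_component`` optionally restricts each class to its largest
    connected component before measuring (robustness mode for noisy
    predictions; off by default — the centroid is defined over all detected
    pixels).
    """
    probs_stack = np.asarray(probs_stack)
    if probs_stack.ndim != 4:
        raise ValueError("expected a (T, H, W, K) probability stack")
    states: List[Dict[int, ObjectState]] = []
    for t in range(probs_stack.shape[0]):
        probs = probs_stack[t]
        mask = classify_pixels(probs)
        frame_states: Dict[int, ObjectState] = {}
        for cls in OBJECT_CLASSES:
            m = _largest_component_only(mask, cls) if largest_component else mask
            c = centroid(m, cls, min_pixels)
            if c is None:
                frame_states[cls] = ObjectState(present=False)
                continue
            box = bounding_box(m, cls, min_pixels)
            sel = m == cls
            conf = float(probs[..., cls][sel].mean())
            dia = coin_diameter_px(m, min_pixels) if cls == LABEL_COIN else None
            frame_states[cls] = ObjectState(
                present=True, centroid=c, bbox=box,
                pixel_count=int(sel.sum()), confidence=conf, diameter_px=dia)
        states.append(frame_states)
    return states


def states_from_masks(masks: np.ndarray, min_pixels: int = MIN_PIXELS) -> List[Dict[int, ObjectState]]:
    """Object states from ground-truth label masks (confidence = 1)."""
    masks = np.asarray(masks)
    onehot = np.eye(4, dtype=np.float32)[masks.astype(np.int64)]
    return extract_states(onehot, min_pixels=min_pixels)
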