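"""Spine-referenced, coin-calibrated hyoid kinematics.

Per retained frame (a frame where hyoid, spine and coin are all detected):

* relative position in pixels:      DxR = Cx - Hx,   DyR = Cy - Hy
  with (Cx, Cy) the cervical-spine centroid and (Hx, Hy) the hyoid centroid —
  referencing the mobile hyoid to the rigid spine removes global head motion;
* scale factor:                     s = 24 / Dpxls   [mm per pixel]
  from the 24 mm calibration coin whose image diameter is Dpxls pixels (the
  region's ellipse major axis, so a tilted coin still reads its true
  diameter);
* normalized position in mm:        N(DxR) = s * DxR,  N(DyR) = s * DyR
* diagonal distance:                D(C,H) = sqrt(N(DxR)^2 + N(DyR)^2).

The excursion summary reports the displacement from the first retained frame
to the frame of maximum diagonal displacement, in horizontal, vertical and
diagonal components.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .extraction import LABEL_COIN, LABEL_HYOID, LABEL_SPINE, ObjectState

COIN_TRUE_MM = 24.0


def relative_position(spine_center: Sequence[float],
                      hyoid_center: Sequence[float]) -> Tuple[float, float]:
    """(DxR, DyR) = spine centre minus hyoid centre, in pixels."""
    cx, cy = spine_center
    hx, hy = hyoid_center
    return (float(cx) - float(hx), float(cy) - float(hy))


def scale_factor(d_pxls: float, coin_true_mm: float = COIN_TRUE_MM) -> float:
    """Millimetres per pixel from the coin's pixel diameter.

    The coin has a known physical diameter (24 mm by convention), so one
    pixel spans coin_true_mm / Dpxls millimetres.
    """
    if d_pxls <= 0:
        raise ValueError(f"coin pixel diameter must be positive, got {d_pxls}")
    return coin_true_mm / float(d_pxls)


def normalize(dx_r: float, dy_r: float, s: float) -> Tuple[float, float]:
    """Pixel offsets to millimetres: (N(DxR), N(DyR)) = (s*DxR, s*DyR)."""
    if s <= 0:
        raise ValueError("scale factor must be positive")
    return (s * dx_r, s * dy_r)


def diagonal_distance(ndx: float, ndy: float) -> float:
    """D(C,H) = sqrt(N(DxR)^2 + N(DyR)^2)."""
    return float(np.hypot(ndx, ndy))


@dataclass
class Trajectory:
    retained_frames: np.ndarray  # indices with hyoid, spine and coin all present
    dx_r_px: np.ndarray
    dy_r_px: np.ndarray
    scale_mm_per_px: np.ndarray  # per retained frame (constant unless per-frame scale)
    ndx_mm: np.ndarray
    ndy_mm: np.ndarray
    diagonal_mm: np.ndarray

    def __len__(self) -> int:
        return len(self.retained_frames)


@dataclass
class ExcursionSummary:
    """Displacement from the first retained frame to the frame of maximum
    diagonal displacement (absolute components; all >= 0)."""

    horizontal_mm: float
    vertical_mm: float
    diagonal_mm: float
    max_diagonal_mm: float
    argmax_frame: int


def build_trajectory(states: Sequence[Dict[int, ObjectState]],
                     per_frame_scale: bool = False,
                     coin_true_mm: float = COIN_TRUE_MM) -> Trajectory:
    """Trajectory over the frames where all three objects were detected.

    With ``per_frame_scale`` false (default) a single clip-level scale is
    computed from the median coin diameter over retained frames, which keeps
    per-frame segmentation jitter of the coin out of the trajectory.
    """
    if len(states) == 0:
        raise ValueError("empty state sequence")
    retained, dxs, dys, dias = [], [], [], []
    for t, st in enumerate(states):
        h, c, coin = st.get(LABEL_HYOID), st.get(LABEL_SPINE), st.get(LABEL_COIN)
        if not (h and c and coin and h.present and c.present and coin.present
                and coin.diameter_px is not None):
            continue
        retained.append(t)
        dx, dy = relative_position(c.centroid, h.centroid)
        dxs.append(dx)
        dys.append(dy)
        dias.append(coin.diameter_px)
    if not retained:
        raise ValueError("no fully-detected frames (hyoid, spine and coin never co-occur)")
    dxs, dys, dias = map(np.asarray, (dxs, dys, dias))
    if per_frame_scale:
        s = np.array([scale_factor(d, coin_true_mm) for d in dias])
    else:
        s = np.full(len(dias), scale_factor(float(np.median(dias)), coin_true_mm))
    ndx, ndy = s * dxs, s * dys
    return Trajectory(
        retained_frames=np.asarray(retained, dtype=int),
        dx_r_px=dxs, dy_r_px=dys, scale_mm_per_px=s,
        ndx_mm=ndx, ndy_mm=ndy, diagonal_mm=np.hypot(ndx, ndy))


def excursion(traj: Trajectory) -> ExcursionSummary:
    """Excursion statistics relative to the first retained frame."""
    if len(traj) == 0:
        raise ValueError("trajectory has no retained frames")
    disp_x = traj.ndx_mm - traj.ndx_mm[0]
    disp_y = traj.ndy_mm - traj.ndy_mm[0]
    diag = np.hypot(disp_x, disp_y)
    k = int(np.argmax(diag))
    return ExcursionSummary(
        horizontal_mm=float(abs(disp_x[k])),
        vertical_mm=float(abs(disp_y[k])),
        diagonal_mm=float(diag[k]),
        max_diagonal_mm=float(diag.max()),
        argmax_frame=int(traj.retained_frames[k]))


def trajectory_from_truth(truth, per_frame_scale: bool = False) -> Trajectory:
    """Reference trajectory straight from phantom ground truth (no detection)."""
    retained = np.flatnonzero(truth.coin_present)
    if len(retained) == 0:
        raise ValueError("no frames with the coin present")
    dx = truth.spine_centers[retained, 0] - truth.hyoid_centers[retained, 0]
    dy = truth.spine_centers[retained, 1] - truth.hyoid_centers[retained, 1]
    s = np.full(len(retained), truth.scale_mm_per_px)
    ndx, ndy = s * dx, s * dy
    return Trajectory(retained_frames=retained, dx_r_px=dx, dy_r_px=dy,
                      scale_mm_per_px=s, ndx_mm=ndx, ndy_mm=ndy,
                      diagonal_mm=np.hypot(ndx, ndy))
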