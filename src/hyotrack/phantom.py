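"""Synthetic lateral-neck phantom for videofluoroscopic swallowing studies.

Real clips of this kind cannot be redistributed, so every downstream stage is
exercised on a rendered stand-in with exact per-pixel labels and a known
trajectory.  The scene contains the three structures the tracker needs:

* a bright, effectively rigid cervical-spine column (a vertical stack of
  rounded vertebral blocks right of the image centre),
* a small mobile hyoid blob left of the spine, executing one smooth
  superior-anterior excursion and returning to rest (raised-cosine pulse),
* a calibration coin of known physical diameter (24 mm) rendered as a
  circle/ellipse anterior-inferior to the spine, never overlapping it.

Optional nuisances emulate the clinical failure modes: a mandible occluder
bar that hides the upper part of the hyoid at peak elevation, a frame index
after which the coin leaves the field of view, global head jitter, and
additive Gaussian noise.  The intensity model is a textured background with
flat plateaus per structure — enough to exercise segmentation, with no claim
of physical X-ray realism.

Conventions (used package-wide): x = column, y = row, origin at the top-left,
pixel centres at integer coordinates.  Anterior displacement is rendered
toward smaller x (the patient faces left); superior toward smaller y.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

ANTERIOR_IS_NEGATIVE_X = True  #: rendered sign convention, see module docstring
SUPERIOR_IS_NEGATIVE_Y = True

#: coin pixel-diameter statistics observed in clinical recordings
COIN_DIAMETER_PX_MEAN = 62.9
COIN_DIAMETER_PX_SD = 7.6

_INT_BACKGROUND = 0.20
_INT_HYOID = 0.60
_INT_SPINE = 0.80
_INT_COIN = 0.95
_INT_OCCLUDER = 0.78
_TEXTURE_SD = 0.03

LABEL_BACKGROUND, LABEL_HYOID, LABEL_SPINE, LABEL_COIN = 0, 1, 2, 3


class PhantomSpecError(ValueError):
    """Invalid phantom specification; names the offending field."""

    def __init__(self, fieldname: str, message: str):
        self.fieldname = fieldname
        super().__init__(f"{fieldname}: {message}")


@dataclass
class PhantomSpec:
    """All parameters of the synthetic scene and motion (seed-deterministic)."""

    frame_count: int = 60
    frame_size: Tuple[int, int] = (224, 224)  # (height, width) px
    fps: float = 30.0
    coin_diameter_px: Optional[float] = None  # None -> drawn N(62.9, 7.6), > 20
    coin_aspect: float = 1.0  # minor/major axis ratio in (0, 1]
    coin_true_mm: float = 24.0
    excursion_mm: Tuple[float, float] = (8.0, 10.0)  # (anterior, superior) peak
    motion_period_frames: int = 30
    occluder_on: bool = False
    coin_exit_frame: Optional[int] = None
    jitter_px: float = 0.5
    noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> "PhantomSpec":
        if self.frame_count < 1:
            raise PhantomSpecError("frame_count", "must be a positive integer")
        h, w = self.frame_size
        if h < 32 or w < 32:
            raise PhantomSpecError("frame_size", "must be at least 32x32")
        if self.fps <= 0:
            raise PhantomSpecError("fps", "must be positive")
        if self.coin_diameter_px is not None:
            if self.coin_diameter_px <= 0:
                raise PhantomSpecError("coin_diameter_px", "must be positive")
            if self.coin_diameter_px >= min(self.frame_size):
                raise PhantomSpecError("coin_diameter_px",
                                       "must be smaller than the frame")
        if not (0 < self.coin_aspect <= 1):
            raise PhantomSpecError("coin_aspect", "must be in (0, 1]")
        if self.coin_true_mm <= 0:
            raise PhantomSpecError("coin_true_mm", "must be positive")
        if self.excursion_mm[0] < 0 or self.excursion_mm[1] < 0:
            raise PhantomSpecError("excursion_mm", "components must be >= 0")
        if self.motion_period_frames < 2:
            raise PhantomSpecError("motion_period_frames", "must be >= 2")
        if self.jitter_px < 0:
            raise PhantomSpecError("jitter_px", "must be >= 0")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd", "must be >= 0")
        return self


@dataclass
class PhantomTruth:
    """Exact ground truth for a rendered clip.

    ``hyoid_centers`` are full-shape (unoccluded) centres — occlusion removes
    pixels, not the bone; ``hyoid_visible_centers`` are the means of the
    actually labelled pixels, so occlusion-induced centroid bias can be
    quantified.  ``true_trajectory_mm`` is the spine-referenced, coin-scaled
    position (N(DxR), N(DyR)) computed from the generated geometry.
    """

    label_masks: np.ndarray  # (T, H, W) uint8 in {0..3}
    hyoid_centers: np.ndarray  # (T, 2) float (x, y)
    hyoid_visible_centers: np.ndarray  # (T, 2) float, NaN when fully hidden
    spine_centers: np.ndarray  # (T, 2) float
    coin_center_and_axes: np.ndarray  # (T, 4): cx, cy, major_px, minor_px
    coin_present: np.ndarray  # (T,) bool
    true_trajectory_mm: np.ndarray  # (T, 2): N(DxR), N(DyR)
    coin_diameter_px: float  # resolved draw
    scale_mm_per_px: float  # 24 / coin_diameter_px


def motion_path(spec: PhantomSpec, frame_index: int) -> Tuple[float, float]:
    """Hyoid displacement (anterior_mm, superior_mm) at ``frame_index``.

    A raised-cosine pulse: zero at frame 0, peaking at ``excursion_mm`` at
    half the motion period, back to zero at the full period and beyond.
    """
    spec.validate()
    if not (0 <= frame_index < spec.frame_count):
        raise IndexError(f"frame_index {frame_index} outside [0, {spec.frame_count})")
    t = frame_index
    period = spec.motion_period_frames
    if t >= period:
        return (0.0, 0.0)
    envelope = 0.5 * (1.0 - np.cos(2.0 * np.pi * t / period))
    return (spec.excursion_mm[0] * envelope, spec.excursion_mm[1] * envelope)


def _resolve_coin_diameter(spec: PhantomSpec, rng: np.random.Generator) -> float:
    if spec.coin_diameter_px is not None:
        return float(spec.coin_diameter_px)
    hi = min(spec.frame_size) * 0.9
    for _ in range(1000):
        d = rng.normal(COIN_DIAMETER_PX_MEAN, COIN_DIAMETER_PX_SD)
        if 20.0 < d < hi:
            return float(d)
    raise PhantomSpecError("coin_diameter_px",
                           "could not draw a diameter in (20, frame) — frame too small")


def _ellipse_mask(xx, yy, cx, cy, a, b, power: float = 2.0):
    return (np.abs((xx - cx) / a) ** power + np.abs((yy - cy) / b) ** power) <= 1.0


def _scene_layout(spec: PhantomSpec, coin_d: float):
    h, w = spec.frame_size
    ppm = coin_d / spec.coin_true_mm  # px per mm
    layout = {
        "spine_cx": 0.64 * w,
        "spine_half_width": 0.08 * w,
        "spine_top": 0.06 * h,
        "spine_bottom": 0.94 * h,
        "n_vertebrae": 6,
        "vert_gap": 0.02 * h,
        "hyoid_base": np.array([0.30 * w, 0.62 * h]),
        "hyoid_a": 0.055 * w,
        "hyoid_b": 0.032 * h,
        "coin_center": np.array([0.20 * w, 0.80 * h]),
        "ppm": ppm,
    }
    peak = layout["hyoid_base"] + np.array([-spec.excursion_mm[0] * ppm,
                                            -spec.excursion_mm[1] * ppm])
    layout["occluder_x"] = (peak[0] - 3.0 * layout["hyoid_a"],
                            peak[0] + 3.0 * layout["hyoid_a"])
    layout["occluder_y"] = (peak[1] - 2.5 * layout["hyoid_b"], peak[1])
    return layout


def make_phantom(spec: PhantomSpec) -> Tuple[np.ndarray, PhantomTruth]:
    """Render a clip; returns (frames, truth) with frames (T, H, W) in [0, 1].

    Deterministic for a fixed spec (including seed): two calls produce
    bit-identical frames and masks.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    coin_d = _resolve_coin_diameter(spec, rng)
    h, w = spec.frame_size
    t_frames = spec.frame_count
    lay = _scene_layout(spec, coin_d)
    ppm = lay["ppm"]
    s_true = spec.coin_true_mm / coin_d  # mm per px

    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    from scipy.ndimage import gaussian_filter
    texture = gaussian_filter(rng.standard_normal((h, w)), 3.0)
    texture *= _TEXTURE_SD / max(texture.std(), 1e-12)
    background = _INT_BACKGROUND + texture

    jitter = (rng.normal(0.0, spec.jitter_px, size=(t_frames, 2))
              if spec.jitter_px > 0 else np.zeros((t_frames, 2)))
    noise = (rng.normal(0.0, spec.noise_sd, size=(t_frames, h, w))
             if spec.noise_sd > 0 else np.zeros((t_frames, h, w)))

    frames = np.empty((t_frames, h, w), dtype=np.float32)
    masks = np.zeros((t_frames, h, w), dtype=np.uint8)
    hyoid_centers = np.empty((t_frames, 2))
    hyoid_visible = np.full((t_frames, 2), np.nan)
    spine_centers = np.empty((t_frames, 2))
    coin_caa = np.zeros((t_frames, 4))
    coin_present = np.zeros(t_frames, dtype=bool)
    traj = np.empty((t_frames, 2))

    coin_major = coin_d / 2.0
    coin_minor = coin_major * spec.coin_aspect

    vert_span = lay["spine_bottom"] - lay["spine_top"]
    n_vert = lay["n_vertebrae"]
    seg_h = (vert_span - (n_vert - 1) * lay["vert_gap"]) / n_vert

    for t in range(t_frames):
        jx, jy = jitter[t]
        img = background.copy()
        mask = np.zeros((h, w), dtype=np.uint8)

        present = spec.coin_exit_frame is None or t < spec.coin_exit_frame
        if present:
            ccx, ccy = lay["coin_center"][0] + jx, lay["coin_center"][1] + jy
            cm = _ellipse_mask(xx, yy, ccx, ccy, coin_major, coin_minor)
            img[cm] = _INT_COIN
            mask[cm] = LABEL_COIN
            coin_caa[t] = (ccx, ccy, 2 * coin_major, 2 * coin_minor)
            coin_present[t] = True

        spine_any = np.zeros((h, w), dtype=bool)
        for k in range(n_vert):
            vy = lay["spine_top"] + k * (seg_h + lay["vert_gap"]) + seg_h / 2.0 + jy
            vm = _ellipse_mask(xx, yy, lay["spine_cx"] + jx, vy,
                               lay["spine_half_width"], seg_h / 2.0, power=4.0)
            spine_any |= vm
        img[spine_any] = _INT_SPINE
        mask[spine_any] = LABEL_SPINE
        sp_pix = np.argwhere(spine_any)  # (row, col)
        spine_centers[t] = sp_pix[:, ::-1].mean(axis=0)

        dmm = motion_path(spec, t)
        hx = lay["hyoid_base"][0] - dmm[0] * ppm + jx
        hy = lay["hyoid_base"][1] - dmm[1] * ppm + jy
        hm = _ellipse_mask(xx, yy, hx, hy, lay["hyoid_a"], lay["hyoid_b"])
        img[hm] = _INT_HYOID
        mask[hm] = LABEL_HYOID
        hyoid_centers[t] = (hx, hy)

        if spec.occluder_on:
            ox, oy = lay["occluder_x"], lay["occluder_y"]
            om = ((xx >= ox[0] + jx) & (xx <= ox[1] + jx)
                  & (yy >= oy[0] + jy) & (yy <= oy[1] + jy))
            img[om] = _INT_OCCLUDER
            mask[om] = LABEL_BACKGROUND

        vis = np.argwhere(mask == LABEL_HYOID)
        if len(vis):
            hyoid_visible[t] = vis[:, ::-1].mean(axis=0)

        traj[t] = (s_true * (spine_centers[t, 0] - hx),
                   s_true * (spine_centers[t, 1] - hy))

        img = img + noise[t]
        frames[t] = np.clip(img, 0.0, 1.0)
        masks[t] = mask

    truth = PhantomTruth(
        label_masks=masks, hyoid_centers=hyoid_centers,
        hyoid_visible_centers=hyoid_visible, spine_centers=spine_centers,
        coin_center_and_axes=coin_caa, coin_present=coin_present,
        true_trajectory_mm=traj, coin_diameter_px=coin_d,
        scale_mm_per_px=s_true)
    return frames, truth


def split_dataset(items: Sequence, ratios: Tuple[float, float, float] = (0.7, 0.1, 0.2),
                  seed: int = 0) -> Tuple[list, list, list]:
    """Partition clips into train/val/test by whole clip (seeded shuffle).

    Sizes follow the ratios by largest-remainder rounding, so no clip's
    frames ever straddle two splits.
    """
    items = list(items)
    if not items:
        raise ValueError("cannot split an empty list of clips")
    r = np.asarray(ratios, dtype=float)
    if (r <= 0).any():
        raise ValueError("ratios must be positive")
    if abs(r.sum() - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    n = len(items)
    exact = r * n
    counts = np.floor(exact).astype(int)
    for i in np.argsort(-(exact - counts))[: n - counts.sum()]:
        counts[i] += 1
    order = np.random.default_rng(seed).permutation(n)
    shuffled = [items[i] for i in order]
    out, lo = [], 0
    for c in counts:
        out.append(shuffled[lo:lo + c])
        lo += c
    return tuple(out)
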