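"""Frame/mask/trajectory I/O, configuration files and provenance headers.

Clips are directories of zero-padded 8-bit grayscale PNGs (``frame_00000.png``)
read in lexicographic order, or multi-page TIFFs.  Label masks are indexed
PNGs with palette indices 0-3 (background, hyoid, spine, coin).  Numeric
outputs are CSV/JSON with a provenance comment header carrying the package
version, seed and configuration hash, so any artifact can be regenerated.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import __version__
from .kinematics import ExcursionSummary, Trajectory
from .phantom import PhantomSpec, PhantomTruth

_MASK_PALETTE = [0, 0, 0, 60, 60, 220, 60, 220, 60, 220, 60, 60]  # bg,hyoid,spine,coin


# ------------------------------------------------------------------- frames
def write_frames(frames: np.ndarray, out_dir) -> List[Path]:
    """Write a (T, H, W) float [0,1] or uint8 stack as 8-bit grayscale PNGs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frames = np.asarray(frames)
    if frames.dtype != np.uint8:
        frames = np.clip(np.round(frames * 255.0), 0, 255).astype(np.uint8)
    paths = []
    for t, frame in enumerate(frames):
        p = out_dir / f"frame_{t:05d}.png"
        Image.fromarray(frame, mode="L").save(p)
        paths.append(p)
    return paths


def read_frames(path) -> np.ndarray:
    """Read a clip into a (T, H, W) float32 stack scaled to [0, 1].

    ``path`` is a directory of PNG frames (lexicographic order) or a
    multi-page TIFF file.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff"})
        if not files:
            raise FileNotFoundError(f"no frame images found in {path}")
        frames, bad = [], []
        for p in files:
            try:
                img = np.asarray(Image.open(p).convert("L"))
            except Exception:
                bad.append(f"{p.name}: unreadable")
                continue
            frames.append(img)
        shapes = {f.shape for f in frames}
        if len(shapes) > 1:
            counts = sorted(shapes, key=lambda s: sum(f.shape == s for f in frames))
            ref = counts[-1]
            bad += [f"{p.name}: size {f.shape} != {ref}"
                    for p, f in zip(files, frames) if f.shape != ref]
        if bad:
            raise ValueError("bad frames:\n  " + "\n  ".join(bad))
        stack = np.stack(frames)
    elif path.suffix.lower() in {".tif", ".tiff"}:
        import tifffile
        stack = tifffile.imread(path)
        if stack.ndim == 2:
            stack = stack[None]
    else:
        raise ValueError(f"expected a frame directory or multi-page TIFF, got {path}")
    return (stack.astype(np.float32) / 255.0)


# -------------------------------------------------------------------- masks
def write_masks(masks: np.ndarray, out_dir) -> List[Path]:
    """Write (T, H, W) label masks (values 0-3) as indexed PNGs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    masks = np.asarray(masks)
    if masks.size and masks.max() > 3:
        raise ValueError(f"mask value {int(masks.max())} outside 0-3")
    paths = []
    for t, mask in enumerate(masks):
        img = Image.fromarray(mask.astype(np.uint8), mode="P")
        img.putpalette(_MASK_PALETTE)
        p = out_dir / f"mask_{t:05d}.png"
        img.save(p)
        paths.append(p)
    return paths


def read_masks(path) -> np.ndarray:
    """Read indexed-PNG label masks back to a (T, H, W) uint8 stack.

    Raises on any palette index outside 0-3, naming the frame and value.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
    if not files:
        raise FileNotFoundError(f"no mask images found in {path}")
    masks = []
    for p in files:
        arr = np.asarray(Image.open(p))
        bad = np.unique(arr[arr > 3])
        if bad.size:
            raise ValueError(f"{p.name}: mask index {int(bad[0])} outside 0-3")
        masks.append(arr.astype(np.uint8))
    return np.stack(masks)


# -------------------------------------------------------------- provenance
def provenance(seed: Optional[int], config_obj=None) -> Dict[str, str]:
    cfg_hash = "none"
    if config_obj is not None:
        if dataclasses.is_dataclass(config_obj):
            config_obj = dataclasses.asdict(config_obj)
        cfg_hash = hashlib.sha256(
            json.dumps(config_obj, sort_keys=True, default=str).encode()).hexdigest()[:12]
    return {"package": f"hyotrack {__version__}",
            "seed": str(seed), "config_sha": cfg_hash}


def _header_lines(prov: Dict[str, str]) -> str:
    return "".join(f"# {k}: {v}\n" for k, v in prov.items())


# -------------------------------------------------------- spec / config IO
def spec_to_yaml(spec: PhantomSpec, path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(spec)))


def spec_from_yaml(path) -> PhantomSpec:
    data = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("frame_size", "excursion_mm"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return PhantomSpec(**data).validate()


def network_config_from_yaml(path):
    from .model import NetworkConfig
    data = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("input_size", "encoder_widths"):
        if key in data and data[key] is not None:
            data[key] = tuple(data[key])
    return NetworkConfig(**data).validate()


# ------------------------------------------------------------- truth / csv
def write_truth_csv(truth: PhantomTruth, path, seed: Optional[int] = None) -> None:
    df = pd.DataFrame({
        "frame": np.arange(len(truth.label_masks)),
        "hx": truth.hyoid_centers[:, 0], "hy": truth.hyoid_centers[:, 1],
        "cx_spine": truth.spine_centers[:, 0], "cy_spine": truth.spine_centers[:, 1],
        "coin_cx": truth.coin_center_and_axes[:, 0],
        "coin_cy": truth.coin_center_and_axes[:, 1],
        "coin_major_px": truth.coin_center_and_axes[:, 2],
        "coin_present": truth.coin_present.astype(int),
        "ndx_mm": truth.true_trajectory_mm[:, 0],
        "ndy_mm": truth.true_trajectory_mm[:, 1],
    })
    with open(path, "w") as fh:
        fh.write(_header_lines(provenance(seed)))
        df.to_csv(fh, index=False)


def write_trajectory_csv(traj: Trajectory, path, seed: Optional[int] = None,
                         config_obj=None) -> None:
    df = pd.DataFrame({
        "frame": traj.retained_frames,
        "DxR_px": traj.dx_r_px, "DyR_px": traj.dy_r_px,
        "s_mm_per_px": traj.scale_mm_per_px,
        "ndx_mm": traj.ndx_mm, "ndy_mm": traj.ndy_mm,
        "diag_mm": traj.diagonal_mm,
    })
    with open(path, "w") as fh:
        fh.write(_header_lines(provenance(seed, config_obj)))
        df.to_csv(fh, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def write_states_csv(states, path, seed: Optional[int] = None) -> None:
    from .extraction import CLASS_NAMES, OBJECT_CLASSES
    rows = []
    for t, st in enumerate(states):
        for cls in OBJECT_CLASSES:
            s = st[cls]
            rows.append({
                "frame": t, "class": CLASS_NAMES[cls], "present": int(s.present),
                "cx": s.centroid[0] if s.centroid else np.nan,
                "cy": s.centroid[1] if s.centroid else np.nan,
                "xmin": s.bbox[0] if s.bbox else np.nan,
                "ymin": s.bbox[1] if s.bbox else np.nan,
                "xmax": s.bbox[2] if s.bbox else np.nan,
                "ymax": s.bbox[3] if s.bbox else np.nan,
                "pixels": s.pixel_count, "confidence": s.confidence,
            })
    with open(path, "w") as fh:
        fh.write(_header_lines(provenance(seed)))
        pd.DataFrame(rows).to_csv(fh, index=False)


def write_json(obj: dict, path, seed: Optional[int] = None, config_obj=None) -> None:
    payload = {"_provenance": provenance(seed, config_obj)}
    payload.update(obj)
    Path(path).write_text(json.dumps(payload, indent=2, default=float) + "\n")


def excursion_to_dict(summary: ExcursionSummary) -> dict:
    return dataclasses.asdict(summary)
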