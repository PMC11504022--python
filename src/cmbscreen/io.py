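"""Readers and writers for the on-disk formats shared across the pipeline.

Slice stacks live either as directories of zero-padded PNG files
(``slice_001.png`` is slice index 0 — file names carry 1-based human labels,
in-memory indices are 0-based) or as single NIfTI volumes sliced along the
third axis.  Labels travel as YOLO-format text lines (``class cx cy w h``,
normalized) or COCO-style JSON (``[x, y, w, h]`` pixel boxes); internally
everything is a corner-format :class:`~cmbscreen.boxes.Box`.  All writers are
deterministic (sorted keys, fixed float formatting).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import yaml
from PIL import Image

from .boxes import Box

__all__ = ["LabelRecord", "read_stack", "write_stack", "convert_labels",
           "read_yolo_labels", "write_yolo_labels", "read_coco_labels",
           "write_coco_labels", "load_config", "save_config", "config_hash",
           "normalize_to_uint8"]


@dataclass(frozen=True)
class LabelRecord:
    image_id: str | int
    box: Box
    class_id: int = 0
    score: float | None = None


def normalize_to_uint8(arr: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Linearly rescale any numeric image to 0-255; returns (image, offset, scale)."""
    arr = np.asarray(arr, dtype=np.float64)
    lo, hi = float(arr.min()), float(arr.max())
    scale = 255.0 / (hi - lo) if hi > lo else 1.0
    out = np.clip((arr - lo) * scale, 0, 255).astype(np.uint8)
    return out, lo, scale


def read_stack(path: str | Path, format: str | None = None) -> np.ndarray:
    """Read an ordered slice stack -> (S, H, W) uint8, normalized to 0-255.

    ``format`` is ``png_dir`` or ``nifti``; inferred from the path if omitted.
    A NIfTI volume of shape (X, Y, Z) yields Z slices of shape (X, Y).
    """
    path = Path(path)
    if format is None:
        format = "png_dir" if path.is_dir() else "nifti"
    if format == "png_dir":
        files = sorted(path.glob("*.png"))
        if not files:
            raise FileNotFoundError(f"no PNG slices in {path}")
        slices = []
        shape = None
        for f in files:
            img = np.asarray(Image.open(f).convert("L"))
            if shape is None:
                shape = img.shape
            elif img.shape != shape:
                raise ValueError(f"mixed resolutions in stack: {f.name} is "
                                 f"{img.shape}, expected {shape}")
            slices.append(img)
        return np.stack(slices).astype(np.uint8)
    if format == "nifti":
        vol = np.asanyarray(nib.load(str(path)).dataobj)
        if vol.ndim != 3:
            raise ValueError(f"expected a 3-D NIfTI volume, got shape {vol.shape}")
        stack = np.moveaxis(vol, 2, 0)
        out, _, _ = normalize_to_uint8(stack)
        return out
    raise ValueError(f"unknown stack format {format!r}")


def write_stack(stack: np.ndarray, path: str | Path, format: str = "png_dir") -> None:
    path = Path(path)
    stack = np.asarray(stack)
    if format == "png_dir":
        path.mkdir(parents=True, exist_ok=True)
        for i, sl in enumerate(stack):
            Image.fromarray(sl.astype(np.uint8)).save(path / f"slice_{i + 1:04d}.png")
        return
    if format == "nifti":
        vol = np.moveaxis(stack, 0, 2).astype(np.int16)
        nib.save(nib.Nifti1Image(vol, affine=np.eye(4)), str(path))
        return
    raise ValueError(f"unknown stack format {format!r}")


# --- labels ----------------------------------------------------------------

def _check_image_size(image_size) -> tuple[int, int]:
    w, h = image_size
    if w <= 0 or h <= 0:
        raise ValueError("image_size must be positive (width, height)")
    return int(w), int(h)


def write_yolo_labels(records: Sequence[LabelRecord], path: str | Path,
                      image_size: tuple[int, int]) -> None:
    w, h = _check_image_size(image_size)
    lines = []
    for r in records:
        cx, cy = r.box.center
        lines.append(f"{r.class_id} {cx / w:.6g} {cy / h:.6g} "
                     f"{r.box.width / w:.6g} {r.box.height / h:.6g}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_yolo_labels(path: str | Path, image_size: tuple[int, int],
                     image_id: str | int = 0) -> list[LabelRecord]:
    w, h = _check_image_size(image_size)
    records = []
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        cid, cx, cy, bw, bh = int(parts[0]), *map(float, parts[1:5])
        if not all(0 <= v <= 1 for v in (cx, cy, bw, bh)):
            raise ValueError(f"YOLO fields outside [0, 1] in {path}: {line!r}")
        box = Box((cx - bw / 2) * w, (cy - bh / 2) * h, (cx + bw / 2) * w, (cy + bh / 2) * h)
        records.append(LabelRecord(image_id=image_id, box=box, class_id=cid))
    return records


def write_coco_labels(records: Sequence[LabelRecord], path: str | Path) -> None:
    anns = []
    for i, r in enumerate(records):
        x, y, w, h = r.box.as_xywh()
        ann = {"id": i, "image_id": r.image_id, "category_id": r.class_id,
               "bbox": [round(v, 6) for v in (x, y, w, h)], "area": round(w * h, 6)}
        if r.score is not None:
            ann["score"] = round(r.score, 6)
        anns.append(ann)
    payload = {"annotations": anns,
               "categories": [{"id": 0, "name": "candidate-cmb"}]}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_coco_labels(path: str | Path) -> list[LabelRecord]:
    payload = json.loads(Path(path).read_text())
    records = []
    for ann in payload["annotations"]:
        x, y, w, h = ann["bbox"]
        if w <= 0 or h <= 0:
            raise ValueError(f"degenerate COCO box in {path}: {ann['bbox']}")
        records.append(LabelRecord(image_id=ann["image_id"], box=Box.from_xywh(x, y, w, h),
                                   class_id=ann.get("category_id", 0),
                                   score=ann.get("score")))
    return records


def convert_labels(records: Sequence[LabelRecord], image_size: tuple[int, int],
                   clip: bool = True, strict: bool = False) -> list[LabelRecord]:
    """Validate/clip label boxes against the image bounds.

    Out-of-bounds boxes are clipped with the clip flag (default) or rejected in
    strict mode; degenerate boxes always raise (at Box construction).
    """
    w, h = _check_image_size(image_size)
    out = []
    for r in records:
        b = r.box
        oob = b.x1 < 0 or b.y1 < 0 or b.x2 > w or b.y2 > h
        if oob:
            if strict:
                raise ValueError(f"box {b.as_tuple()} outside image {image_size}")
            if clip:
                b = b.clipped(w, h)
        out.append(LabelRecord(image_id=r.image_id, box=b, class_id=r.class_id,
                               score=r.score))
    return out


# --- configuration / logging ----------------------------------------------

def load_config(path: str | Path) -> dict:
    with open(path) as f:
        return yaml.safe_load(f)


def save_config(cfg: dict, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(cfg, sort_keys=True))


def config_hash(cfg: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def append_jsonl(path: str | Path, record: dict) -> None:
    with open(path, "a") as f:
        f.write(json.dumps(record, sort_keys=True, default=str) + "\n")
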