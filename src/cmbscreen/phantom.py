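"""Seeded SWI/phase patient phantoms with ground truth.

The generator emulates the statistical structure a two-stage microbleed
screening pipeline relies on, without attempting anatomical realism:

* **CMBs** — round hypointense blobs spanning 1-3 consecutive slices, dark in
  both the susceptibility-weighted (SWI) and the phase image (paramagnetic
  hemosiderin).
* **Calcification mimics** — identical appearance in SWI, but *hyperintense*
  in the phase image (diamagnetic), the discriminative cue a clinician uses.
  A configurable fraction is "phase-ambiguous": rendered with a CMB-like dark
  phase signature (emulating filtering/partial-volume artefacts), so patient
  metadata carries the only remaining information about them.
* **Vessel mimics** — elongated hypointense tubes persisting over >= 4 slices.
* **Metadata coupling** — mimic frequency depends on age and gender with
  strength ``metadata_effect``: calcification odds rise for younger female
  patients, microbleed-positive patients skew older, so text prompts are
  genuinely informative for candidate classification.

Ground-truth boxes enclose CMBs only.  Everything is driven by a single seed;
records regenerate byte-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
from scipy import ndimage

from .boxes import Box
from .prompts import PatientMeta

__all__ = ["PhantomSpec", "PhantomObject", "PatientRecord", "generate_patient",
           "generate_dataset", "regenerate_from_manifest"]


@dataclass(frozen=True)
class PhantomSpec:
    slices_per_patient: int = 16
    image_side: int = 256
    cmb_count_mean: float = 3.0           # Poisson mean for CMB-positive patients
    cmb_diameter: tuple[float, float] = (4.0, 32.0)   # px footprint on a slice
    calcification_rate: float = 1.5       # Poisson mean of calcification mimics
    vessel_rate: float = 1.0              # Poisson mean of vessel mimics
    positive_fraction: float = 0.37       # fraction of patients carrying CMBs
    background_level: float = 150.0
    noise_sigma: float = 6.0
    bias_field_strength: float = 18.0
    contrast: float = 0.55                # fractional intensity drop of a blob
    phase_contrast: float = 0.45          # fractional phase shift (sign by object kind)
    phase_ambiguity: float = 0.35         # fraction of mimics with ~no phase cue
    metadata_effect: float = 1.0          # strength of age/gender -> mimic-rate coupling
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.cmb_diameter
        if lo < 2.0:
            raise ValueError("minimum CMB diameter must be >= 2 px")
        if hi > self.image_side / 4:
            raise ValueError("maximum CMB diameter must be <= image_side / 4")
        for p in (self.positive_fraction, self.phase_ambiguity):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass
class PhantomObject:
    kind: Literal["cmb", "calcification", "vessel"]
    center: tuple[float, float]           # (x, y)
    diameter: float
    slice_start: int
    slice_stop: int                       # exclusive
    phase_delta: float                    # signed fractional phase contrast
    phase_ambiguous: bool = False         # mimic rendered with CMB-like phase
    boxes: dict[int, Box] = field(default_factory=dict)  # slice -> rendered footprint


@dataclass
class PatientRecord:
    patient_id: str
    swi_stack: np.ndarray                 # (S, H, W) uint8, 0-255
    phase_stack: np.ndarray               # (S, H, W) uint8
    meta: PatientMeta
    gt_boxes: list[list[Box]]             # per slice, CMBs only
    objects: list[PhantomObject] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.swi_stack.shape != self.phase_stack.shape:
            raise ValueError("SWI and phase stacks must have identical shapes")
        if len(self.gt_boxes) != self.swi_stack.shape[0]:
            raise ValueError("gt_boxes must have one entry per slice")

    @property
    def n_slices(self) -> int:
        return self.swi_stack.shape[0]

    @property
    def has_cmbs(self) -> bool:
        return any(len(b) for b in self.gt_boxes)


# --- metadata model --------------------------------------------------------

_AGE_MEAN = {("cmb", "male"): 66.0, ("cmb", "female"): 64.0,
             ("neg", "male"): 57.0, ("neg", "female"): 59.0}
_MALE_FRACTION = 0.61
_AGE_SD = 9.0


def _draw_meta(rng: np.random.Generator, positive: bool, patient_id: str) -> PatientMeta:
    gender = "male" if rng.random() < _MALE_FRACTION else "female"
    key = ("cmb" if positive else "neg", gender)
    age = int(np.clip(round(rng.normal(_AGE_MEAN[key], _AGE_SD)), 18, 95))
    return PatientMeta(patient_id=patient_id, gender=gender, age=age)


def _calcification_multiplier(meta: PatientMeta, strength: float) -> float:
    """Mimic-frequency modulation: calcifications are relatively more frequent
    in younger female patients, the demographic where image-only models err."""
    z = 0.04 * (60.0 - meta.age) + (0.8 if meta.gender == "female" else -0.8)
    return float(np.exp(strength * z))


# --- rendering -------------------------------------------------------------

def _bias_field(rng: np.random.Generator, side: int, strength: float) -> np.ndarray:
    coarse = rng.standard_normal((5, 5))
    return ndimage.zoom(coarse, side / 5.0, order=3)[:side, :side] * strength


def _blob_profile(side: int, cx: float, cy: float, diameter: float) -> np.ndarray:
    """Gaussian-smoothed disk, peak 1.0, on the full image grid (local patch)."""
    r = diameter / 2.0
    pad = int(np.ceil(r)) + 4
    x0, x1 = max(0, int(cx) - pad), min(side, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(side, int(cy) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dist = np.sqrt((xx + 0.5 - cx) ** 2 + (yy + 0.5 - cy) ** 2)
    disk = (dist <= r).astype(np.float64)
    disk = ndimage.gaussian_filter(disk, sigma=1.0)
    out = np.zeros((side, side))
    out[y0:y1, x0:x1] = disk
    peak = out.max()
    return out / peak if peak > 0 else out


def _vessel_profile(side: int, cx: float, cy: float, width: float, length: float,
                    theta: float) -> np.ndarray:
    pad = int(np.ceil(length / 2)) + 4
    x0, x1 = max(0, int(cx) - pad), min(side, int(cx) + pad + 1)
    y0, y1 = max(0, int(cy) - pad), min(side, int(cy) + pad + 1)
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dx, dy = xx + 0.5 - cx, yy + 0.5 - cy
    u = dx * np.cos(theta) + dy * np.sin(theta)       # along the vessel
    v = -dx * np.sin(theta) + dy * np.cos(theta)      # across
    capsule = (np.abs(u) <= length / 2) & (np.abs(v) <= width / 2)
    prof = ndimage.gaussian_filter(capsule.astype(np.float64), sigma=1.0)
    out = np.zeros((side, side))
    out[y0:y1, x0:x1] = prof
    peak = out.max()
    return out / peak if peak > 0 else out


def _footprint_box(profile: np.ndarray, threshold: float = 0.3) -> Box | None:
    mask = profile >= threshold * profile.max() if profile.max() > 0 else None
    if mask is None or not mask.any():
        return None
    ys, xs = np.nonzero(mask)
    return Box(float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1))


def _slice_taper(span: int) -> np.ndarray:
    """Partial-volume through-plane profile: full in the middle, tapered at ends."""
    if span == 1:
        return np.array([1.0])
    t = np.ones(span)
    t[0] = t[-1] = 0.6
    return t


def _place_objects(rng: np.random.Generator, spec: PhantomSpec, meta: PatientMeta,
                   n_cmbs: int) -> list[PhantomObject]:
    side, S = spec.image_side, spec.slices_per_patient
    calc_mean = spec.calcification_rate * _calcification_multiplier(meta, spec.metadata_effect)
    n_calc = rng.poisson(calc_mean)
    n_vessel = rng.poisson(spec.vessel_rate)
    # truncate Poisson tails to what the slice area can hold without overlap
    cap = max(4, int(side * side / (3.5 * spec.cmb_diameter[1]) ** 2))
    while n_cmbs + n_calc + n_vessel > cap and n_calc + n_vessel > 0:
        if n_vessel >= n_calc:
            n_vessel -= 1
        else:
            n_calc -= 1
    n_cmbs = min(n_cmbs, cap)
    kinds = ["cmb"] * n_cmbs + ["calcification"] * n_calc + ["vessel"] * n_vessel

    objects: list[PhantomObject] = []
    taken: list[tuple[float, float, float]] = []   # (cx, cy, effective radius)
    margin = spec.cmb_diameter[1]
    attempts = 0
    for kind in kinds:
        placed = False
        while not placed:
            attempts += 1
            if attempts > 200 * max(1, len(kinds)):
                raise ValueError(
                    f"could not place {len(kinds)} non-overlapping objects on a "
                    f"{side}x{side} slice; reduce object rates or diameters"
                )
            d = float(rng.uniform(*spec.cmb_diameter))
            # rendered extent: blobs cover ~d, vessels stretch to ~2d along their axis
            r_eff = 2.2 * d if kind == "vessel" else 1.0 * d
            cx = float(rng.uniform(margin, side - margin))
            cy = float(rng.uniform(margin, side - margin))
            if any((cx - tx) ** 2 + (cy - ty) ** 2 < (r_eff + tr) ** 2
                   for tx, ty, tr in taken):
                continue
            if kind == "vessel":
                span = int(rng.integers(4, max(5, S // 2) + 1))
            else:
                span = int(rng.integers(1, 4))
            span = min(span, S)
            start = int(rng.integers(0, S - span + 1))
            ambiguous = False
            if kind == "cmb":
                delta = -float(rng.uniform(0.7, 1.3)) * spec.phase_contrast
            elif kind == "calcification":
                if rng.random() < spec.phase_ambiguity:
                    # phase-ambiguous mimic: indistinguishable from a CMB in
                    # both SWI and phase (filtering/partial-volume artefact);
                    # only patient metadata carries information about it
                    delta = -float(rng.uniform(0.7, 1.3)) * spec.phase_contrast
                    ambiguous = True
                else:
                    delta = float(rng.uniform(0.7, 1.3)) * spec.phase_contrast
            else:
                delta = -float(rng.uniform(0.4, 0.8)) * spec.phase_contrast
            objects.append(PhantomObject(kind=kind, center=(cx, cy), diameter=d,
                                         slice_start=start, slice_stop=start + span,
                                         phase_delta=delta, phase_ambiguous=ambiguous))
            taken.append((cx, cy, r_eff))
            placed = True
    return objects


def generate_patient(spec: PhantomSpec, seed: int, patient_id: str | None = None,
                     force_positive: bool | None = None) -> PatientRecord:
    """Render one patient phantom (SWI stack, phase stack, metadata, ground truth)."""
    rng = np.random.default_rng(seed)
    positive = (rng.random() < spec.positive_fraction) if force_positive is None else force_positive
    pid = patient_id or f"phantom-{seed:08d}"
    meta = _draw_meta(rng, positive, pid)
    # zero-truncated Poisson count for CMB-positive patients; a zero mean
    # disables CMBs entirely
    if positive and spec.cmb_count_mean > 0:
        n_cmbs = max(1, int(rng.poisson(spec.cmb_count_mean)))
    else:
        n_cmbs = 0
    objects = _place_objects(rng, spec, meta, n_cmbs)

    side, S = spec.image_side, spec.slices_per_patient
    bias = _bias_field(rng, side, spec.bias_field_strength)
    swi = np.empty((S, side, side), dtype=np.float64)
    phase = np.empty_like(swi)
    for s in range(S):
        swi[s] = spec.background_level + bias + rng.normal(0, spec.noise_sigma, (side, side))
        # phase images are high-pass filtered in practice: flat background, no bias field
        phase[s] = spec.background_level + rng.normal(0, spec.noise_sigma, (side, side))

    amp = spec.contrast * spec.background_level
    for obj in objects:
        cx, cy = obj.center
        if obj.kind == "vessel":
            theta = float(rng.uniform(0, np.pi))
            prof = _vessel_profile(side, cx, cy, width=max(2.0, obj.diameter / 3.0),
                                   length=obj.diameter * 2.0, theta=theta)
        else:
            prof = _blob_profile(side, cx, cy, obj.diameter)
        taper = _slice_taper(obj.slice_stop - obj.slice_start)
        for k, s in enumerate(range(obj.slice_start, obj.slice_stop)):
            swi[s] -= amp * taper[k] * prof
            phase[s] += obj.phase_delta * spec.background_level * taper[k] * prof
        box = _footprint_box(prof)
        if box is not None:
            for s in range(obj.slice_start, obj.slice_stop):
                obj.boxes[s] = box

    gt: list[list[Box]] = [[] for _ in range(S)]
    for obj in objects:
        if obj.kind == "cmb":
            for s, b in obj.boxes.items():
                gt[s].append(b)

    swi_u8 = np.clip(swi, 0, 255).astype(np.uint8)
    phase_u8 = np.clip(phase, 0, 255).astype(np.uint8)
    return PatientRecord(patient_id=pid, swi_stack=swi_u8, phase_stack=phase_u8,
                         meta=meta, gt_boxes=gt, objects=objects)


# --- dataset ---------------------------------------------------------------

def _split_sizes(n: int) -> tuple[int, int, int]:
    n_test = max(1, round(0.2 * n))
    n_val = max(1, round(0.2 * n))
    return n - n_val - n_test, n_val, n_test


def generate_dataset(spec: PhantomSpec, n: int, seed: int) -> dict:
    """Generate ``n`` patients in disjoint seeded train/val/test splits.

    Returns ``{"train": [...], "val": [...], "test": [...], "manifest": {...}}``.
    The manifest alone suffices to regenerate the dataset exactly.
    """
    if n < 3:
        raise ValueError("need at least 3 patients for a 3-way split")
    root = np.random.default_rng(seed)
    patient_seeds = [int(s) for s in root.integers(0, 2**31 - 1, size=n)]
    records = [generate_patient(spec, s, patient_id=f"p{idx:04d}")
               for idx, s in enumerate(patient_seeds)]
    n_train, n_val, n_test = _split_sizes(n)
    splits = {"train": records[:n_train],
              "val": records[n_train:n_train + n_val],
              "test": records[n_train + n_val:]}
    manifest = {
        "spec": asdict(spec),
        "n": n,
        "seed": int(seed),
        "patient_seeds": patient_seeds,
        "split_sizes": {"train": n_train, "val": n_val, "test": n_test},
        "patients": [
            {"patient_id": r.patient_id, "seed": s, "has_cmbs": bool(r.has_cmbs),
             "checksum": int(r.swi_stack.sum()) + int(r.phase_stack.sum())}
            for r, s in zip(records, patient_seeds)
        ],
    }
    return {**splits, "manifest": manifest}


def regenerate_from_manifest(manifest: dict) -> dict:
    spec_dict = dict(manifest["spec"])
    spec_dict["cmb_diameter"] = tuple(spec_dict["cmb_diameter"])
    spec = PhantomSpec(**spec_dict)
    return generate_dataset(spec, manifest["n"], manifest["seed"])
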