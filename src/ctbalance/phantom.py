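"""Synthetic imbalanced abdominal-CT cohort generator.

Real L3 body-composition datasets are clinical and private, so this module
builds phantom cohorts that reproduce the statistical structure the method
depends on, without attempting anatomical realism:

* a small minority (~5%) of slices per patient volume are flagged as L3;
* tissue pixels (SM/SAT/VAT) occupy a minority of each slice;
* tissue intensities are drawn from truncated normal distributions whose
  supports are exactly the Hounsfield-unit ranges used for post-processing
  (SM [29, 150], SAT [-150, -50], VAT [-190, -30]);
* a posterior bone feature varies smoothly along z and takes a distinct,
  wide-winged configuration on L3-flagged slices, so that a small
  classifier can genuinely learn to detect them.

Every phantom is a deterministic function of its seed: same seed, same
bits. HU values are quantized to integers (as in real CT), which also makes
the 16-bit-PNG round trip exact.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.stats import truncnorm

from .types import BACKGROUND, OTHER, SAT, SM, VAT, SegmentationMask

#: Post-processing HU support per tissue code; bone/organ/background supports
#: are package choices at plausible CT values.
HU_SUPPORT = {
    SM: (29.0, 150.0),
    SAT: (-150.0, -50.0),
    VAT: (-190.0, -30.0),
    OTHER: (-20.0, 90.0),
    BACKGROUND: (-1024.0, -950.0),
}
#: Bone pixels carry the "other" mask code but their own HU distribution.
BONE_SUPPORT = (200.0, 1200.0)

DEFAULT_HU_MEANS = {SM: 50.0, SAT: -100.0, VAT: -90.0, OTHER: 35.0, BACKGROUND: -1000.0}
DEFAULT_HU_SD = {SM: 18.0, SAT: 18.0, VAT: 25.0, OTHER: 20.0, BACKGROUND: 12.0}
BONE_HU_MEAN, BONE_HU_SD = 450.0, 130.0

#: Offset added to HU before writing unsigned 16-bit PNGs (air ~ -1000).
PNG_HU_OFFSET = 1024


@dataclass
class PhantomParams:
    """Generation parameters for one synthetic cohort.

    ``l3_fraction`` is the per-patient fraction of slices flagged L3
    (the study regime is ~0.03–0.05); it must lie in (0, 0.5).
    """

    image_size: int = 64
    slices_per_patient: int = 40
    l3_fraction: float = 0.05
    pixel_spacing_mm: float = 0.9
    tissue_hu_means: dict = field(default_factory=lambda: dict(DEFAULT_HU_MEANS))
    tissue_hu_sd: dict = field(default_factory=lambda: dict(DEFAULT_HU_SD))
    noise_sd: float = 5.0
    seed: int = 0

    def validate(self) -> None:
        if self.image_size <= 0 or self.slices_per_patient <= 0:
            raise ValueError("image_size and slices_per_patient must be positive")
        if not (0.0 < self.l3_fraction < 0.5):
            raise ValueError(f"l3_fraction must lie in (0, 0.5), got {self.l3_fraction}")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


@dataclass
class PatientVolume:
    """Ordered stack of HU slices with per-slice L3 flags and tissue masks."""

    patient_id: str
    slices: list  # list of 2-D int16 HU arrays
    l3_flags: np.ndarray  # bool per slice
    masks: list  # list of SegmentationMask, index-aligned with slices
    pixel_spacing_mm: float

    def __post_init__(self) -> None:
        self.l3_flags = np.asarray(self.l3_flags, dtype=bool)
        n = len(self.slices)
        if not (len(self.l3_flags) == n and len(self.masks) == n):
            raise ValueError("slices, l3_flags and masks must be index-aligned")
        if n and not self.l3_flags.any():
            raise ValueError("each patient must have at least one L3 slice")

    @property
    def n_slices(self) -> int:
        return len(self.slices)

    def l3_indices(self) -> np.ndarray:
        return np.flatnonzero(self.l3_flags)


def n_l3_slices(params: PhantomParams) -> int:
    """Number of L3-flagged slices per patient: round(fraction * slices), >= 1."""
    return max(1, int(round(params.l3_fraction * params.slices_per_patient)))


def _ellipse(size: int, cx: float, cy: float, ax: float, ay: float) -> np.ndarray:
    """Boolean ellipse in normalized [-1, 1] coordinates."""
    c = np.linspace(-1.0, 1.0, size)
    x, y = np.meshgrid(c, c, indexing="xy")
    return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0


def _slice_mask(
    size: int,
    z_phase: float,
    l3_weight: float,
    blob_centers: np.ndarray,
    blob_widths: np.ndarray,
    blob_drift: np.ndarray,
    z_frac: float,
) -> np.ndarray:
    """Deterministic tissue-code mask for one slice.

    Concentric geometry: SAT ring just inside the abdomen outline, SM band
    inside that, interior split between organ tissue ("other"), VAT blobs
    and a posterior bone feature. ``l3_weight`` in [0, 1] blends in the L3
    bone signature (wide transverse wings).
    """
    # Abdomen outline breathes slightly along z.
    ax = 0.88 * (1.0 + 0.03 * np.sin(z_phase))
    ay = 0.72 * (1.0 + 0.03 * np.cos(z_phase))
    abdomen = _ellipse(size, 0.0, 0.0, ax, ay)
    inner1 = _ellipse(size, 0.0, 0.0, 0.85 * ax, 0.85 * ay)  # SAT/SM interface
    inner2 = _ellipse(size, 0.0, 0.0, 0.66 * ax, 0.66 * ay)  # SM/interior interface

    mask = np.zeros((size, size), dtype=np.uint8)
    mask[abdomen & ~inner1] = SAT
    mask[inner1 & ~inner2] = SM
    mask[inner2] = OTHER

    # VAT blobs: smooth Gaussian bumps drifting slowly with z.
    c = np.linspace(-1.0, 1.0, size)
    x, y = np.meshgrid(c, c, indexing="xy")
    fld = np.zeros((size, size))
    for (bx, by), w, (dx, dy) in zip(blob_centers, blob_widths, blob_drift):
        cxz = bx + dx * z_frac
        cyz = by + dy * z_frac
        fld += np.exp(-(((x - cxz) ** 2 + (y - cyz) ** 2) / (2.0 * w**2)))
    vat = (fld > 0.55) & _ellipse(size, 0.0, 0.0, 0.60 * ax, 0.60 * ay)
    mask[vat] = VAT

    # Posterior vertebral body; transverse wings widen into the L3 signature.
    by0 = 0.40
    body = _ellipse(size, 0.0, by0, 0.13 + 0.05 * l3_weight, 0.13 + 0.02 * np.sin(z_phase))
    wing_w = 0.06 + 0.30 * l3_weight
    wing_h = 0.05 + 0.10 * l3_weight
    wings = _ellipse(size, -0.20, by0, wing_w, wing_h) | _ellipse(size, 0.20, by0, wing_w, wing_h)
    bone = (body | wings) & inner2
    mask[bone] = OTHER
    return mask, bone


def _l3_weights(n_slices: int, l3_start: int, n_l3: int) -> np.ndarray:
    """Bone-signature weight per slice: 1 on the L3 block, raised-cosine
    decay over the 3 neighbouring slices, 0 elsewhere (smooth along z)."""
    w = np.zeros(n_slices)
    w[l3_start : l3_start + n_l3] = 1.0
    ramp = 3
    for j in range(1, ramp):
        val = 0.5 * (1 + np.cos(np.pi * j / ramp)) * 0.5  # decays, stays < 1
        lo, hi = l3_start - j, l3_start + n_l3 - 1 + j
        if lo >= 0:
            w[lo] = max(w[lo], val)
        if hi < n_slices:
            w[hi] = max(w[hi], val)
    return w


def _sample_hu(
    volume_masks: np.ndarray,
    bone_masks: np.ndarray,
    params: PhantomParams,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per-pixel integer HU for a whole volume, truncated per tissue.

    Textural noise is folded into the truncated draw (total sd =
    hypot(tissue_sd, noise_sd)), so every tissue pixel stays inside its
    declared HU support exactly — no post-hoc clipping spikes.
    """
    hu = np.zeros(volume_masks.shape, dtype=np.float64)
    regions = [(volume_masks == code, code, HU_SUPPORT[code],
                params.tissue_hu_means[code], params.tissue_hu_sd[code])
               for code in (BACKGROUND, SM, SAT, VAT, OTHER)]
    # Bone overrides the organ distribution inside its footprint.
    regions.append((bone_masks, None, BONE_SUPPORT, BONE_HU_MEAN, BONE_HU_SD))
    for sel, _code, (lo, hi), mean, sd in regions:
        n = int(sel.sum())
        if n == 0:
            continue
        total_sd = float(np.hypot(sd, params.noise_sd))
        a, b = (lo - mean) / total_sd, (hi - mean) / total_sd
        hu[sel] = truncnorm.rvs(a, b, loc=mean, scale=total_sd, size=n, random_state=rng)
    out = np.rint(hu).astype(np.int16)
    return out


def generate_patient(params: PhantomParams, patient_seed: int, patient_id: str | None = None) -> PatientVolume:
    """Generate one deterministic phantom patient volume."""
    params.validate()
    rng = np.random.default_rng(patient_seed)
    s, n = params.image_size, params.slices_per_patient
    n_l3 = n_l3_slices(params)
    if n_l3 >= n:
        raise ValueError("l3_fraction/slices_per_patient give no majority class")

    margin = min(2, max(0, (n - n_l3) // 2 - 1))
    l3_start = int(rng.integers(margin, n - n_l3 - margin + 1))
    flags = np.zeros(n, dtype=bool)
    flags[l3_start : l3_start + n_l3] = True
    weights = _l3_weights(n, l3_start, n_l3)

    n_blobs = 4
    blob_centers = rng.uniform(-0.35, 0.35, size=(n_blobs, 2))
    blob_widths = rng.uniform(0.12, 0.22, size=n_blobs)
    blob_drift = rng.uniform(-0.15, 0.15, size=(n_blobs, 2))
    z_phase0 = rng.uniform(0, 2 * np.pi)

    masks_arr = np.zeros((n, s, s), dtype=np.uint8)
    bones_arr = np.zeros((n, s, s), dtype=bool)
    for i in range(n):
        z_frac = i / max(1, n - 1)
        masks_arr[i], bones_arr[i] = _slice_mask(
            s, z_phase0 + 2 * np.pi * z_frac * 0.5, weights[i],
            blob_centers, blob_widths, blob_drift, z_frac,
        )
    hu = _sample_hu(masks_arr, bones_arr, params, rng)

    pid = patient_id if patient_id is not None else f"P{patient_seed:010d}"
    masks = [
        SegmentationMask(masks_arr[i], params.pixel_spacing_mm) for i in range(n)
    ]
    return PatientVolume(pid, [hu[i] for i in range(n)], flags, masks, params.pixel_spacing_mm)


def generate_cohort(params: PhantomParams, n_patients: int, seed: int | None = None) -> list:
    """Generate ``n_patients`` phantoms with per-patient seeds derived from
    the master seed (``params.seed`` unless overridden)."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    master = params.seed if seed is None else seed
    rng = np.random.default_rng(master)
    patient_seeds = rng.integers(0, 2**31 - 1, size=n_patients)
    return [
        generate_patient(params, int(ps), patient_id=f"P{idx:04d}")
        for idx, ps in enumerate(patient_seeds)
    ]


# ---------------------------------------------------------------------------
# Cohort I/O: 16-bit grayscale PNGs (HU + offset), indexed-PNG masks,
# CSV label table, JSON sidecar.  read(write(c)) == c bit-for-bit.
# ---------------------------------------------------------------------------

_MASK_PALETTE = [0, 0, 0, 60, 80, 230, 120, 230, 120, 250, 160, 60, 180, 180, 180]


def write_cohort(cohort: list, directory) -> Path:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    rows = []
    for vol in cohort:
        pdir = d / vol.patient_id
        pdir.mkdir(exist_ok=True)
        for i, (hu, mask) in enumerate(zip(vol.slices, vol.masks)):
            enc = (hu.astype(np.int32) + PNG_HU_OFFSET).astype(np.uint16)
            Image.fromarray(enc).save(pdir / f"img_{i:04d}.png")
            m = Image.fromarray(mask.codes.astype(np.uint8), mode="P")
            m.putpalette(_MASK_PALETTE + [0] * (768 - len(_MASK_PALETTE)))
            m.save(pdir / f"mask_{i:04d}.png")
            rows.append(
                dict(patient_id=vol.patient_id, slice_index=i,
                     is_l3=bool(vol.l3_flags[i]), pixel_spacing_mm=vol.pixel_spacing_mm)
            )
    pd.DataFrame(rows).to_csv(d / "labels.csv", index=False)
    meta = {
        "hu_offset": PNG_HU_OFFSET,
        "patient_ids": [v.patient_id for v in cohort],
        "n_patients": len(cohort),
    }
    (d / "meta.json").write_text(json.dumps(meta, indent=2))
    return d


def read_cohort(directory) -> list:
    d = Path(directory)
    meta_path = d / "meta.json"
    if not meta_path.exists():
        raise FileNotFoundError(f"not a cohort directory (missing meta.json): {d}")
    meta = json.loads(meta_path.read_text())
    offset = int(meta["hu_offset"])
    labels = pd.read_csv(d / "labels.csv")
    cohort = []
    for pid in meta["patient_ids"]:
        sub = labels[labels.patient_id == pid].sort_values("slice_index")
        if sub.empty:
            raise FileNotFoundError(f"patient {pid} missing from {d / 'labels.csv'}")
        spacing = float(sub.pixel_spacing_mm.iloc[0])
        slices, masks = [], []
        for i in sub.slice_index:
            ipath = d / pid / f"img_{i:04d}.png"
            mpath = d / pid / f"mask_{i:04d}.png"
            if not ipath.exists() or not mpath.exists():
                raise FileNotFoundError(f"missing slice files for {pid} slice {i} under {d}")
            enc = np.asarray(Image.open(ipath), dtype=np.int32)
            slices.append((enc - offset).astype(np.int16))
            codes = np.asarray(Image.open(mpath), dtype=np.uint8)
            masks.append(SegmentationMask(codes, spacing))
        cohort.append(
            PatientVolume(pid, slices, sub.is_l3.to_numpy(dtype=bool), masks, spacing)
        )
    return cohort


def cohort_slice_counts(cohort: list) -> tuple[int, int]:
    """(n_l3, n_non_l3) over a cohort."""
    n_l3 = sum(int(v.l3_flags.sum()) for v in cohort)
    n_tot = sum(v.n_slices for v in cohort)
    return n_l3, n_tot - n_l3
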