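"""HU-range refinement of predicted segmentation masks.

Spatial prediction is trusted for the class choice; the calibrated
Hounsfield value of each pixel then vetoes implausible assignments. A
pixel predicted as a tissue class whose HU lies outside that tissue's
characteristic interval is reassigned — by default to "other" (code 4),
because the SAT interval is a strict subset of the VAT interval, which
makes any range-based reassignment *between* the fat classes ambiguous.
Background and "other" pixels are never touched, so the operation is
idempotent and can only shrink tissue classes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize as _sk_resize

from .types import OTHER, SAT, SM, VAT

DEFAULT_HU_RANGES = {SM: (29.0, 150.0), SAT: (-150.0, -50.0), VAT: (-190.0, -30.0)}


@dataclass
class HURangeTable:
    """Inclusive HU intervals keyed by tissue class code (1–3)."""

    ranges: dict = field(default_factory=lambda: dict(DEFAULT_HU_RANGES))

    def __post_init__(self) -> None:
        for k, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ValueError(f"empty HU interval for class {k}: [{lo}, {hi}]")

    def to_json(self) -> str:
        return json.dumps({str(k): list(v) for k, v in self.ranges.items()})

    @classmethod
    def from_json(cls, text: str) -> "HURangeTable":
        d = json.loads(text)
        return cls({int(k): tuple(v) for k, v in d.items()})


def hu_refine(predicted_codes: np.ndarray, hu: np.ndarray,
              table: HURangeTable | None = None,
              rule: str = "to_other") -> np.ndarray:
    """Veto out-of-range tissue pixels using original (un-windowed) HU.

    ``hu`` may be at the native resolution; it is nearest-neighbour
    resampled to the mask's resolution if the shapes differ.
    ``rule='to_other'`` (default) reassigns vetoed pixels to code 4;
    ``rule='nearest_valid'`` reassigns to the tissue class whose interval
    contains the HU value (ties broken by nearest interval centre), or to
    4 when no interval matches.
    """
    table = table or HURangeTable()
    pred = np.asarray(predicted_codes)
    hu = np.asarray(hu, dtype=float)
    if hu.shape != pred.shape:
        if hu.ndim != 2 or pred.ndim != 2:
            raise ValueError("masks and HU arrays must be 2-D")
        hu = _sk_resize(hu, pred.shape, order=0, anti_aliasing=False, preserve_range=True)
    out = pred.copy()
    for cls, (lo, hi) in table.ranges.items():
        bad = (pred == cls) & ((hu < lo) | (hu > hi))
        if not bad.any():
            continue
        if rule == "to_other":
            out[bad] = OTHER
        elif rule == "nearest_valid":
            out[bad] = _nearest_valid(hu[bad], table)
        else:
            raise ValueError(f"unknown rule {rule!r}")
    return out


def _nearest_valid(hu_vals: np.ndarray, table: HURangeTable) -> np.ndarray:
    classes = sorted(table.ranges)
    centres = np.array([np.mean(table.ranges[k]) for k in classes])
    contains = np.stack([(hu_vals >= table.ranges[k][0]) & (hu_vals <= table.ranges[k][1])
                         for k in classes])  # (K, n)
    dist = np.abs(hu_vals[None, :] - centres[:, None])
    dist[~contains] = np.inf
    best = np.argmin(dist, axis=0)
    out = np.array(classes, dtype=np.asarray(list(classes)).dtype)[best]
    none_match = ~contains.any(axis=0)
    out = np.where(none_match, OTHER, out)
    return out.astype(np.uint8)
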