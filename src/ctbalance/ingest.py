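"""Thin readers for clinical image formats (NIfTI volumes, DICOM series).

These return plain HU slice stacks plus pixel spacing; combine them with a
per-slice label table (``patient_id, slice_index, is_l3``) to build a
:class:`~ctbalance.phantom.PatientVolume` for the detection pipeline.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np


def load_nifti_volume(path) -> tuple:
    """Load a NIfTI volume as (slices, pixel_spacing_mm); axial slices along
    the last axis, values assumed to already be in HU."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()
    spacing = float(zooms[0])
    slices = [np.asarray(data[:, :, i]) for i in range(data.shape[2])]
    return slices, spacing


def load_dicom_series(directory) -> tuple:
    """Load a single-series DICOM directory as (slices, pixel_spacing_mm).

    Slices are ordered by InstanceNumber and rescaled to HU via
    RescaleSlope/RescaleIntercept.
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files under {directory}")
    datasets = [pydicom.dcmread(str(f)) for f in files]
    datasets.sort(key=lambda d: int(getattr(d, "InstanceNumber", 0)))
    spacing = float(datasets[0].PixelSpacing[0])
    slices = []
    for d in datasets:
        arr = d.pixel_array.astype(np.float64)
        slope = float(getattr(d, "RescaleSlope", 1.0))
        intercept = float(getattr(d, "RescaleIntercept", 0.0))
        slices.append(arr * slope + intercept)
    return slices, spacing
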