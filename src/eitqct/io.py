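"""Readers and writers for the pipeline's file formats.

Waveforms travel as CSV with a required ``time_s, impedance`` header; frame
stacks, HU volumes, masks and displacement fields as NIfTI (displacements as
a 4-D vector image in mm); cohort tables as one-row-per-subject CSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .ct_functional import DisplacementField, HUVolume
from .eit_signal import EITFrameSequence, ImpedanceSeries

WAVEFORM_COLUMNS = ("time_s", "impedance")

#: Relative tolerance on timestamp gaps before a waveform counts as
#: non-uniformly sampled.
UNIFORMITY_RTOL = 1e-6


def write_waveform_csv(series: ImpedanceSeries, path) -> None:
    df = pd.DataFrame({"time_s": series.times_s, "impedance": series.values})
    df.to_csv(path, index=False)


def read_waveform_csv(path, plane_label: Optional[str] = None) -> ImpedanceSeries:
    """Load a waveform CSV, enforcing the header and uniform sampling."""
    df = pd.read_csv(path)
    missing = set(WAVEFORM_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: waveform CSV is missing columns {sorted(missing)}")
    if len(df) < 2:
        raise ValueError(f"{path}: waveform needs at least 2 samples")
    t = df["time_s"].to_numpy(dtype=float)
    gaps = np.diff(t)
    if np.any(gaps <= 0):
        raise ValueError(f"{path}: timestamps are not strictly increasing")
    dt = float(np.median(gaps))
    worst = float(np.max(np.abs(gaps - dt)))
    if worst > UNIFORMITY_RTOL * dt + 1e-12:
        raise ValueError(
            f"{path}: non-uniform sampling, max timestamp gap deviation {worst:g} s "
            f"against median step {dt:g} s"
        )
    return ImpedanceSeries(values=df["impedance"].to_numpy(dtype=float),
                           sample_rate_hz=1.0 / dt, plane_label=plane_label)


def _identity_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def write_hu_volume(vol: HUVolume, path, mask_path=None) -> None:
    nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32),
                             _identity_affine(vol.spacing)), str(path))
    if mask_path is not None:
        nib.save(nib.Nifti1Image(vol.lung_mask.astype(np.uint8),
                                 _identity_affine(vol.spacing)), str(mask_path))


def read_hu_volume(path, mask_path=None) -> HUVolume:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    voxels = np.asarray(img.dataobj, dtype=float)
    if mask_path is not None:
        mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    else:
        mask = np.ones(voxels.shape, dtype=bool)
    return HUVolume(voxels=voxels, spacing=spacing, lung_mask=mask)


def write_displacement_field(field: DisplacementField, path) -> None:
    nib.save(nib.Nifti1Image(field.u.astype(np.float32),
                             _identity_affine(field.spacing)), str(path))


def read_displacement_field(path) -> DisplacementField:
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    u = np.asarray(img.dataobj, dtype=float)
    return DisplacementField(u=u, spacing=spacing)


def write_frame_sequence(seq: EITFrameSequence, path, mask_path) -> None:
    # stored (row, col, time) so the grid occupies the spatial axes
    data = np.moveaxis(seq.frames, 0, -1).astype(np.float32)
    aff = np.eye(4)
    nib.save(nib.Nifti1Image(data, aff), str(path))
    nib.save(nib.Nifti1Image(seq.roi_mask.astype(np.uint8), aff), str(mask_path))


def read_frame_sequence(path, mask_path, sample_rate_hz: float,
                        plane_label: Optional[str] = None) -> EITFrameSequence:
    data = np.asarray(nib.load(str(path)).dataobj, dtype=float)
    frames = np.moveaxis(data, -1, 0)
    mask = np.asarray(nib.load(str(mask_path)).dataobj) > 0
    return EITFrameSequence(frames=frames, sample_rate_hz=sample_rate_hz,
                            roi_mask=mask, plane_label=plane_label)
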