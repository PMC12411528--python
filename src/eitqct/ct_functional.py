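"""Parenchymal functional metrics from HU volumes and displacement fields.

Two families of regional lung-function surrogates are computed:

* **Attenuation classes.**  On a lung-masked HU volume, voxels below
  -950 HU are counted as emphysema-like low attenuation (Emph%) and voxels
  in [-950, -856) HU as functional small-airway disease / air trapping
  (fSAD%); the half-open convention makes the three classes a counting
  partition of the mask.

* **Deformation metrics.**  From the exhale-to-inhale (FRC -> TLC)
  displacement field u(x), the deformation gradient F = I + grad(u) is formed
  by spacing-aware central differences (one-sided at the grid boundary).
  The per-voxel Jacobian det(F) = lambda1 * lambda2 * lambda3 measures local
  volume expansion; the anisotropic deformation index

      ADI = sqrt(((l1 - l2) / l2)^2 + ((l2 - l3) / l3)^2)

  with principal stretches l1 >= l2 >= l3 (square roots of the eigenvalues
  of F^T F) measures how directionally non-uniform the expansion is.  ADI is
  zero for isotropic expansion and invariant to rigid rotations.  Voxels with
  non-positive Jacobian ("folding") are flagged and excluded from summaries,
  never clipped.

CT-based inspiratory capacity is the masked lung volume at TLC minus that at
FRC, in liters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "HUVolume",
    "DisplacementField",
    "DeformationMetrics",
    "classify_parenchyma",
    "deformation_gradient",
    "principal_stretches",
    "jacobian_field",
    "adi_field",
    "compute_deformation_metrics",
    "inspiratory_capacity",
    "summarize_by_lobe",
    "EMPH_THRESHOLD_HU",
    "FSAD_THRESHOLD_HU",
]

EMPH_THRESHOLD_HU = -950.0
FSAD_THRESHOLD_HU = -856.0


@dataclass
class HUVolume:
    """HU values on a regular grid with a lung mask and optional lobe labels."""

    voxels: np.ndarray
    spacing: Tuple[float, float, float]
    lung_mask: np.ndarray
    lobe_labels: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        self.lung_mask = np.asarray(self.lung_mask, dtype=bool)
        if self.lung_mask.shape != self.voxels.shape:
            raise ValueError("lung_mask shape must match voxel shape")
        if self.lobe_labels is not None and np.shape(self.lobe_labels) != self.voxels.shape:
            raise ValueError("lobe_labels shape must match voxel shape")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors (mm) on a regular grid."""

    u: np.ndarray  # (nx, ny, nz, 3)
    spacing: Tuple[float, float, float]
    valid_mask: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.u = np.asarray(self.u, dtype=float)
        if self.u.ndim != 4 or self.u.shape[-1] != 3:
            raise ValueError("displacement field must have shape (nx, ny, nz, 3)")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("displacement field contains non-finite values")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if self.valid_mask is not None and self.valid_mask.shape != self.u.shape[:3]:
            raise ValueError("valid_mask shape must match the field grid")


@dataclass
class DeformationMetrics:
    """Per-voxel Jacobian, sorted principal stretches and ADI."""

    jacobian: np.ndarray
    stretches: np.ndarray  # (..., 3), descending
    adi: np.ndarray
    fold_mask: np.ndarray  # det(F) <= 0
    boundary_mask: np.ndarray  # one-sided-difference voxels

    @property
    def n_folded(self) -> int:
        return int(self.fold_mask.sum())


def classify_parenchyma(vol: HUVolume,
                        emph_threshold: float = EMPH_THRESHOLD_HU,
                        fsad_threshold: float = FSAD_THRESHOLD_HU) -> pd.DataFrame:
    """Emph% / fSAD% per lobe (when labeled) and for the whole lung.

    Emph% = 100 |{HU < emph_threshold}| / |mask|; fSAD% = 100
    |{emph_threshold <= HU < fsad_threshold}| / |mask|.  The remainder column
    completes the partition to exactly 100%.
    """
    if not vol.lung_mask.any():
        raise ValueError("lung mask is empty")
    if not emph_threshold < fsad_threshold:
        raise ValueError(
            f"thresholds must be ordered emph < fsad, got {emph_threshold}, {fsad_threshold}"
        )

    def _row(region: str, sel: np.ndarray) -> dict:
        hu = vol.voxels[sel]
        n = hu.size
        n_emph = int((hu < emph_threshold).sum())
        n_fsad = int(((hu >= emph_threshold) & (hu < fsad_threshold)).sum())
        return {
            "region": region,
            "n_voxels": n,
            "emph_pct": 100.0 * n_emph / n,
            "fsad_pct": 100.0 * n_fsad / n,
            "normal_pct": 100.0 * (n - n_emph - n_fsad) / n,
        }

    rows = []
    if vol.lobe_labels is not None:
        labels = np.asarray(vol.lobe_labels)
        for lobe in pd.unique(labels[vol.lung_mask]):
            rows.append(_row(str(lobe), vol.lung_mask & (labels == lobe)))
    rows.append(_row("total", vol.lung_mask))
    return pd.DataFrame(rows)


def deformation_gradient(field: DisplacementField) -> np.ndarray:
    """Per-voxel deformation gradient F = I + grad(u), shape (..., 3, 3).

    Central differences in physical units; one-sided at the boundary.
    """
    if any(n < 3 for n in field.u.shape[:3]):
        raise ValueError(f"grid must be >= 3 voxels per axis, got {field.u.shape[:3]}")
    shape = field.u.shape[:3]
    F = np.zeros(shape + (3, 3))
    for i in range(3):
        grads = np.gradient(field.u[..., i], *field.spacing, edge_order=1)
        for j in range(3):
            F[..., i, j] = grads[j]
    F[..., 0, 0] += 1.0
    F[..., 1, 1] += 1.0
    F[..., 2, 2] += 1.0
    return F


def principal_stretches(F: np.ndarray) -> np.ndarray:
    """Sorted (descending) principal stretches: sqrt of eigenvalues of F^T F."""
    C = np.einsum("...ki,...kj->...ij", F, F)
    eigs = np.linalg.eigvalsh(C)  # ascending
    eigs = np.clip(eigs, 0.0, None)
    return np.sqrt(eigs[..., ::-1])


def jacobian_field(F: np.ndarray) -> np.ndarray:
    """Per-voxel det(F); non-positive values indicate grid folding."""
    return np.linalg.det(F)


def adi_field(stretches: np.ndarray) -> np.ndarray:
    """Anisotropic deformation index from sorted principal stretches.

    Input order does not matter: stretches are re-sorted descending.  Voxels
    with non-positive lambda2 or lambda3 yield NaN (rejected, not clipped).
    """
    s = np.sort(np.asarray(stretches, dtype=float), axis=-1)[..., ::-1]
    l1, l2, l3 = s[..., 0], s[..., 1], s[..., 2]
    with np.errstate(divide="ignore", invalid="ignore"):
        adi = np.sqrt(((l1 - l2) / l2) ** 2 + ((l2 - l3) / l3) ** 2)
    adi = np.where((l2 > 0) & (l3 > 0), adi, np.nan)
    return adi


def compute_deformation_metrics(field: DisplacementField) -> DeformationMetrics:
    """Jacobian, principal stretches and ADI for a displacement field."""
    F = deformation_gradient(field)
    jac = jacobian_field(F)
    stretches = principal_stretches(F)
    adi = adi_field(stretches)
    fold = jac <= 0
    boundary = np.zeros(field.u.shape[:3], dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        sl[ax] = 0
        boundary[tuple(sl)] = True
        sl[ax] = -1
        boundary[tuple(sl)] = True
    return DeformationMetrics(jacobian=jac, stretches=stretches, adi=adi,
                              fold_mask=fold, boundary_mask=boundary)


def inspiratory_capacity(tlc: HUVolume, frc: HUVolume) -> float:
    """CT-based inspiratory capacity: masked TLC volume minus FRC volume (L)."""
    for name, vol in (("TLC", tlc), ("FRC", frc)):
        if not vol.lung_mask.any():
            raise ValueError(f"{name} lung mask is empty")
    tlc_l = tlc.lung_mask.sum() * tlc.voxel_volume_mm3 * 1e-6
    frc_l = frc.lung_mask.sum() * frc.voxel_volume_mm3 * 1e-6
    return float(tlc_l - frc_l)


def summarize_by_lobe(values: np.ndarray,
                      lobe_labels: Optional[np.ndarray],
                      mask: np.ndarray,
                      exclude_mask: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Per-lobe and whole-lung mean/median of a per-voxel metric.

    ``exclude_mask`` removes flagged voxels (folding, boundary) from the
    summaries; the number excluded is reported per region.
    """
    values = np.asarray(values, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if values.shape != mask.shape:
        raise ValueError("metric and mask shapes differ")
    if lobe_labels is not None and np.shape(lobe_labels) != values.shape:
        raise ValueError("lobe label shape does not match the metric grid")
    keep = mask.copy()
    if exclude_mask is not None:
        keep &= ~np.asarray(exclude_mask, dtype=bool)
    keep &= np.isfinite(values)

    def _row(region: str, sel_region: np.ndarray) -> dict:
        sel = sel_region & keep
        n_excluded = int((sel_region & mask).sum() - sel.sum())
        v = values[sel]
        return {
            "region": region,
            "n_voxels": int(sel.sum()),
            "n_excluded": n_excluded,
            "mean": float(v.mean()) if v.size else np.nan,
            "median": float(np.median(v)) if v.size else np.nan,
        }

    rows = []
    if lobe_labels is not None:
        labels = np.asarray(lobe_labels)
        if not np.all(labels[mask] != None):  # noqa: E711 - object arrays
            raise ValueError("lobe labels do not cover the lung mask")
        for lobe in pd.unique(labels[mask]):
            rows.append(_row(str(lobe), mask & (labels == lobe)))
    rows.append(_row("total", np.ones_like(mask)))
    return pd.DataFrame(rows)
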