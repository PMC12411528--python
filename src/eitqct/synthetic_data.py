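"""Synthetic inputs with known ground truth for every pipeline stage.

The generators emulate the statistical structure the analysis assumes:

* tidal-breathing impedance waveforms with distinct respiratory (< 25 cpm)
  and cardiac (40-100 cpm) spectral peaks, controllable exhale/inhale
  asymmetry, slow baseline drift, and white Gaussian noise;
* 32x32-style EIT frame sequences whose in-mask sum reproduces a waveform;
* HU volumes with exactly prescribed emphysema-like (< -950 HU) and
  air-trapping (-950 to -856 HU) voxel fractions;
* displacement fields with analytically known Jacobian and principal
  stretches;
* cohort tables with prescribed monotone couplings between variables.

Each breath cycle is a raised-cosine rise over the first 1/(1+r) of the
period followed by a raised-cosine decay over the remaining r/(1+r), where
r is the target exhalation-to-inhalation area ratio.  Both limbs have mean
height exactly half the tidal amplitude, so the per-cycle exhale/inhale area
ratio equals r analytically while the slope declines gradually through
expiration, as seen in obstructed breathing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ct_functional import DisplacementField, HUVolume
from .eit_signal import EITFrameSequence, ImpedanceSeries

__all__ = [
    "BreathWaveformSpec",
    "WaveformTruth",
    "SyntheticWaveform",
    "CohortSpec",
    "generate_breath_waveform",
    "generate_frame_sequence",
    "generate_hu_volume",
    "generate_affine_displacement",
    "generate_rotation_displacement",
    "generate_cohort",
    "DEFAULT_EIT_VARIABLES",
    "DEFAULT_CT_VARIABLES",
]

#: Drift frequency in cycles/min; below the 2 cpm respiration-band floor by
#: construction so drift never contaminates band integrals.
DRIFT_RATE_CPM = 1.0

EMPH_THRESHOLD_HU = -950.0
FSAD_THRESHOLD_HU = -856.0
LOBE_NAMES = ("RUL", "RML", "RLL", "LUL", "LLL")


@dataclass
class BreathWaveformSpec:
    """Parameters of one synthetic tidal-breathing recording.

    Defaults follow a resting adult monitored by a 10 fps EIT system for a
    stable period of at least 60 s: respiratory rate 12 cpm, heart rate
    70 cpm, cardiac impedance amplitude 10% of tidal.
    """

    duration_s: float = 90.0
    sample_rate_hz: float = 10.0
    respiratory_rate_cpm: float = 12.0
    cardiac_rate_cpm: float = 70.0
    cardiac_amplitude_fraction: float = 0.10
    ei_ratio_target: float = 2.0
    tidal_amplitude: float = 1.0
    baseline_drift_amplitude: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        nyq_cpm = self.sample_rate_hz * 60.0 / 2.0
        if self.cardiac_rate_cpm >= nyq_cpm:
            raise ValueError(
                f"cardiac rate {self.cardiac_rate_cpm} cpm violates the Nyquist limit "
                f"{nyq_cpm} cpm at {self.sample_rate_hz} Hz"
            )
        if self.respiratory_rate_cpm >= self.cardiac_rate_cpm:
            raise ValueError(
                f"respiratory rate {self.respiratory_rate_cpm} cpm must be below the "
                f"cardiac rate {self.cardiac_rate_cpm} cpm"
            )
        if self.ei_ratio_target <= 0:
            raise ValueError(f"ei_ratio_target must be positive, got {self.ei_ratio_target}")
        min_duration = 2 * 60.0 / self.respiratory_rate_cpm
        if self.duration_s <= min_duration:
            raise ValueError(
                f"duration {self.duration_s} s must exceed two breath periods "
                f"({min_duration:.1f} s)"
            )
        if self.tidal_amplitude <= 0:
            raise ValueError("tidal_amplitude must be positive")


@dataclass
class WaveformTruth:
    """Ground-truth labels attached to a generated waveform."""

    cycle_start_times_s: np.ndarray
    ei_ratio: float
    respiratory_rate_cpm: float
    cardiac_rate_cpm: float
    cardiac_amplitude: float
    tidal_amplitude: float


@dataclass
class SyntheticWaveform:
    series: ImpedanceSeries
    truth: WaveformTruth


def _breath_template(phase: np.ndarray, r: float) -> np.ndarray:
    """Piecewise-linear breath cycle on phase in [0, 1); peak height 1.

    Linear rise over [0, 1/(1+r)), linear decay over [1/(1+r), 1).  With
    equal peak height the limb areas are proportional to the limb durations,
    so the exhale/inhale area ratio equals r analytically, and the sharp
    peak/trough corners are localizable to sub-sample precision by the
    analysis stage.
    """
    fi = 1.0 / (1.0 + r)
    rise = phase < fi
    out = np.empty_like(phase)
    out[rise] = phase[rise] / fi
    out[~rise] = (1.0 - phase[~rise]) / (1.0 - fi)
    return out


def generate_breath_waveform(spec: BreathWaveformSpec) -> SyntheticWaveform:
    """Synthesize a tidal-breathing global impedance waveform.

    The output is the sum of the periodic asymmetric breath shape, a cardiac
    sinusoid, a slow sinusoidal drift (1 cpm) and white Gaussian noise, with
    ground-truth cycle boundaries, E:I ratio and rates attached.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    t = np.arange(n) / spec.sample_rate_hz
    period_s = 60.0 / spec.respiratory_rate_cpm
    phase = (t / period_s) % 1.0
    breath = spec.tidal_amplitude * _breath_template(phase, spec.ei_ratio_target)
    cardiac_amp = spec.cardiac_amplitude_fraction * spec.tidal_amplitude
    cardiac = cardiac_amp * np.sin(2 * np.pi * spec.cardiac_rate_cpm / 60.0 * t)
    drift_phase = rng.uniform(0, 2 * np.pi)
    drift = spec.baseline_drift_amplitude * np.sin(2 * np.pi * DRIFT_RATE_CPM / 60.0 * t
                                                   + drift_phase)
    noise = rng.normal(0.0, spec.noise_sd, size=n) if spec.noise_sd > 0 else 0.0
    values = breath + cardiac + drift + noise
    series = ImpedanceSeries(values=values, sample_rate_hz=spec.sample_rate_hz)
    truth = WaveformTruth(
        cycle_start_times_s=np.arange(0.0, spec.duration_s, period_s),
        ei_ratio=spec.ei_ratio_target,
        respiratory_rate_cpm=spec.respiratory_rate_cpm,
        cardiac_rate_cpm=spec.cardiac_rate_cpm,
        cardiac_amplitude=cardiac_amp,
        tidal_amplitude=spec.tidal_amplitude,
    )
    return SyntheticWaveform(series=series, truth=truth)


def generate_frame_sequence(spec: BreathWaveformSpec, grid_side: int = 32,
                            mask_fraction: float = 0.5,
                            plane_label: Optional[str] = None) -> Tuple[EITFrameSequence, SyntheticWaveform]:
    """Frame stack whose in-mask sum equals a generated breath waveform.

    A fixed smooth spatial pattern (normalized to unit in-mask sum) is
    modulated by the temporal waveform; out-of-mask pixels carry independent
    Gaussian noise with the spec's noise_sd.
    """
    if grid_side < 4:
        raise ValueError(f"grid_side must be >= 4, got {grid_side}")
    if not (0.0 < mask_fraction <= 1.0):
        raise ValueError(f"mask_fraction must be in (0, 1], got {mask_fraction}")
    wf = generate_breath_waveform(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1]))
    yy, xx = np.mgrid[0:grid_side, 0:grid_side]
    c = (grid_side - 1) / 2.0
    r2 = (xx - c) ** 2 + (yy - c) ** 2
    # radial quantile keeps the masked pixel count at mask_fraction of the grid
    radius2 = np.quantile(r2, mask_fraction)
    mask = r2 <= radius2
    if not mask.any():
        mask[int(c), int(c)] = True
    pattern = np.exp(-r2 / (2.0 * (grid_side / 4.0) ** 2))
    pattern = np.where(mask, pattern, 0.0)
    pattern /= pattern[mask].sum()
    frames = wf.series.values[:, None, None] * pattern[None, :, :]
    if spec.noise_sd > 0:
        outside = ~mask
        noise = rng.normal(0.0, spec.noise_sd, size=frames.shape)
        frames = frames + np.where(outside[None, :, :], noise, 0.0)
    seq = EITFrameSequence(frames=frames, sample_rate_hz=spec.sample_rate_hz,
                           roi_mask=mask, plane_label=plane_label)
    return seq, wf


def generate_hu_volume(shape: Tuple[int, int, int] = (24, 24, 24),
                       emph_fraction: float = 0.0,
                       fsad_fraction: float = 0.0,
                       seed: int = 0,
                       spacing: Tuple[float, float, float] = (1.5, 1.5, 1.5),
                       with_lobes: bool = False) -> HUVolume:
    """Lung volume with exactly prescribed sub-threshold voxel fractions.

    Exactly ``round(emph_fraction * n_lung)`` voxels draw HU uniformly from
    [-1024, -951] (< -950), ``round(fsad_fraction * n_lung)`` further voxels
    from [-950, -857] and the remainder from [-856, -500]; only class
    membership matters downstream, so uniform within-class draws suffice.
    """
    if emph_fraction < 0 or fsad_fraction < 0:
        raise ValueError("fractions must be non-negative")
    if emph_fraction + fsad_fraction > 1:
        raise ValueError(
            f"emph_fraction + fsad_fraction = {emph_fraction + fsad_fraction:g} exceeds 1"
        )
    rng = np.random.default_rng(seed)
    mask = np.ones(shape, dtype=bool)
    n_lung = int(mask.sum())
    n_emph = int(round(emph_fraction * n_lung))
    n_fsad = int(round(fsad_fraction * n_lung))
    hu = rng.uniform(FSAD_THRESHOLD_HU, -500.0, size=n_lung)
    order = rng.permutation(n_lung)
    hu[order[:n_emph]] = rng.uniform(-1024.0, EMPH_THRESHOLD_HU - 1.0, size=n_emph)
    hu[order[n_emph:n_emph + n_fsad]] = rng.uniform(EMPH_THRESHOLD_HU, FSAD_THRESHOLD_HU - 1.0,
                                                    size=n_fsad)
    voxels = np.zeros(shape, dtype=float)
    voxels[mask] = hu
    lobes = None
    if with_lobes:
        lobes = np.empty(shape, dtype=object)
        edges = np.linspace(0, shape[2], len(LOBE_NAMES) + 1).astype(int)
        for name, lo, hi in zip(LOBE_NAMES, edges[:-1], edges[1:]):
            lobes[:, :, lo:hi] = name
    return HUVolume(voxels=voxels, spacing=spacing, lung_mask=mask, lobe_labels=lobes)


@dataclass
class AffineTruth:
    """Analytic deformation metrics of an affine displacement field."""

    jacobian: float
    stretches: Tuple[float, float, float]  # sorted descending


def generate_affine_displacement(shape: Tuple[int, int, int],
                                 scales: Tuple[float, float, float],
                                 spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0)
                                 ) -> Tuple[DisplacementField, AffineTruth]:
    """Displacement u(x) = (S - I) x for diagonal S = diag(scales).

    The analytic Jacobian is the product of the scales everywhere and the
    principal stretches are the sorted scales.
    """
    scales = tuple(float(s) for s in scales)
    if any(s <= 0 for s in scales):
        raise ValueError(f"scales must be positive, got {scales}")
    coords = [np.arange(n) * sp for n, sp in zip(shape, spacing)]
    grids = np.meshgrid(*coords, indexing="ij")
    u = np.stack([(s - 1.0) * g for s, g in zip(scales, grids)], axis=-1)
    fld = DisplacementField(u=u, spacing=spacing)
    truth = AffineTruth(jacobian=float(np.prod(scales)),
                        stretches=tuple(sorted(scales, reverse=True)))
    return fld, truth


def generate_rotation_displacement(shape: Tuple[int, int, int],
                                   angle_rad: float,
                                   spacing: Tuple[float, float, float] = (1.0, 1.0, 1.0),
                                   pre_scales: Optional[Tuple[float, float, float]] = None
                                   ) -> DisplacementField:
    """Displacement u(x) = (R S - I) x: optional diagonal stretch then a rigid
    rotation about the z axis.  With ``pre_scales=None`` the field is a pure
    isometry (stretches all 1)."""
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    mat = rot if pre_scales is None else rot @ np.diag(pre_scales)
    coords = [np.arange(n) * sp for n, sp in zip(shape, spacing)]
    grids = np.meshgrid(*coords, indexing="ij")
    x = np.stack(grids, axis=-1)
    u = x @ (mat - np.eye(3)).T
    return DisplacementField(u=u, spacing=spacing)


#: Default variable panels for synthetic cohorts, named with the U-/M-/L-
#: plane prefixes used throughout the outputs.
DEFAULT_EIT_VARIABLES: Dict[str, Tuple[float, float]] = {
    "U-Low": (5.0, 20.0),
    "U-High": (0.5, 4.0),
    "U-Perfusion": (0.2, 2.0),
    "U-EI": (1.0, 5.0),
    "U-Skewness": (-0.2, 0.8),
    "M-EI": (1.0, 5.0),
    "L-Skewness": (-0.2, 0.8),
}
DEFAULT_CT_VARIABLES: Dict[str, Tuple[float, float]] = {
    "Dh_norm": (0.6, 1.2),
    "WT_norm": (0.8, 1.4),
    "Emph_pct": (0.0, 10.0),
    "fSAD_pct": (5.0, 35.0),
    "Jacobian": (1.2, 2.5),
    "ADI": (0.2, 1.2),
    "IC_L": (1.5, 3.5),
}


@dataclass
class CohortSpec:
    """Synthetic cohort with prescribed monotone inter-variable couplings.

    ``couplings`` maps (x_variable, y_variable) to -1, 0 or +1: +/-1 draws
    the y variable as a strictly monotone transform of x (sample Spearman rho
    exactly +/-1), 0 leaves the pair independent.
    """

    n_subjects: int = 6
    couplings: Mapping[Tuple[str, str], int] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValueError(f"n_subjects must be >= 3, got {self.n_subjects}")
        for pair, sign in self.couplings.items():
            if sign not in (-1, 0, 1):
                raise ValueError(f"coupling sign for {pair} must be -1, 0 or +1, got {sign}")


def generate_cohort(spec: CohortSpec) -> Tuple[pd.DataFrame, Dict[Tuple[str, str], int]]:
    """Per-subject variable table with prescribed monotone couplings.

    Returns the cohort table (one row per subject) and the ground-truth
    coupling signs.  Uncoupled variables are independent uniform draws within
    physiologically plausible ranges.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ranges = {**DEFAULT_EIT_VARIABLES, **DEFAULT_CT_VARIABLES}
    for x, y in spec.couplings:
        ranges.setdefault(x, (0.0, 1.0))
        ranges.setdefault(y, (0.0, 1.0))

    unit: Dict[str, np.ndarray] = {}
    coupled_to: Dict[str, Tuple[str, int]] = {
        y: (x, s) for (x, y), s in spec.couplings.items() if s != 0
    }

    def draw(name: str, stack: Tuple[str, ...] = ()) -> np.ndarray:
        if name in unit:
            return unit[name]
        if name in coupled_to and name not in stack:
            src, sign = coupled_to[name]
            base = draw(src, stack + (name,))
            u = base if sign > 0 else 1.0 - base
        else:
            u = rng.uniform(0.0, 1.0, size=spec.n_subjects)
        unit[name] = u
        return u

    data = {"subject": [f"S{i + 1}" for i in range(spec.n_subjects)]}
    for name, (lo, hi) in ranges.items():
        data[name] = lo + (hi - lo) * draw(name)
    return pd.DataFrame(data), dict(spec.couplings)
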