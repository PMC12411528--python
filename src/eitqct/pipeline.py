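"""End-to-end orchestration: inputs -> per-stage CSVs -> association table.

Three run modes share the same analysis path:

* ``synthetic_cohort`` — draw a cohort table with prescribed monotone
  couplings and correlate it (the fastest way to exercise the statistical
  stage with known ground truth);
* ``synthetic_full`` — simulate each subject's EIT waveforms (three
  anatomical planes), HU volumes, displacement field and TLC/FRC masks, run
  every analysis stage, then correlate the resulting per-subject variables;
* ``data`` — consume user-supplied waveform CSVs (one per subject-plane)
  plus a per-subject CT variable table.

Every run writes stage CSVs, the long-format association table and a
``manifest.json`` recording the configuration, its hash and per-stage
bookkeeping, so each number in the association table is traceable to a
stage file.  All randomness flows from the single root seed, split per
stage; outputs are byte-identical across reruns of the same configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import correlation_matrix
from .breath_hysteresis import analyze_breaths, summarize_hysteresis
from .ct_functional import (HUVolume, classify_parenchyma, compute_deformation_metrics,
                            inspiratory_capacity, summarize_by_lobe)
from .eit_signal import (ImpedanceSeries, compute_spectrum, peak_respiratory_frequency,
                         select_stable_window, split_ventilation_perfusion)
from .io import read_waveform_csv, write_waveform_csv
from .synthetic_data import (BreathWaveformSpec, CohortSpec, generate_affine_displacement,
                             generate_breath_waveform, generate_cohort, generate_hu_volume)

logger = logging.getLogger("eitqct.pipeline")

PLANES = ("U", "M", "L")
PLANE_NAMES = {"U": "upper", "M": "middle", "L": "lower"}


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run."""

    mode: str = "synthetic_cohort"
    outdir: str = "run_out"
    seed: int = 0
    n_subjects: int = 6
    couplings: List[Tuple[str, str, int]] = field(default_factory=list)
    band_mode: str = "fixed_40cpm"
    window_s: float = 60.0
    min_prominence_frac: float = 0.2
    min_cycle_s: float = 1.5
    hu_emph_threshold: float = -950.0
    hu_fsad_threshold: float = -856.0
    ci_method: str = "fisher_z"
    p_method: str = "auto"
    alpha: float = 0.01
    waveform_manifest: Optional[str] = None  # data mode: CSV subject,plane,path
    ct_table: Optional[str] = None  # data mode: CSV subject,<CT variables...>

    def validate(self) -> None:
        if self.mode not in ("synthetic_cohort", "synthetic_full", "data"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if not self.hu_emph_threshold < self.hu_fsad_threshold:
            raise ValueError(
                f"HU thresholds must be ordered emph < fsad, got "
                f"{self.hu_emph_threshold}, {self.hu_fsad_threshold}"
            )
        if self.band_mode not in ("fixed_40cpm", "adaptive_2p5x"):
            raise ValueError(f"unknown band_mode {self.band_mode!r}")
        if self.mode == "data":
            for label, p in (("waveform_manifest", self.waveform_manifest),
                             ("ct_table", self.ct_table)):
                if p is None:
                    raise ValueError(f"data mode requires {label}")
                if not Path(p).exists():
                    raise ValueError(f"{label} path does not exist: {p}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "couplings" in raw:
            raw["couplings"] = [tuple(c) for c in raw["couplings"]]
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def canonical_json(self) -> str:
        d = asdict(self)
        d["couplings"] = [list(c) for c in d["couplings"]]
        return json.dumps(d, sort_keys=True)

    def sha256(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()


def validate_inputs(paths: Mapping[str, str]) -> pd.DataFrame:
    """Report-only validation of input files; never mutates anything.

    ``paths`` maps a role (``waveform_csv``, ``cohort_csv``, generic
    ``file``) to a path; each row of the report carries pass/fail and an
    actionable message.
    """
    rows = []
    for role, p in paths.items():
        path = Path(p)
        if not path.exists():
            rows.append({"role": role, "path": str(p), "ok": False,
                         "message": f"path does not exist: {p}"})
            continue
        try:
            if role.startswith("waveform"):
                read_waveform_csv(path)
                msg = "ok"
            elif role.startswith("cohort") or role.startswith("ct"):
                df = pd.read_csv(path)
                if "subject" not in df.columns:
                    raise ValueError(f"{p}: missing required 'subject' column")
                msg = f"ok ({len(df)} rows)"
            else:
                msg = "ok (existence only)"
            rows.append({"role": role, "path": str(p), "ok": True, "message": msg})
        except Exception as exc:  # report, don't raise
            rows.append({"role": role, "path": str(p), "ok": False, "message": str(exc)})
    return pd.DataFrame(rows)


def process_waveform(series: ImpedanceSeries, config: RunConfig) -> Dict[str, float]:
    """One subject-plane recording -> band integrals plus hysteresis medians."""
    window = select_stable_window(series, window_s=min(config.window_s, series.duration_s))
    spec = compute_spectrum(window)
    vent, _perf = split_ventilation_perfusion(window, mode=config.band_mode)
    cycles = analyze_breaths(vent, min_prominence_frac=config.min_prominence_frac,
                             min_cycle_s=config.min_cycle_s)
    summary = summarize_hysteresis(cycles, plane_label=series.plane_label)
    return {
        "Low": spec.low_integral,
        "High": spec.high_integral,
        "Perfusion": spec.perfusion_integral,
        "PeakRespCpm": peak_respiratory_frequency(spec),
        "EI": summary.ei_ratio_median,
        "Skewness": summary.skewness_median,
        "NCycles": summary.n_cycles,
    }


def _eit_table_from_waveforms(entries: Sequence[Tuple[str, str, ImpedanceSeries]],
                              config: RunConfig) -> pd.DataFrame:
    """(subject, plane-prefix, series) triples -> wide per-subject table."""
    per_subject: Dict[str, Dict[str, float]] = {}
    for subject, prefix, series in entries:
        try:
            feats = process_waveform(series, config)
        except ValueError as exc:
            logger.warning("subject %s plane %s excluded: %s", subject, prefix, exc)
            continue
        row = per_subject.setdefault(subject, {})
        for k, v in feats.items():
            row[f"{prefix}-{k}"] = v
    df = pd.DataFrame.from_dict(per_subject, orient="index")
    df.index.name = "subject"
    return df.reset_index()


def _synthetic_full_tables(config: RunConfig, outdir: Path):
    """Simulate subjects end to end; returns (eit_table, ct_table)."""
    data_dir = outdir / "data"
    data_dir.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(config.n_subjects)
    n = config.n_subjects
    # per-subject condition grids: monotone severity from subject 1 to n
    ei_targets = np.linspace(1.5, 4.0, n)
    resp_rates = np.linspace(16.0, 11.0, n)
    cardiac_rates = np.linspace(60.0, 85.0, n)
    emph_fracs = np.linspace(0.0, 0.12, n)
    fsad_fracs = np.linspace(0.05, 0.30, n)
    jac_scales = np.linspace(1.35, 1.05, n)
    ic_voxels = np.round(np.linspace(3000, 1800, n)).astype(int)

    entries = []
    ct_rows = []
    for i in range(n):
        subject = f"S{i + 1}"
        s_int = int(subject_seeds[i].generate_state(1)[0] % (2 ** 31))
        for j, prefix in enumerate(PLANES):
            spec = BreathWaveformSpec(
                duration_s=90.0, sample_rate_hz=10.0,
                respiratory_rate_cpm=resp_rates[i],
                cardiac_rate_cpm=cardiac_rates[i],
                cardiac_amplitude_fraction=0.10,
                ei_ratio_target=float(ei_targets[i]) * (1.0 + 0.05 * j),
                tidal_amplitude=1.0,
                baseline_drift_amplitude=0.05,
                noise_sd=0.01,
                seed=s_int + j,
            )
            wf = generate_breath_waveform(spec)
            series = ImpedanceSeries(values=wf.series.values, sample_rate_hz=10.0,
                                     plane_label=PLANE_NAMES[prefix])
            write_waveform_csv(series, data_dir / f"{subject}_{prefix}.csv")
            entries.append((subject, prefix, series))
        vol = generate_hu_volume(shape=(20, 20, 20), emph_fraction=float(emph_fracs[i]),
                                 fsad_fraction=float(fsad_fracs[i]), seed=s_int + 10)
        cls = classify_parenchyma(vol, config.hu_emph_threshold, config.hu_fsad_threshold)
        total = cls[cls.region == "total"].iloc[0]
        s = float(jac_scales[i])
        fld, _truth = generate_affine_displacement((12, 12, 12), (s, s * 1.1, s * 0.95))
        met = compute_deformation_metrics(fld)
        interior = ~met.boundary_mask & ~met.fold_mask
        spacing = (10.0, 10.0, 10.0)  # 1 mL voxels
        frc_mask = np.zeros((20, 20, 20), dtype=bool)
        frc_mask.flat[:2000] = True
        tlc_mask = np.zeros((20, 20, 20), dtype=bool)
        tlc_mask.flat[:2000 + ic_voxels[i]] = True
        ic = inspiratory_capacity(
            HUVolume(np.zeros((20, 20, 20)), spacing, tlc_mask),
            HUVolume(np.zeros((20, 20, 20)), spacing, frc_mask),
        )
        ct_rows.append({
            "subject": subject,
            "Emph_pct": float(total.emph_pct),
            "fSAD_pct": float(total.fsad_pct),
            "Jacobian": float(met.jacobian[interior].mean()),
            "ADI": float(np.nanmean(met.adi[interior])),
            "IC_L": ic,
        })
    eit = _eit_table_from_waveforms(entries, config)
    ct = pd.DataFrame(ct_rows)
    return eit, ct


def _data_tables(config: RunConfig):
    manifest = pd.read_csv(config.waveform_manifest)
    required = {"subject", "plane", "path"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(
            f"{config.waveform_manifest}: waveform manifest missing columns {sorted(missing)}"
        )
    entries = []
    base = Path(config.waveform_manifest).parent
    for _, row in manifest.iterrows():
        p = Path(row["path"])
        if not p.is_absolute():
            p = base / p
        prefix = str(row["plane"]).strip()[0].upper()
        series = read_waveform_csv(p, plane_label=PLANE_NAMES.get(prefix))
        entries.append((str(row["subject"]), prefix, series))
    ct = pd.read_csv(config.ct_table)
    if "subject" not in ct.columns:
        raise ValueError(f"{config.ct_table}: missing required 'subject' column")
    return entries, ct


def run_pipeline(config: RunConfig) -> Path:
    """Execute a full run; returns the output directory.

    Writes ``cohort.csv`` (merged per-subject variables), ``associations.csv``
    (long-format Spearman table) and ``manifest.json``.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stages: Dict[str, dict] = {}

    if config.mode == "synthetic_cohort":
        couplings = {(x, y): s for x, y, s in config.couplings}
        cohort, truth = generate_cohort(CohortSpec(n_subjects=config.n_subjects,
                                                   couplings=couplings, seed=config.seed))
        x_vars = [c for c in cohort.columns if c.split("-")[0] in PLANES]
        y_vars = [c for c in cohort.columns if c != "subject" and c not in x_vars]
        stages["cohort"] = {"n_subjects": len(cohort),
                            "couplings": [list(k) + [v] for k, v in truth.items()]}
    else:
        if config.mode == "synthetic_full":
            eit, ct = _synthetic_full_tables(config, outdir)
        else:
            entries, ct = _data_tables(config)
            eit = _eit_table_from_waveforms(entries, config)
        eit.to_csv(outdir / "eit_variables.csv", index=False)
        ct.to_csv(outdir / "ct_variables.csv", index=False)
        cohort = eit.merge(ct, on="subject", how="inner")
        x_vars = [c for c in eit.columns if c != "subject" and not c.endswith("NCycles")]
        y_vars = [c for c in ct.columns if c != "subject"]
        stages["eit"] = {"n_subject_planes": int(eit.notna().sum().sum()),
                         "file": "eit_variables.csv"}
        stages["ct"] = {"n_subjects": len(ct), "file": "ct_variables.csv"}

    cohort.to_csv(outdir / "cohort.csv", index=False)
    stages["association"] = {"x_vars": list(x_vars), "y_vars": list(y_vars),
                             "file": "associations.csv"}
    assoc = correlation_matrix(cohort, x_vars, y_vars, alpha=config.alpha,
                               p_method=config.p_method, ci_method=config.ci_method,
                               seed=config.seed)
    assoc.to_csv(outdir / "associations.csv", index=False)

    manifest = {
        "package_version": __version__,
        "config": json.loads(config.canonical_json()),
        "config_sha256": config.sha256(),
        "stages": stages,
        "outputs": sorted(p.name for p in outdir.glob("*.csv")),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir
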