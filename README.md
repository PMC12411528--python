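# eitqct

Joint analysis of electrical impedance tomography (EIT) breathing signals
and quantitative CT (qCT) lung metrics, for researchers studying regional
ventilation in obstructive airway disease (asthma, COPD) who want to relate
what EIT sees *in time* to what CT sees *in space*.

EIT delivers impedance-change images of the thorax at 10 frames per second;
summing the lung region of each frame gives a *global impedance waveform*
that rises and falls with every breath and carries a small cardiac
component. CT, registered between full inhalation (TLC) and normal
exhalation (FRC), delivers structural and functional maps. `eitqct`
computes, from these two modalities:

- **Frequency-domain EIT variables** — FFT of the waveform, band integrals
  over the low (2–25 cpm), high (25–40 cpm) and perfusion (> 40 cpm)
  regions, and an exact ventilation/perfusion signal split at either a fixed
  40 cpm cutoff or an adaptive 2.5x-peak-respiratory-frequency cutoff.
- **Breath-hysteresis variables** — trough-to-trough cycle segmentation,
  the exhalation-to-inhalation area ratio E:I = E/I (areas split at the
  cycle peak; elevated when expiration is prolonged) and cycle skewness
  (third standardized moment of time under the cycle read as a density).
- **qCT structural metrics** — hydraulic luminal diameter Dh = 4·LA/Pe and
  airway wall thickness WT = (D_outer − D_ave)/2 per labeled branch, with
  config-driven normalization by predicted healthy tracheal values.
- **qCT functional metrics** — Emph% (HU < −950) and fSAD% (−950 ≤ HU <
  −856) attenuation classes; per-voxel Jacobian det F = λ1·λ2·λ3 and
  anisotropic deformation index
  ADI = sqrt(((λ1−λ2)/λ2)² + ((λ2−λ3)/λ3)²) from a registration
  displacement field; CT-based inspiratory capacity in liters.
- **Association analysis** — Spearman ρ between every EIT and every CT
  variable with exact-permutation P values for small cohorts (n ≤ 8),
  Fisher-z or bootstrap 95% confidence intervals, a P < 0.01 significance
  gate and a labeled Benjamini–Hochberg column.

Because clinical EIT+CT cohorts are rarely shareable, the package includes a
first-class synthetic-data module that generates every input with known
ground truth (breath waveforms with prescribed E:I, HU volumes with exact
class fractions, displacement fields with analytic Jacobian/ADI, cohorts
with prescribed monotone couplings), and the test suite validates the whole
pipeline by parameter recovery against it. See `docs/methods.md` for the
models and their assumptions.

## Worked example

```python
from eitqct import (analyze_breaths, compute_spectrum,
                    peak_respiratory_frequency, select_stable_window,
                    split_ventilation_perfusion, summarize_hysteresis)
from eitqct.synthetic_data import BreathWaveformSpec, generate_breath_waveform

# 90 s of tidal breathing at 14 cpm with a 72 cpm cardiac component at 10%
# of tidal amplitude, mild drift and noise, target E:I = 3
spec = BreathWaveformSpec(duration_s=90.0, respiratory_rate_cpm=14.0,
                          cardiac_rate_cpm=72.0, cardiac_amplitude_fraction=0.10,
                          ei_ratio_target=3.0, noise_sd=0.02,
                          baseline_drift_amplitude=0.05, seed=42)
wf = generate_breath_waveform(spec)

window = select_stable_window(wf.series, window_s=60.0)
sp = compute_spectrum(window)
vent, perf = split_ventilation_perfusion(window, mode="fixed_40cpm")
summary = summarize_hysteresis(analyze_breaths(vent))

print(f"peak respiratory frequency: {peak_respiratory_frequency(sp):.1f} cpm")
print(f"band integrals  low: {sp.low_integral:.3f}  high: {sp.high_integral:.3f}"
      f"  perfusion: {sp.perfusion_integral:.3f}")
print(f"breath cycles: {summary.n_cycles}")
print(f"E:I ratio (median): {summary.ei_ratio_median:.2f}"
      f"   skewness (median): {summary.skewness_median:.3f}")
```

prints

```
peak respiratory frequency: 14.0 cpm
band integrals  low: 0.421  high: 0.152  perfusion: 0.583
breath cycles: 14
E:I ratio (median): 1.85   skewness (median): 0.342
```

Reading the numbers: the spectral peak sits exactly at the simulated
respiratory rate; the low band dominates the high band, as expected for a
resting subject breathing below 25 cpm; the perfusion integral is inflated
here because the wide 40–300 cpm band accumulates the white-noise floor
(perfusion content is better read at the cardiac bin — see
`docs/methods.md`); 14 complete cycles are segmented from the 60 s window at
14 cpm; and the positive skewness flags the exhale-heavy cycle shape. The
E:I median of 1.85 on the ventilation channel underestimates the target of 3
because the sub-40 cpm filter flattens the sharp synthetic cycle peaks —
on the unfiltered noiseless waveform the recovery is exact, and across
subjects the filtered value remains monotone in the true asymmetry, which is
what the rank-based association stage consumes.

A full synthetic cohort run, from couplings to the association table:

```bash
eitqct run --config run.yaml   # mode: synthetic_cohort / synthetic_full / data
```

writes `cohort.csv`, `associations.csv` (long format: var_x, var_y, n, rho,
p_value, ci_low, ci_high, significant, p_bh) and a `manifest.json` with the
config hash, deterministically for a fixed seed. Individual stages are also
exposed as `eitqct synth|eit|ct|assoc ...` subcommands.

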