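# Methods

`eitqct` implements a joint analysis of thoracic electrical impedance
tomography (EIT) time series and quantitative CT (qCT) lung metrics, of the
kind used to study regional ventilation in obstructive airway disease. This
note documents the models, the numerical choices, and what the synthetic
data generator does and does not emulate.

## Global impedance waveform and its frequency decomposition

An EIT acquisition yields reconstructed impedance-change images (32x32 grid,
10 frames per second). Summing the in-mask pixels of each frame produces the
*global impedance waveform*, which tracks overall lung aeration through the
breath cycle with a smaller cardiac component superimposed.

`compute_spectrum` takes the FFT of the mean-removed waveform with a
rectangular window by default (a Hann taper is available via the `taper`
argument) and reports a one-sided **amplitude** spectrum: a unit-amplitude
on-bin sinusoid contributes 1.0 at its bin. Frequencies are expressed in
cycles per minute (cpm = Hz x 60). Three bands are integrated:

| band | range (cpm) | physiological reading |
|---|---|---|
| low | 2 – 25 | normal resting respiratory rates |
| high | 25 – 40 | abnormally fast respiration |
| perfusion | 40 – Nyquist | cardiac / pulsatile blood flow (resting heart rates 40–100 bpm) |

Content below 2 cpm (baseline drift, DC) is excluded from every band. Band
areas use the trapezoidal rule with the spectrum linearly interpolated at
the exact band edges, so the three integrals are *exactly* additive over the
2 cpm–Nyquist range. Amplitude (not power) was chosen as the integrated
quantity; swapping to power requires only squaring before integration and is
recorded in the output metadata.

`split_ventilation_perfusion` partitions the FFT bins at a cutoff — fixed
40 cpm, or adaptive at 2.5x the peak respiratory frequency (the
maximum-amplitude bin in 2–40 cpm, lowest bin on ties) — and inverse
transforms each group. The split is an exact linear partition:
ventilation + perfusion + mean reconstructs the input to floating precision.
The adaptive cutoff is rejected with a diagnostic when it reaches the
Nyquist frequency.

`select_stable_window` extracts the most stable `window_s` (default 60 s)
segment: candidate windows begin at detected troughs of the sub-40 cpm
channel, each is scored by the variance of its peak prominences, and the
earliest window within float jitter of the minimum score wins. This makes
"a stable 60-s period" deterministic and reproducible.

## Breath segmentation and hysteresis metrics

Cycles of the ventilation channel are delimited trough to trough
(`detect_breath_cycles`): peaks need a prominence of at least 20% of the
global range and a separation of at least 1.5 s, troughs are the minima
between consecutive peaks, and a recording boundary counts as a trough only
when it reaches genuine trough depth — so a recording cut mid-breath sheds
its partial first/last cycle, while one cut at a trough keeps all cycles.
Cardiac ripple sits far below the prominence threshold and never spawns
cycles.

For each cycle the linear baseline joining the bounding troughs is
subtracted, and the area is split at the peak into the inhalation area I
(trough to peak) and the exhalation area E (peak to trough); **E:I = E / I**
rises when expiration is prolonged (normal spontaneous breathing is roughly
3:1 to 5:1 in time). At 10 fps a short inhalation limb spans only ~8–10
samples and splitting at the nearest sampled peak biases E:I by up to ~10%,
so the default split (`method="line_refined"`) refines the peak time by
intersecting straight-line fits to the limbs flanking the sampled maximum —
exact for piecewise-linear cycles, clipped to one sample around the maximum
otherwise. Plain sample-split (`"trapezoid"`) and cubic-spline
(`"spline"`) variants are available.

**Cycle skewness** treats the baseline-subtracted cycle as a probability
density over time within the cycle and returns the third standardized moment
of time: zero for time-symmetric cycles, positive when the impedance area
concentrates late (exhale side), negated by time reversal. The alternative —
sample skewness of the impedance values — was rejected as the default
because it does not directly encode the inhale/exhale imbalance. Per-subject
summaries report both the median (default input to the association stage,
robust at ~12 cycles per minute of recording) and the mean.

## Quantitative CT metrics

**Airway structure.** Per branch, the hydraulic luminal diameter is
Dh = 4·LA/Pe (luminal area over perimeter; equals the diameter for a circle)
and the wall thickness is WT = (D_outer − D_ave)/2. Both are normalized by
predicted healthy tracheal values from regression equations in age, height
(meters) and sex (1 = male, 0 = female). The published transcriptions of
those reference equations are not dimensionally interpretable as printed, so
the equations live in an editable config (`PredictionEquation`: intercept,
optional log-intercept, coefficient x factor-product terms with natural
logs); the literal printed forms ship as defaults and corrected equations
can be dropped in without code changes. Aggregation of segmental airways to
the five sub-lobar groups is the unweighted mean across member segments.

**Parenchymal function.** On a lung-masked HU volume, Emph% counts voxels
with HU < −950 (emphysema-like low attenuation) and fSAD% counts voxels in
[−950, −856) (air trapping); the half-open convention makes
Emph% + fSAD% + remainder = 100 exactly. `classify_parenchyma` is agnostic
to which scan space (inspiratory TLC or registered expiratory FRC) the
volume lives in; callers choose, since conventions differ.

From an FRC→TLC displacement field, F = I + ∇u is formed by spacing-aware
central differences (one-sided at the grid boundary; boundary voxels flagged
and excluded from summaries). Per voxel, the **Jacobian** det F = λ1·λ2·λ3
measures local volume expansion, and the **anisotropic deformation index**

    ADI = sqrt(((λ1 − λ2)/λ2)^2 + ((λ2 − λ3)/λ3)^2),   λ1 ≥ λ2 ≥ λ3

(principal stretches = square roots of the eigenvalues of FᵀF) measures
directional non-uniformity: zero for isotropic expansion, invariant to rigid
rotation. Voxels with det F ≤ 0 (grid folding) are flagged, counted and
excluded — never clipped. CT-based inspiratory capacity is the masked lung
volume at TLC minus that at FRC, in liters.

## Association analysis

Spearman's ρ is computed as the Pearson correlation of mid-ranks (average
ranks on ties); a constant variable yields NaN with a diagnostic. Two-sided
P values come from exact enumeration of all n! rank permutations for n ≤ 8
(mid-rank statistics when ties exist; refused above n = 10), otherwise from
the t approximation t = ρ·sqrt((n−2)/(1−ρ²)). 95% confidence intervals use
the Fisher z-transform with variance 1.06/(n−3) by default, or a seeded
pairwise bootstrap (10,000 draws, percentile interval). Significance is
gated at P < 0.01 with **no** multiplicity correction, matching the design
this analysis reproduces; Benjamini–Hochberg adjusted P values are emitted
as an extra labeled column (`p_bh`).

A note on calibration: an exact permutation test has discrete attainable
levels, so its true type-I rate at α = 0.01 is the largest attainable level
below 0.01 — 2/720 ≈ 0.0028 at n = 6 and ≈ 0.0072 at n = 8. The test is
therefore conservative by construction; the calibration check in the test
suite runs 2,000 independent-null cohorts at n = 8, where the attainable
level is close enough to the nominal α for the empirical rate to fall within
central binomial 99% bounds of 0.01.

## Synthetic-data generator

The generator supplies every input with constructed ground truth.

*Breathing waveforms* are periodic piecewise-linear (triangle) cycles:
linear rise over the first 1/(1+r) of the period, linear decay over the
remaining r/(1+r), peak height = tidal amplitude. With equal peak height the
limb areas are proportional to the limb durations, so the per-cycle
exhale/inhale area ratio equals the target r *analytically*, and the sharp
corners let the analysis stage localize peaks to sub-sample precision. A
smooth-limbed template was considered and rejected: its flat extrema make
the peak position — and hence the E:I split — unrecoverable to 5% at 10 fps.
The cost is that triangles carry harmonic content above 40 cpm (~1% of
spectral area), which legitimately enters the perfusion band; recovery
checks therefore read the cardiac amplitude at the cardiac frequency bin.
Added on top: a cardiac sinusoid (amplitude expressed as a fraction of
tidal), a 1 cpm sinusoidal drift (below the 2 cpm band floor by
construction, so it never contaminates band integrals) and white Gaussian
noise — the weakest noise assumption, and filterable by the band logic.
Defaults describe a resting adult at the study conditions: 10 fps, 12 cpm
respiration, 70 cpm heart rate, cardiac amplitude 10% of tidal, ≥ 60 s
recordings.

*Frame sequences* modulate a fixed smooth spatial pattern (unit in-mask sum)
by the waveform, so the masked per-frame sum reproduces it exactly;
out-of-mask pixels carry independent noise.

*HU volumes* assign exactly `round(fraction x n_lung)` voxels to each
attenuation class by uniform draws within [−1024, −951], [−950, −857] and
[−856, −500]; only class membership matters downstream.

*Displacement fields* are affine, u(x) = (S − I)x for diagonal S, with
analytic Jacobian ∏ scales and principal stretches = sorted scales; a
rotation generator (u = (RS − I)x) supports isometry and rotation-invariance
checks.

*Cohorts* draw per-subject variables uniformly within plausible ranges, with
prescribed couplings: ±1 makes one variable a strictly monotone transform of
another (sample ρ exactly ±1), 0 leaves the pair independent. Inter-subject
variances are configuration, not inference — no population data constrain
them.

What the generator does **not** emulate: anatomically realistic thorax
geometry or electrode physics, reconstruction artifacts, non-stationary
breathing (rate drift, sighs, apneas), correlated or cardiorespiratory-
coupled noise, or realistic spatial HU texture. Passing recovery tests
demonstrates correctness of the computational pipeline under its stated
assumptions, not robustness to all the messiness of clinical recordings.

## Pipeline and determinism

`run_pipeline` supports three modes sharing one analysis path:
`synthetic_cohort` (coupled cohort table → association matrix),
`synthetic_full` (per-subject waveform, volume and field simulation through
every stage; problem sizes kept small — 90 s waveforms, 20³ volumes, 12³
fields — because only ranks, counts and constructed identities matter for
the couplings being verified) and `data` (user CSVs/NIfTI). All randomness
descends from one root seed split per stage; outputs are byte-identical
across reruns of an identical configuration, and `manifest.json` records the
canonical config hash, stage bookkeeping and output files so every number in
the association table is traceable to a stage file.

## Known limitations

- The healthy-reference airway equations are implemented as printed and are
  likely garbled in transcription; normalized Dh/WT values should be
  interpreted only relatively until corrected coefficients are configured.
- Band integrals are emitted raw and total-normalized; which (if either)
  normalization best suits cross-subject comparison is an open question.
- The ventilation/perfusion split is a frequency-domain separation; breath
  harmonics above the cutoff are attributed to the perfusion channel, an
  intrinsic limitation of any spectral gate. Consequently, E:I computed on
  the ventilation channel (the pipeline default, since cardiac ripple would
  otherwise corrupt the peak split) is biased toward 1 for waveforms with
  substantial super-cutoff harmonic content — such as the sharp-cornered
  synthetic cycles — while remaining monotone in the underlying asymmetry;
  absolute E:I recovery is validated on unfiltered noiseless waveforms.
- With white measurement noise, the wide perfusion band (40 cpm to Nyquist)
  accumulates a noise floor proportional to its width; perfusion-channel
  quantities are best read at the cardiac frequency rather than as whole-band
  integrals when noise is non-negligible.
- Whole-trace (rather than per-cycle) skewness is available via
  `compute_cycle_skewness` on a full ventilation segment, but no claim is
  made about which variant matches any particular published analysis.
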