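# Methods

## The measurement model

A ratiometric GEVI pairs a voltage-sensitive green fluorophore with a
voltage-insensitive red reference on one protein. For a cell at membrane
potential `Vm` the expected green/red ratio follows a Boltzmann sigmoid

```
r(Vm) = R_max · {1 − (Δr/100) / (1 + exp(−(Vm − V_half)/k_s))}
```

with maximum ratio `R_max`, maximal relative change `Δr` (percent), midpoint
`V_half` (mV) and slope factor `k_s` (mV). The measured per-cell ratio is
`r(Vm)` times a voltage-independent multiplicative noise term (imperfect
trafficking, maturation, pH sensitivity) that is approximately log-normal
with geometric SD ≈ 1.31 in untreated cells. Because that noise is
median-symmetric in log space, the *median* ratio of a population estimates
`r(Vm)` up to a constant factor, and anchoring the scale at one known
voltage (gramicidin-collapsed cells at 0 mV, or a control group at an
assumed resting Vm) lets the Boltzmann be inverted for a compound
population Vm.

### Parameter orientation

The same Boltzmann curve has two parameterizations related by
`(R_max, Δr, k_s) ↔ (R_max(1−Δr/100), −100Δr/(100−Δr), −k_s)`;
`BoltzmannParams.canonical()` resolves the pair to the `Δr > 0` member, and
fit-recovery comparisons go through it. The published rASAP fit table is
internally inconsistent with the observed response directions
(depolarization by gramicidin *lowers* the ratio; Kir2.1 hyperpolarization
*raises* it): taken verbatim, the printed signs make the modeled ratio
increase with depolarization. The canonical calibration shipped here
therefore stores the printed magnitudes with the `k_s` sign flipped
(rASAP: `R_max = 0.56`, `Δr = −178.6 %`, `V_half = −11.5 mV`,
`k_s = −54.0 mV`); the correction is recorded in `orientation_note` and in
the `orientation_corrected` field of serialized calibrations. The rArc
values (41 %, −49 mV, +27.8 mV) already have the physical orientation and
are kept as printed, with `R_max` normalized to 1 because no absolute
maximum ratio is available. The absolute signs remain convention-dependent;
only the orientation (ratio decreasing with depolarization) is fixed by the
data directions.

### Inversion and population Vm

`invert_boltzmann` is the closed-form logit inversion; it raises a range
error naming the attainable open interval when the requested ratio lies
at/beyond an asymptote. `estimate_population_vm(median_sample,
median_reference, params, reference_vm)` rescales the curve so its value at
`reference_vm` equals `median_reference` and inverts at `median_sample`.
Uncertainty on reported Vm is propagated to first order through the
analytic derivative of the calibration; no bootstrap over calibration
parameters is attempted (their covariance is not available).

### Kinetics and induction models

Voltage-step responses are `1 − (Δr/100)·[a_f(1−e^{−t/τ_f}) +
a_s(1−e^{−t/τ_s})]` with `a_f + a_s = 1` and `τ_f < τ_s` enforced. Slow
induction time courses are flat at `y0` until a delay `t_del`, then rise as
`y0 + (y_max−y0)(1−e^{−(t−t_del)/τ})³`. Latency metrics have closed forms
`t_q = t_del + τ·ln(1/(1−q^{1/3}))`: half-time `t_del + 1.5784·τ`, 20–80 %
rise `1.7565·τ`. The K⁺ equilibrium potential uses the Nernst equation with
R = 8.314 J K⁻¹ mol⁻¹, F = 96485 C mol⁻¹ and a default temperature of
310.15 K (overridable).

## Image analysis

High-content fields carry one blue (Hoechst) frame, four sequential green
frames and one red frame. Processing per field:

1. **Background.** Per channel, the camera offset is subtracted, then a
   rolling-ball background (146 µm default radius). For balls larger than
   32 px the estimate is computed on a downscaled image and resized back —
   the standard shrink trick, accurate because the background is smooth by
   construction of the method. The ball input is lightly smoothed so the
   estimate rides on the noise mean, not its lower envelope. Output is not
   clipped: retaining small negatives keeps downstream ratio statistics
   unbiased.
2. **Segmentation.** The blue frame is thresholded (explicit counts, or
   Otsu guarded by a robust noise floor of median + 6·MAD so that empty
   fields yield no particles), touching nuclei are split by
   distance-transform watershed seeded at local maxima separated by at
   least one minimal-nucleus radius, and particle analysis removes
   edge-touching particles and areas outside 26–117 µm² (inclusive bounds).
3. **Extraction.** Per nucleus ROI, mean blue, red, and **fourth-frame**
   green intensity — the green fluorophore undergoes rapid, saturable
   photoswitching at illumination onset, so only the stabilized frame is
   quantified. ROIs containing raw green/red pixels at the bit-depth
   ceiling (2^14−1 by default) are flagged saturated.
4. **Time-lapse.** Without a nuclear stain (phototoxicity under repeated
   illumination), a binary mask of red pixels strictly inside
   (500, 3500) counts replaces segmentation; the frame statistic is
   mean(green)/mean(red) over the mask.

Coordinates are 0-based row-major; areas are pixel counts × pixel_size².
Boundary pixels belong to exactly one watershed particle.

## Gating

- **Red gate:** keep records with red intensity strictly inside (lo, hi)
  and not saturated. Defaults are the 5 % and 99 % quantiles (the original
  dashed-line cutoffs are not published); explicit counts are supported for
  parity with the time-lapse mask. Audit counts per removal reason sum to
  the input count.
- **Background-offset optimization:** for each candidate green offset the
  ratios are recomputed, binned into 10 equal-count red bins, and the
  squared slope of a line through the per-bin median ratios is recorded;
  the minimizing offset is returned with the whole slope² profile. A grid
  search keeps the profile inspectable; on data constructed with a uniform
  residual offset the slope vanishes exactly at the true value.
- **Cell-cycle gate:** the G0/G1 and G2/M modes of the blue (DNA-content)
  intensity are located by Gaussian KDE (Silverman bandwidth) peak finding;
  records inside `[G1·(1−w), G2·(1+w)]` with `w = 0.4` are kept
  (an 8 %-CV population sits fully inside). Signal below G0/G1 is debris,
  above G2/M non-separated doublets. A unimodal histogram falls back to
  `[peak·(1−w), 2·peak·(1+w)]` with a warning. The original peak-location
  rule is unpublished; KDE + half-width is this package's stand-in.

## Population statistics

`summarize_ratios` reports the median, geometric SD `exp(SD(ln r))`, and a
Gaussian fit `f_max·exp(−(x−x0)²/2σ²)` to the density histogram of
`x = log10(r)` (Freedman–Diaconis bins; the original binning rule is
unpublished). `bootstrap_median_sd` resamples with replacement (default
10 000 resamples, chunked to bound memory) and reports the SD of the median
as percent of the median; the asymptotic value for a log-normal sample is
`1.2533·ln(gsd)/√n` (≈1.07 % at gsd 1.31, n = 1000). Group comparisons pair
control and treatment **within days only** — dish medians are averaged per
group per day, relative changes computed per day, and summarized as
mean ± sem (and sd) across days; days missing a group are excluded with a
warning.

## Synthetic data

The generators are first-class, tested code; their defaults *are* the study
conditions. Fields are rendered at 0.65 µm/px (chosen so 26–117 µm² nuclei
span ~60–280 px, comfortably segmentable; not a published value) on a
14-bit camera with Poisson shot noise, 3-count read noise and a 100-count
offset. Cells are disks on a jittered grid with enough separation that
nuclei never touch; nucleus radii are truncated-normal (4.2 ± 0.45 µm,
bounds 3.3–5.6 µm). Green/red fluorescence covers the whole cell footprint
(in the real assay the nuclear ROI reads defocused membrane signal from
above/below the nucleus), so the ROI-mean green/red equals the cell's true
ratio. Ratio noise is multiplicative on the green channel only (the red
reference is stable), geometric SD 1.31 by default; expression is
log-normal on red (median 1200 counts, gsd 1.8). Photoswitching multiplies
green frame k by `(1−f) + f·e^{−(k−1)/τ}` with `f = 0.3`, `τ = 0.7` frames —
the loss saturates by frame 4; the true magnitude and time course are not
published, so these are free scene parameters, and because the multiplier
is common to all cells it cancels from all relative comparisons. Blue
intensity is bimodal (20 % G2/M at 2× G1, 8 % CV) with optional debris and
doublet contaminants for gating tests. Backgrounds are smooth random
surfaces (±30 % around per-channel levels).

What the generator does **not** emulate: optical PSF/defocus, flat-field or
vignetting errors, electrical coupling between cells, pH drift, focus
drift, or non-log-normal outlier populations. Passing tests therefore
demonstrate correctness of the *analysis chain* under the method's own
statistical assumptions, not robustness to every real-microscope artifact.

## Numerical choices

- All nonlinear fits use least squares (`scipy.optimize.curve_fit`) with
  relative tolerance 1e-10 and a 50 000-evaluation budget; initializations
  are deterministic and derivative-free (midpoint from quartile crossings,
  slope factor from the 25–75 % span, amplitudes from data extremes,
  kinetic τs from threshold crossings of the normalized rise).
- Degenerate inputs return flagged results rather than raising where the
  spec of the operation allows: constant-ratio Boltzmann data →
  `Δr = 0`, `unidentifiable`; τ-collapse in the double exponential → a
  single-exponential fallback flagged `single_exponential`; flat induction
  series → `no_amplitude` / `no_induction`.
- The first two post-induction samples are masked before latency fits by
  default: the brief ratio transient after solution application is a
  handling artifact, not biology, and it also cancels exactly when induced
  and control series share it multiplicatively.
- Every stochastic utility takes an explicit seed; rendering is bit-exact
  under a fixed seed.

## Problem sizes

Simulation-backed checks use the smallest sizes at which the statistics are
meaningful: bootstrap checks at n = 1000 (20 seeds), kinetic recovery over
100 replicates of 500 ms at 20 kHz, and the in-silico hyperpolarization
experiment at 4 fields (1024² px) × 250 cells per group per dish —
1000 cells per group per dish, giving a per-dish median SD of ~1.5 %,
comparable to the real assay's dish-to-dish variability. The test suite
averages the experiment over 3 dishes; `scripts/acceptance.py` over 5,
mirroring a five-replicate measurement campaign.

## Known limitations

- Absolute Vm estimates inherit the calibration-orientation convention and
  the anchor assumption (gramicidin ≈ 0 mV, or an assumed control Vm); they
  are best interpreted as differences between groups.
- The Gaussian log-ratio fit assumes unimodality; strongly contaminated
  distributions should be gated first.
- The latency reconstruction (`t_del = 42.5 min`, `τ = 19.36 min`) is
  derived from the published 73-min half-time and 34-min 20–80 % rise via
  the closed forms, not from published parameter values.
- `optimize_background_offset` assumes the residual offset is spatially
  uniform within a dish.
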