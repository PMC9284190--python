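# Methods

This note documents the models, defaults and design choices behind
`pentaplex`, in the spirit of a methods appendix: what is assumed, what
is configurable, and what the synthetic validation does and does not
demonstrate.

## Mixing model and observation geometry

Acquisition is LED-sequential on an RGB sensor: with five fluorescence
LEDs, one pixel yields a stacked signal vector `S` of length 15
(LED-major order, R/G/B within each LED; the brightfield LED is never
part of unmixing). The mixing model is linear, `S = A F`, with `F ≥ 0`
the per-pixel fluorochrome abundances. Columns of `A` are normalized to
unit maximum, so abundances carry the intensity scale; this makes
predicted and experimentally estimated matrices directly comparable.

A predicted fingerprint column factorizes as

```
A[(ℓ,c), f] ∝ brightness_f · ∫ LED_ℓ·filter_ℓ·ex_f dλ · ∫ em_f·penta·sensor_c dλ
```

which assumes the emission spectrum is independent of excitation
wavelength (Kasha's rule) and that the sensor responds linearly. Filter
angle-of-incidence shifts, photobleaching and Bayer demosaicing are not
modeled.

## Default optics

Shipped spectra (`pentaplex/data/spectra/*.csv`, 2 nm grid) are
Gaussian-mixture approximations of the published part numbers: LEDs at
385/470/567/627/720 nm with their excitation filters (400 nm short-pass,
470/10, 550/25, 640/10, 750/25 band-passes), a five-window emission
filter with passbands centered near 432/515/595/681/809 nm, an RGB
sensor with peaks near 460/535/600 nm plus a near-infrared response
shared by all three channels (necessary for CF750 detection), and the
six dyes with literature-typical excitation/emission peaks and red
emission tails. Relative brightness: DAPI 1.0, BV605 0.8, AF488 1.0,
AF555 0.9, AF647 1.0, CF750 0.5. Spectra are configuration data — any
YAML + CSV set can replace them; nothing is hard-coded.

The resulting 15×6 matrix has condition number ≈ 1.5 and reproduces the
qualitative crosstalk structure expected of this optical chain, e.g.
AF555 appearing strongly in the L567 R and G rows and CF750 leaking
into the L627 (AF647) row block through its blue excitation shoulder.

## Unmixing

`unmix_pixel` uses scipy's active-set NNLS (exact). `unmix_image`
vectorizes over pixels by enumerating candidate active sets: for each
of the `2^k − 1` supports (k = number of dyes, largest supports first)
it applies a precomputed pseudo-inverse to all unresolved pixels and
accepts solutions satisfying the KKT conditions (feasible on the
support, non-negative gradient off it), which certifies global
optimality for this convex problem. Pixels that remain numerically
marginal fall back to scipy NNLS. Tolerance is `1e-9 ×` the signal
scale. Rank-deficient `A` triggers a warning; the solution is then a
minimizer but not necessarily unique. An optional noise floor lets
background pixels skip the solver (off by default in the analysis
pipeline — per-cell background baselines are needed for
normalization). A 2448×2048 frame with the default 15×6 matrix unmixes
in well under a minute on one CPU.

## Cycle corrections

Order is fixed: dark → align → quench-subtract, all clamped at zero
(signals are physical). The clamp fraction is logged per cycle; when
counting clamped pixels the pipeline ignores deviations within ~5 read-
noise SDs (estimated from the dark frame) so that background noise
flipping sign is not reported as over-subtraction; fractions above 20%
still warn.

Registration runs on the raw DAPI window (G+B under the 385 nm LED)
before unmixing, so that unmixing sees consistent geometry. The coarse
stage is ORB keypoints, brute-force Hamming matching with cross-check,
and RANSAC with a Euclidean (rigid) model — the scheme used on
instruments of this class. Corner keypoints on blob-like nuclei are
pixel-quantized, which limits rotation accuracy to ~0.2°, so a
refinement stage matches nucleus blob centroids (sub-pixel
center-of-mass) by nearest neighbor under the current transform and
re-fits by trimmed Kabsch least squares over a shrinking match radius
(12 → 5 → 2 px). On the synthetic slides this recovers mounting errors
up to 10 px / 2° to ≈ 0.01 px and ≈ 0.002°. Cycle 1 is the reference;
the unstained autofluorescence acquisition (stored as cycle 0) shares
its mounting. Quenched images are aligned with their own cycle's
transform. No flat-field correction is applied, and registration is
rigid only.

## Segmentation and QC

The built-in backend is deliberately classical: Gaussian smoothing,
Otsu threshold of the DAPI maximum projection, hole filling, small-
object removal, distance-transform watershed for touching nuclei, and
cell bodies grown by bounded dilation (or a cytoplasm-guided watershed
when a cytoplasm image is given). Learned segmenters are heavyweight
external dependencies; the registry (`register_backend`) accepts any
callable producing label masks, so they can be plugged in without
touching the pipeline. QC removes cells with more than one nucleus,
cells with nucleus/cell area ratio > 1 (possible when nucleus and cell
are segmented independently), nucleus-free cells and orphan nuclei —
each counted separately. Nuclei are assigned to the cell covering the
majority of their pixels. The filter is idempotent.

## Quantification, normalization, thresholds

Markers flagged nuclear (ER, PR, Ki67, GATA3; DAPI) are averaged over
the nucleus mask, others over the whole cell. Per marker, cell means
are divided by their 10th percentile across cells — placing background
cells near 1 — and winsorized at the 99th percentile to suppress
outliers (the chosen reading of "normalize to p10, use p99"; divide-
then-winsorize keeps the scale interpretable and is recorded with both
reference values). A zero 10th percentile raises rather than silently
producing infinities.

Positivity is called per marker against the isotype (IgG) control
carried on the *same fluorochrome channel* in the same run — channels,
not antibodies, set the null because nonspecific binding and residual
crosstalk are channel properties. Threshold = IgG mean + 3 SD on the
normalized scale, strict inequality (ties are negative; the convention
is fixed by test). Phenotype rules are ordered boolean expressions over
positivity flags, first match wins, default `other`. Built-in rule
sets: CD45 vs the HER2/EpCAM/MUC1/EGFR composite, and a five-way
HER2/ER/PR/Ki67 mosaic.

## Simulator

What it emulates: fine-needle-aspirate-like monolayers of a few hundred
to a few thousand cells at 0.6 µm/px; elliptical cells (mean radius
9 px) with contained nuclei (0.55 semi-axis fraction); membrane markers
on the cytoplasmic ring, nuclear markers on the nucleus; per-phenotype
log-normal expression (tumor median ≈ 110–150 abundance units on
HER2/EpCAM/MUC1/EGFR, immune CD45 ≈ 150, σ_log 0.35–0.5); a universal
nonspecific-binding floor (median 3, the IgG null level) so control
channels have realistic non-zero baselines; DAPI counterstain every
cycle (median 300); uniform autofluorescence (4 counts/row); camera
model Poisson(shot) → Gaussian read noise (SD 2) → dark offset (100),
clipped at zero; quench residual 2% per cycle, accumulating
geometrically across cycles so quench subtraction is a meaningful test;
rigid mounting errors up to ±6 px, ±0.6° drawn per cycle; bilinear
warping with dark-offset fill.

What it does not emulate: tissue architecture, 3-D shape, spatially
structured autofluorescence, illumination falloff, Bayer mosaics,
photobleaching, focus drift within a cycle, or segmentation-hostile
morphology (heavily overlapping cells). Passing end-to-end tests
therefore demonstrates the correctness of the computational chain under
its stated model — not robustness to every artifact of real tissue.
Default problem sizes in tests and the verification script (100–500
cells, 4 cycles, 50 registration trials) were chosen as the smallest
sizes at which the statistical criteria are meaningful.

## Numerical conventions

- SNR = (mean(fg) − mean(bg)) / SD(bg); infinite background-free SNR is
  flagged, not raised. CV uses the sample (n−1) SD, reported in %.
  Both conventions are stated because published values depend on them.
- Focus score is gradient energy (mean squared Sobel magnitude):
  reference-free, zero for constant images, strictly decreasing under
  Gaussian defocus, quadratic under linear rescaling (rankings are
  rescale-invariant). Plane selection takes the argmax, ties to the
  lower index. The default sweep mirrors a two-stage autofocus: seven
  planes, 150 µm apart.
- Fingerprint estimation from single stains selects foreground pixels
  above the 0.95 quantile of a σ=2-smoothed copy of the brightest
  plane; selecting on the raw plane would bias that plane's average
  upward through its own shot noise (≈ 3% on the default slides).
  Plane averages use raw pixels. Whether real calibrations use cell
  foregrounds or whole fields is configurable via the quantile.
- All randomness flows through `numpy.random.Generator` seeds;
  simulate + analyze is byte-deterministic for a fixed seed.

## Known limitations

- The active-set enumeration in `unmix_image` is exponential in the
  number of dyes; it is fast for ≤ 8 dyes and falls back gracefully,
  but a different batching strategy would be needed for 15-plex panels.
- Registration assumes enough (≥ ~20) nuclei in the field; sparse
  fields raise a registration error rather than guessing.
- The classical segmenter under-performs learned models on crowded or
  irregular nuclei; it is the reference implementation, not the
  recommended production segmenter.
- IgG thresholds require an IgG cycle in the same run; a user-supplied
  constant threshold is accepted with a warning otherwise.
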