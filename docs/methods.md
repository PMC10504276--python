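# Methods

## Signal model

Each voxel of the phantom carries a mean linear backscatter intensity `I`, a
static field fraction `f ∈ [0, 1]` and a temporal correlation time `τ > 0`.
The complex field over time is a static + dynamic circular complex Gaussian
mixture

    A(t) = √I · [ √f · γ_s + √(1−f) · γ_d(t) ] + n(t)

with `γ_s` a frozen unit draw, `γ_d` a unit-variance AR(1) process updated
exactly over the actual inter-frame gaps (`γ_d(t+Δ) = a·γ_d(t) + √(1−a²)·ξ`,
`a = exp(−Δ/τ)`), and `n(t)` i.i.d. detector noise of variance `σ²ₙ`. A
lateral Gaussian PSF blur (default 2.5 px FWHM along the fast axis,
normalised to unit L2 so the per-voxel mean intensity is preserved) creates
realistic speckle grain; axial blur is omitted because the 7.24 µm axial
pitch is small against every structure of interest and a crisp surface keeps
the segmentation tests sharp.

This mixture was chosen over explicit scatterer motion because it gives every
downstream estimator a closed form: the complex autocorrelation at lag Δt is
`f + (1−f)·exp(−Δt/τ)` (times `I`), and the noise-only expectation of `|A|²`
is `σ²ₙ`. No microscopic motion model is implied by the imaging method
itself.

Reproducibility: one master seed; each slow-axis location draws from an
independent stream spawned as `SeedSequence(seed, spawn_key=(2, location))`,
so frame stacks are independent across locations and bit-identical across
runs and processes.

## Scan protocols

Two protocols are encoded exactly. The block-repeating raster (LIV): 4
blocks × 32 locations × 16 repeats at a 409.6 ms inter-scan interval —
2048 frames and 128 locations per volume, a per-location window of
(16−1) × 0.4096 = 6.144 s, and a volume time of 4 × 16 × 0.4096 = 26.2144 s.
The fast raster: 4 frames at 12.8 ms per location, 512 frames in 6.5536 s,
window 38.4 ms. Where displays quote 13/39 ms, those are rounded
presentations of the 12.8 ms interval; both constants are exposed and all
computation uses 12.8 ms. Inter-scan intervals are start-to-start; timing
validation rejects protocols whose frames (or block passes) cannot fit
their interval.

## Contrast estimators

**LIV** is the population variance (divisor N, not N−1) of the dB-scale
intensity `10·log₁₀(|A|² + ε)` over the N frames at one location, with
`ε = 10⁻¹²` flooring the log so air stays finite (−120 dB). No noise
correction is applied; consequently low-SNR voxels carry a noise-induced
LIV floor (about 1.9 dB² at 20 dB SNR in the phantom) — the same artifact
the imaging literature reports for uncorrected LIV in deep tissue. LIV is
insensitive to frame order and to global dB offsets.

**Bulk phase correction**: for each consecutive frame pair the global phase
is `arg Σ A_i* A_{i+1}` over the pixels above the median mean-intensity; the
angle is measured against the already-corrected previous frame, so it is the
full correction for the next frame. Pairs with a zero-energy frame are
skipped and flagged.

**Fast-DOCT** is `clip(1 − ρ, 0, 1)` with

    ρ = |Σ_K Σ_pairs A_i* A_{i+1}| / √( max(E₀ − M σ²ₙ, δ) · max(E₁ − M σ²ₙ, δ) )

summing the lag-1 pairs of the (default 4) frames over a spatial kernel K
(default 3×3), `M = |K|·n_pairs`, `E₀/E₁` the kernel-summed pair energies.
Only lag-1 pairs are used — the minimal reading of correlation "among the
repeated frames". The numerator carries no noise term: cross-terms of
independent noise have zero mean. The guard is
`δ = max(0.5·M·σ²ₙ, 10⁻¹²)`; pixels whose corrected energy falls below δ are
reported in a validity mask instead of being clipped, because after removing
the noise energy nothing real remains there. For noise-only pixels the
corrected energy has mean 0 and standard deviation `√M·σ²ₙ` (inflated ~1.6×
by the PSF correlation), so ≳95 % of them are flagged, while tissue at
20 dB SNR sits two orders of magnitude above the guard.

**Estimator bias and the pooled estimator.** The kernel map is a sample
coherence over M samples; for truly independent data its magnitude does not
vanish but floors at `E[ρ̂] ≈ (√π/2)/√M` (the Rayleigh mean of the
zero-coherence estimate; `ρ̂²` is Beta(1, M−1)-distributed). With the default
3×3 kernel and 3 pairs, M = 27 and the floor is ≈ 0.17, so a fully
decorrelated region renders at ≈ 0.83, not 1.0 — and at small true
correlation the map is biased upward by up to ~0.13. Quantitative region
statistics therefore use the *pooled* estimator (`pooled_decorrelation`,
`pooled_correlation_multilag`): one correlation over all masked voxels and
pairs, whose bias decays as `1/√(total samples)` and is < 0.01 for ≥ 10⁴
voxels. The kernel map is for display and structure detection; the pooled
estimate is for numbers. `coherence_floor(M)` exposes the analytic floor.

**Correlation-time estimation** fits `ln ρ(Δt) = −Δt/τ` through the origin
over lags 1–3 of the fast stack, using only lags whose pooled |ρ| clears a
multiple (default 5×) of the analytic zero-coherence floor so lags lost in
estimator noise cannot drag the fit. The per-pixel map variant
(`estimate_tau_map`, default 7×7 kernel, 2.5× floor factor) is noisier and
biased at small correlations — region estimates are preferred for recovery
claims. Over τ ∈ [5, 100] ms at 30 dB SNR the region estimate recovers τ
within ≤ 14 % worst-case (typically ≤ 5 %).

## Segmentation and projections

The surface is the first depth where the 16-frame-averaged dB intensity
stays above `noise floor + margin` (default margin 10 dB, minimum run 3
consecutive pixels) per (x, y) column, followed by 5×5 median smoothing.
The noise floor is the *mean dB of noise*, i.e. `10·log₁₀ σ²ₙ − 2.507 dB`
(the mean-log offset of exponentially distributed intensity). Because the
parenchyma is static-dominated, frame averaging does not suppress its
speckle; the pipeline therefore pre-smooths the mean-dB volume laterally
(default 5×3 box) before thresholding. With these defaults the recovered
surface is within 2 px RMS of ground truth down to 15 dB SNR (measured
≈ 0.4 px), and all-noise volumes yield no valid columns.

Slab projections average a fixed-thickness band `[surface, surface+slab)`
per column. At full scale the band is 100 px = 724 µm; the smoke grid
(nz = 64) defaults to 24 px because its tissue depth is 464 µm and the
phantom's tubules are confined to the superficial ~150 µm (sparse tubes in
a deep slab would dilute the projection contrast that densely packed real
cortex does not lose). Columns truncated by the volume bottom are averaged
over the available voxels only — zero-padding is excluded so shallow regions
are not biased dark. Invalid surface columns stay invalid (NaN) in every
projection and render black.

## Rendering

The LIV composite is HSV with hue = LIV clipped to `hue_range` (default
0–10 dB²) mapped red (0°) → green (120°), saturation 1, value = dB intensity
clipped to `value_window` (default the [p1, p99] percentiles of the image —
the display windows are not physical constants and are config-exposed).
Invalid pixels render black. Fast-DOCT renders as grayscale decorrelation
gated by the validity mask and optionally by a dB window. Rendering is a
pure function of its inputs: identical inputs give identical bytes.

## Phantom presets and parameters

| parameter | default | rationale |
|---|---|---|
| axial pitch | 7.24 µm | fixed by the 100 px = 724 µm slab convention |
| lateral pitch (fast/slow) | 5.86 / 23.4 µm | 3 mm FOV over 512 A-lines / 128 locations |
| tube outer diameter | 40 µm | wall-to-wall tubule size |
| lumen diameter | 22 µm | hypo-scattering core, backscatter 0.1× |
| wall τ / static fraction | 50 ms / 0.05 | active epithelium; the τ knob spans the fast-contrast visibility boundary |
| shell thickness, τ, f | 60 µm, 1.5 s, 0.10 | superficial high-dynamics layer of the obstructed kidney |
| parenchyma τ / f | 30 s / 0.98 | ex vivo parenchyma is nearly frozen over the 6.1 s window; renders red in the composite |
| lumen τ / f | 30 s / 0.8 | quiescent fluid |
| SNR | 20 dB | typical tissue-above-noise margin; config-exposed |
| PSF FWHM | 2.5 px lateral | matches an 18 µm-class lateral resolution at the 5.86 µm pitch |

`normal` places ≥ 3 non-intersecting convoluted tubes (smooth sinusoidal
centerlines in disjoint lateral bands, meandering in depth within the
superficial band; a KD-tree check enforces ≥ one diameter of clearance).
`obstructed_1w` keeps two short residual segments plus the shell;
`obstructed_2w` has the shell only. All presets share a smooth curved
surface with noise-only air above it.

**Fast-DOCT visibility rule.** Tubule visibility in the millisecond contrast
is defined as wall-region mean decorrelation ≥ 0.25 — a quarter of full
scale, below which the walls sink into the dark background of the display.
A ratio against the parenchyma cannot serve here: parenchyma decorrelation
is ≈ 0.01, so any wall τ up to ~1 s produces a large ratio while remaining
invisible in the rendered image. With Δt = 12.8 ms the rule places the
visibility boundary between wall τ of 20 ms (wall mean ≈ 0.31) and 50 ms
(≈ 0.16): the fast contrast sees tubules only for τ ≲ 20–35 ms, while LIV
sees them at every τ — the two-contrast dichotomy the method is designed
around. Contrast-ratio grades elsewhere use ≥ 3 "clearly visible", 1.5–3
"moderate", < 1.5 "not visible", for reporting only.

## What the phantom does and does not emulate

It emulates: 4D complex speckle with controllable two-scale temporal
statistics, static-dominated parenchyma, tubule geometry at the correct
scale, a curved surface with noise-only space above, additive circular
Gaussian detector noise, and the exact frame timing of both protocols. It
does **not** emulate: beam propagation, confocal gating or depth-dependent
sensitivity; attenuation or refraction; dense tubule packing (tubes are
sparse, which is why the smoke slab is thinner than full scale); blood flow
(the tissues are ex vivo); bulk sample motion beyond global per-frame phase
offsets; or axial PSF extent. Passing tests therefore validate the
*estimators and pipeline logic* under known statistics — not system-level
image quality on real tissue.

## Numerical choices

* dB floor ε = 10⁻¹² of full scale (−120 dB) keeps LIV finite in air.
* Fast-DOCT guard δ = 0.5·M·σ²ₙ (see above); kernel sums use edge
  replication.
* τ-fit lag qualification: 5× (region) / 2.5× (map) the analytic coherence
  floor; an all-disqualified pixel yields NaN rather than a fabricated τ.
* Surface smoothing fills invalid columns with the median height before the
  median filter so borders are not dragged toward zero, then re-applies
  validity.
* Degenerate inputs are rejected with named errors: < 2 frames for either
  contrast, non-increasing timestamps, kernels larger than the frame, empty
  air masks for noise estimation, slabs that cannot fit the grid.
* Volumes compare bit-identically across reruns on one platform; the
  manifest stores SHA-256 checksums of every artifact.

## Problem sizes

The default ("smoke") grid is nz = 64 × nx = 128 × ny = 16 at full-scale
pixel pitches, i.e. a 464 µm × 750 µm × 375 µm block; a full two-protocol
pipeline run takes ~1.5 s and the whole test suite ~12 s on one core.
Estimator calibrations use ≥ 10⁴ voxels (64×256 blocks) and the LIV
expectation check uses 1.2×10⁵ pixels. These sizes were chosen so the
Monte-Carlo standard errors sit well inside the asserted tolerances.

## Known limitations

* The lumen FWHM read from the OCT image (~14–17 µm) underestimates the
  22 µm lumen: at the simulated resolution the dip is only partially
  resolved, so its half-depth width shrinks — the same resolution-limited
  underestimate reported for real systems of this class. The LIV FWHM
  (~42–46 µm) tracks the 40 µm dynamic annulus and is always the larger of
  the two.
* The surface-layer thickness estimator counts above-threshold voxels in the
  top 150 µm and is biased slightly low by speckle dropouts (measures
  ≈ 59–61 µm for the 60 µm shell).
* `estimate_tau_map` is magnitude-biased for τ ≪ Δt at map scale; use region
  estimates for quantitative recovery.
* The 1-week-obstruction preset models "hardly visible" tubules by spatial
  sparsity (two short segments) with unchanged wall dynamics; degraded
  per-cell dynamics would be an equally defensible choice.
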