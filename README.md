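# doctk — dynamic OCT contrasts on synthetic kidney speckle phantoms

Label-free dynamic optical coherence tomography (DOCT) turns the temporal
fluctuation statistics of repeated complex OCT frames into functional tissue
contrast: metabolically active cells shuffle scatterers, the speckle
decorrelates, and the fluctuation magnitude maps activity without any dye.
In ex vivo kidney this reveals the renal tubules — convoluted pipe-like
structures whose epithelial lining is highly dynamic — and their
disappearance after ureter obstruction, when tubular function is lost and a
thin high-dynamics shell appears at the organ surface instead.

`doctk` implements the full analysis as a tested Python library, together
with a synthetic speckle phantom that makes every stage verifiable against
closed-form ground truth:

* **Scan protocols** — a block-repeating raster (4 blocks × 32 locations ×
  16 repeats at 409.6 ms → 2048 frames, 26.2 s per volume, 6.14 s window per
  location) for slow dynamics, and a fast raster (4 frames at 12.8 ms,
  512 frames in 6.55 s) for millisecond dynamics.
* **LIV (logarithmic intensity variance)** — per pixel, the population
  variance of the dB-scale intensity over the N repeated frames:

      LIV(x, z) = (1/N) Σᵢ [ I_dB(x, z, tᵢ) − ⟨I_dB(x, z)⟩ ]²

  computed without noise correction; sensitive to second-scale dynamics.
* **Fast-DOCT** — one minus the magnitude of the noise-corrected complex
  correlation between consecutive frames,

      ρ = |Σ_K Σ_pairs Aᵢ* Aᵢ₊₁| / √[(E₀ − Mσ²ₙ)(E₁ − Mσ²ₙ)],   Fast-DOCT = 1 − ρ

  over a spatial kernel K (default 3×3) after per-frame bulk-phase
  correction; the noise-energy offset keeps detector noise from reading as
  fake dynamics, and pixels with no energy left after the offset are flagged
  invalid rather than displayed. Sensitive to millisecond-scale dynamics.
* **Surface-segmented slab projections** — threshold-crossing surface
  segmentation on the 16-frame-averaged dB volume, then mean projections
  over a fixed-thickness slab below the surface (100 px = 724 µm at the
  7.24 µm axial pitch; failed columns propagate as black).
* **Pseudo-color rendering** — HSV composites with hue = LIV (red → green),
  saturation 1, value = windowed dB intensity; grayscale Fast-DOCT gated by
  the validity mask.
* **Metrics** — FWHM structure diameters, region statistics over ground-truth
  masks, and phenotype reports (tubule and shell contrast ratios, Fast-DOCT
  visibility, surface-layer thickness).

The phantom models each voxel's field as a static + AR(1)-dynamic circular
complex Gaussian mixture `A(t) = √I [√f·γₛ + √(1−f)·γ_d(t)] + n(t)` with
per-voxel correlation time τ, so the complex autocorrelation at lag Δt is
exactly `f + (1−f)·exp(−Δt/τ)` and every estimator has an analytic oracle.
Three presets emulate the studied conditions: `normal` (≥3 convoluted
tubules, 40 µm wall-to-wall, dynamic walls around a hypo-scattering lumen),
`obstructed_1w` (two short residual segments plus a 60 µm superficial
shell), and `obstructed_2w` (shell only).

## Worked example

```bash
python examples/04_kidney_pipeline.py
```

```
--- normal ---
  tubule LIV contrast ratio:  3.4242861589688363
  shell LIV contrast ratio:   None
  surface layer thickness:    None um
  grades: {'tubule_liv': 'clearly visible', 'tubule_fdoct': 'not visible', 'shell_liv': 'absent'}
  outputs: 14 files in scratch/example_runs/normal
--- obstructed_2w ---
  tubule LIV contrast ratio:  None
  shell LIV contrast ratio:   12.968485740488624
  surface layer thickness:    59.659296875 um
  grades: {'tubule_liv': 'absent', 'tubule_fdoct': 'absent', 'shell_liv': 'clearly visible'}
  outputs: 14 files in scratch/example_runs/obstructed_2w
```

In the normal kidney the tubule columns of the LIV slab projection are 3.4×
brighter than the surrounding parenchyma (ratio ≥ 3 reads as "clearly
visible"), while at the default wall correlation time of 50 ms the
millisecond contrast does not resolve them. In the 2-week obstructed kidney
the tubule ratio is absent — there are no tubules — and a high-dynamics
layer of ≈60 µm hugs the surface (shell/parenchyma ratio ≈ 13). Each run
directory contains the dB/LIV/Fast-DOCT volumes (TIFF), the surface map,
slab projections, the red-green LIV composite and grayscale Fast-DOCT PNGs,
a JSON phenotype report, and a checksummed manifest; reruns with the same
seed are bit-identical.

The other examples demonstrate protocol arithmetic (`01`), estimator
calibration against the AR(1) closed form (`02`), the noise-offset
correction and its low-SNR artifact (`03`), and the LIV-always /
Fast-DOCT-sometimes visibility dichotomy under the wall-τ knob (`05`).

A thin CLI wraps the same pipeline: `doctk all --config run.yaml --seed 7
--out results/` runs everything; `simulate`, `contrast`, `project`,
`render` and `report` run the stages individually against a shared output
directory, and `validate` checks a config without computing.

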