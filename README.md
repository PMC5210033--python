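# adrenadc

Measuring the apparent diffusion coefficient (ADC) of normal adrenal
glands — or any small, irregular, hyperintense structure — from multi-b
diffusion-weighted MRI (DW-MRI) is hard: the glands are a few voxels
wide, bordered by fat, and nearly invisible on the ADC map itself.
`adrenadc` implements, as a tested library, the workstation workflow
that makes it feasible: segment the gland on the b = 500 s/mm² diffusion
image where it is conspicuous, transfer the ROI onto the ADC map, and
average pixel-by-pixel. Because no imaging data accompany such studies,
the package ships a synthetic phantom generator with exact ground truth
so the whole chain is verifiable end to end.

It is intended for imaging researchers who want a reproducible,
scriptable version of this measurement — and for anyone auditing
published group comparisons from summary statistics alone.

## What it computes

**Signal model.** Each voxel follows the monoexponential decay
S(b) = S₀·exp(−b·ADC); the ADC map is −slope of the ordinary
least-squares fit of ln S on b over the acquired b-values
(0, 20, 500, 1000 s/mm² by default). A segmented IVIM-style variant
(diffusion coefficient from b ≥ 100 only, perfusion fraction from the
extrapolated intercept) is available.

**Segmentation.** Per slice, the reader supplies two reference voxels —
the brightest just outside the gland and the dimmest inside. The
threshold is their midpoint, T = (I_out + I_in)/2; the ROI is the
8-connected component of {I ≥ T} containing the interior reference,
holes filled. Masks are stacked across slices and fused with the ADC
map (identity for same-grid volumes, nearest-neighbour otherwise); the
gland's value is the pooled mean over all ROI voxels.

**Cohort & statistics.** An ordered exclusion cascade (radiological →
clinical → missing data) with per-stage audit; Tanner-based
prepubertal/postpubertal grouping; Shapiro–Wilk-gated group comparison
(Welch t or Mann–Whitney), also recomputable from printed (mean, SD, n)
summaries; and two-way random-effects intraclass correlation (ICC) in
all four agreement/consistency × single/average forms, with
F-distribution confidence intervals.

## Worked example

```python
import adrenadc as ad

spec = ad.PhantomSpec(rician_sigma=23.5, rng_seed=42)   # SNR ~20 at b=500
series, truth = ad.generate_phantom(spec)
adc_map = ad.compute_adc_map(series)
roi = ad.segment_gland(series, truth.seeds["right"], b_select=500.0, side="right")
g = ad.measure_mean_adc(roi, adc_map, subject_id="phantom")
print(f"measured {g.mean_adc*1e3:.4f} x10^-3 mm^2/s over {g.voxel_count} voxels")
```

prints

```
measured 1.4318 x10^-3 mm^2/s over 132 voxels
```

— within 0.6% of the configured true gland ADC of 1.44 × 10⁻³ mm²/s
despite per-voxel Rician noise, because the pooled ROI mean averages
132 voxels. Run the scripts in `examples/` for the other capabilities
(phantom anatomy, cohort cascade, group comparison, observer agreement),
e.g. `python examples/02_fit_and_measure.py`.

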