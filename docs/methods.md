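# Methods

## Signal model and ADC fitting

Every voxel is modelled as a single monoexponential compartment,
S(b) = S₀·exp(−b·ADC), and fitted by unweighted ordinary least squares
of ln S on b. Only strictly positive signals enter the fit; a voxel
with fewer than two positive points is excluded from the fit mask
rather than guessed at. Negative fitted decay rates (signal rising with
b, possible under noise) clamp to ADC = 0 so the map stays complete.
Unweighted OLS on the log-signal is the simplest defensible estimator
here; a variance-weighted variant would down-weight high-b points and
could be added behind the same interface.

Clinical scanners sometimes advertise "multiexponential" map generation
without publishing the model. With only four b-values a full
biexponential (IVIM) fit of four parameters is under-determined, so the
package's default is monoexponential and the IVIM behaviour is offered
only in segmented form: the diffusion coefficient from the b ≥ 100
s/mm² points, the perfusion fraction f = 1 − S_int/S(0) from the
extrapolated high-b intercept. The split at 100 s/mm² is the
conventional perfusion/diffusion boundary.

## Segmentation

The inclusion rule is intensity ≥ threshold: the gland is hyperintense
on fat-saturated DW-MRI while the surrounding fat is suppressed, so the
midpoint of (brightest adjacent, dimmest interior) separates gland from
fat from below. A literal upper-bound reading of a "maximum value"
threshold is incompatible with a bright structure on a dark background
and is not implemented. Other choices:

- strictly 2-D per-slice segmentation with 8-connectivity — the manual
  procedure it mirrors operates slice by slice; no 3-D region growing;
- one threshold per slice (each seed pair yields its own), rather than
  one per gland — thresholds adapt to per-slice coil shading;
- hole filling via the border-connected background complement of the
  slice, which is exactly "selecting the interior of the surrounded
  area";
- seeds are explicit programmatic inputs standing in for the
  radiologist's picks; there is no automatic gland detection.

Equal-to-threshold voxels are included (≥, not >); this is the
tie-break that makes the midpoint-of-two-voxels rule include the
interior reference itself when gland and background meet at the
threshold exactly.

## Fusion and measurement

The ROI (drawn on the b = 500 image) and the ADC map come from the same
acquisition, so the default transfer is the identity. When grids
differ, each target voxel centre is mapped into the mask grid and
sampled nearest-neighbour — a label is never interpolated. The
per-gland statistic is the pooled arithmetic mean over all ROI voxels
across slices; "average of the pixels chosen in each slice" is
ambiguous between pooled and slice-averaged, and pooled is the standard
ROI statistic. The slice-mean variant is exposed
(`measure_mean_adc(..., method="slice_mean")`) for sensitivity checks;
the two coincide when slices contribute equally.

## Phantom

The generator emulates the acquisition geometry and contrast that the
measurement relies on, not scanner physics:

- grid 64 × 64 × 16 voxels at 2.0 × 2.4 × 5.0 mm (axial slices along
  the last axis) — in-plane resolution of a typical 172 × 133 matrix
  over a ~345 × 321 mm abdominal field of view, 5 mm slices;
- b = (0, 20, 500, 1000) s/mm²;
- suppressed-fat background: ADC 0.30 × 10⁻³ mm²/s, S₀ = 50;
- two kidney ellipsoids: ADC 1.90 × 10⁻³, S₀ = 600, placed ≥ 2 voxels
  from the glands;
- two adrenal glands as inverted-Y shapes (limb length 5, half-width 1
  voxel) spanning 3 slices, tapered at the end slices; ADC
  1.44 × 10⁻³ (right) and 1.58 × 10⁻³ (left), S₀ = 1000. At b = 500
  the gland-to-fat contrast is ≈ 10:1.

Gland size and shape are configuration, not measurement: no published
voxel dimensions exist for the real glands, so the defaults are a
plausible small-organ geometry and the segmentation claims should be
read accordingly. Rician noise is realised as |S + N(0,σ) + i·N(0,σ)|
per voxel per b-value, the standard magnitude-image model; it
reproduces the upward low-SNR bias but none of EPI distortion, motion,
respiratory or chemical-shift artifacts, partial-volume mixing at gland
boundaries (phantom voxels are pure compartments), or anatomical
variability. Passing the phantom suite therefore demonstrates
correctness of the algorithms under the stated model, not clinical
performance.

Ground-truth seeds imitate the reader: per gland slice, the interior
reference is the dimmest in-mask voxel and the exterior reference the
brightest voxel in a two-voxel shell outside the gland, both read off
the (noisy) image nearest b = 500.

The roster generator assigns exclusion flags in disjoint blocks in
cascade order, so configured counts are recovered exactly; survivors
receive ages and Tanner stages from configured ranges (defaults: 12
prepubertal, ages 0.17–12.5 y, Tanner 1; 20 postpubertal, 11.9–61 y,
Tanner 2–5 or unstaged adults). The reader-table generator produces
truth + per-reader bias + Gaussian noise per (subject, reader, session),
clamped at zero (never binding at realistic ADC scales).

## Statistics

- Normality gate: Shapiro–Wilk at α = 0.05 on each group; both must
  pass for the t branch.
- The default t-test is Welch's (unequal variances): the compared
  groups differ in size and spread, and "Student's t-test" in clinical
  reports rarely specifies pooling. The pooled-variance form is
  available via `equal_var=True`.
- Non-normal (or zero-variance) groups fall to the two-sided
  Mann–Whitney test — exact enumeration for small tie-free samples,
  normal approximation with tie correction otherwise (scipy's `auto`
  policy) — with a Hodges–Lehmann shift CI.
- Summary-statistic comparisons use the textbook Welch formulas
  (t, Welch–Satterthwaite df, CI of the difference) from (mean, SD, n)
  alone. Recomputing a published comparison from rounded summaries will
  not reproduce its raw-data p-value exactly; agreement is expected in
  sign and significance, not digits.
- ICC: two-way random-effects ANOVA mean squares, all four forms.
  The default reported form is absolute agreement (a systematic reader
  shift should count as error in a reliability claim); consistency
  forms are reported alongside because "average ICC" phrasing in the
  literature does not disambiguate. CIs use the exact F bounds for
  consistency forms and the Satterthwaite-approximate bounds for
  agreement forms. Degenerate inputs: identical rater columns give
  ICC = 1 (MSE = 0 is nudged only inside the CI formulas to keep F
  bounds finite); a table with no between-subject variance raises
  rather than returning a meaningless ratio.

## Problem sizes and determinism

The phantom suite runs at the default 64 × 64 × 16 grid; noisy-recovery
checks use 50 replicates at SNR 20 (defined on the mean gland signal at
b = 500), which bounds the Monte-Carlo error on the replicate-mean ADC
well below the 5% recovery criterion. ICC cross-checks use 100 random
tables of 5–19 subjects × 2–5 raters. All generators draw from a single
`numpy.random.Generator` seeded per spec; repeated calls with the same
spec are bit-identical. The acceptance script derives every sub-seed
from its `--seed` argument.

The variance components behind the acceptance script's simulated reader
tables are package choices: subject SD 0.22 × 10⁻³ mm²/s (the scale of
the printed cohort SDs), inter-reader bias 0.02 × 10⁻³, reading noise
0.08 × 10⁻³, and intra-reader session noise 0.05 × 10⁻³ — realistic
reading-error magnitudes for a structure this small.

## Known limitations

- No noise-floor correction in the ADC fit: at very low SNR the Rician
  bias flattens the decay and the fitted ADC is biased low; at the
  phantom's SNR 20 this bias is ≈ 0.1%.
- Nearest-neighbour fusion only; no deformable registration, no
  partial-volume handling.
- The segmentation cannot separate cortex from medulla, and no
  automatic detection is attempted — seeds must be supplied.
- BMI-for-age arrives as a precomputed flag; growth-chart computation
  is out of scope.
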