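# Methods

This note documents the models, defaults and numerical choices behind
`qmapsr`, and what the desk-scale experiments do and do not show.

## Synthetic cohort

Each subject is a 2-D phantom on the high-resolution display grid
(default 512 × 512, field of view 220 mm, 0.43 mm pixels; tests and the
shipped desk configuration use proportionally scaled grids). Geometry
is procedural, not anatomical: a head-like ellipse with seeded
low-frequency radial wobble, a cortical gray-matter (GM) ribbon (~4 %
of the grid thick), a white-matter (WM) interior and two elliptical
cerebrospinal-fluid (CSF) ventricles. The agreement battery only needs
labelled compartments with realistic values and subject-to-subject
variability, so anatomical registration is deliberately out of scope.

Tissue values are drawn hierarchically: one subject-level draw per
tissue per parameter from Normal(mean, SD), then Gaussian within-tissue
pixel jitter with SD = 1 % of the tissue mean (avoids degenerate
zero-variance regions while keeping tissue contrast dominant). Values
are clipped to the representable range `[0, stored_max × 0.1]`
(stored maxima 43,000 / 20,000 / 1,600 for T1 / T2 / PD; the DICOM
rescale slope is 0.1, i.e. stored integer = 10 × physical).

Healthy-tissue defaults are the routine-scan cohort statistics for GM
(T1 1232.65 ± 34.98 ms, T2 93.33 ± 3.50 ms, PD 80.11 ± 1.23 %) and WM
(837.86 ± 35.88 ms, 79.92 ± 2.05 ms, 68.21 ± 1.29 %). Lesion classes
(white-matter hyperintensity, infarct, encephalomalacia) default to the
midpoints of the reported lesion ranges with SDs wide enough to span
them. CSF values are not reported anywhere usable, so the default —
T1 4000 ms, T2 300 ms, PD 100 % — is an explicit, overridable guess
anchored on encephalomalacia (T1 3469–3893 ms, T2 272–350 ms,
PD 101–108 %) being described as CSF-like tissue. Background is zero
and is not modelled further.

Region masks partition each tissue into contiguous angular sectors
(10 GM, 9 WM by default), standing in for atlas regions of interest:
they exercise the per-region statistics without claiming anatomy.
Lesions are disjoint discs (1.5–3 % of the grid in radius) placed
rejection-sampled strictly inside eroded WM, so they can never touch GM
or CSF. Cohort splits are subject-level (round(n × fraction), clamped
so both sides are nonempty); training members are always lesion-free,
mirroring a healthy-only training set.

## Degradation model

No forward model of the multidynamic multiecho sequence is attempted
(the real fast scan is a genuine acquisition, not a degradation of the
routine one). The standard low-resolution MRI surrogate is used
instead: centred k-space truncation to the protocol's acquisition
matrix (frequency axis = image rows), zero-fill reconstruction to the
display grid, real part, negatives clipped to zero.

Two numerical details matter:

* **Symmetric truncation.** For an even crop the raw kept band
  (−K/2 … K/2−1) is conjugate-asymmetric; taking the real part of its
  inverse transform leaks energy onto the +K/2 line, which a second
  crop would remove — truncation would not be idempotent. The unmatched
  −K/2 Nyquist line is therefore zeroed, making the kept band
  symmetric, the output exactly real and the operation exactly
  idempotent. A full-axis crop leaves the axis untouched (identity).
* **Clipping.** Negative ringing is clipped because quantitative values
  are physical. Clipping is nonlinear; repeating the truncation on a
  clipped image changes it at the ~1 % energy level for aggressive
  crops. Exact idempotence holds on the `clip=False` linear path.

Noise is seeded complex Gaussian added in k-space (unitary transform
convention), with the protocol's base sigma (stored-intensity units)
amplified by `sqrt(accel_factor × display-area / acquired-area)` —
fewer samples at higher acceleration means noisier maps. Routine scans
default to noiseless; fast-scan sigmas (90 / 8.5 / 7 stored units for
T1 / T2 / PD) were chosen so the fast map's WM pixel SD lands near 3×
the routine map's at the native 512 scale (measured ratio ≈ 3.3). At
small desk grids truncation ringing dominates the routine map's pixel
SD, so the realized ratio there is lower; this affects nothing the
tests assert. No coil, partial-Fourier, motion or B1 model is included.

## Network and training

Generator: 9×9 convolution + ReLU head; five residual blocks (3×3
conv – batch norm – ReLU – 3×3 conv – batch norm, identity skip); a
post-residual 3×3 convolution summed with the head activation (long
skip) under ReLU; a 1×1 convolution into one sub-pixel (pixel-shuffle)
stage per factor of 2; tanh output. The pre-shuffle convolution uses
ICNR initialization (identical sub-pixel kernel groups), so upsampling
starts as nearest-neighbour interpolation and the early iterations are
free of checkerboard artifacts. One input/output channel — each
parameter map gets its own model with identical hyperparameters.

Discriminator: eight 3×3 convolutions, channel plan
64,64,128,128,256,256,512,512 at full scale (strides alternate 1/2),
leaky-ReLU (slope 0.2), batch norm on all but the first convolution,
then a global-average-pooled fully connected head with sigmoid output.
Channel widths are not dictated by the architecture description and
follow the conventional doubling plan; the pooled head keeps the
discriminator input-size agnostic. Labels: real → 1, generated → 0,
trained with binary cross-entropy on both halves.

Composite generator loss `L1 + 1e-3·adversarial + 2e-6·perceptual`.
The adversarial term is the batch sum −Σ log D(G(x)) with
probabilities clamped to [1e-7, 1−1e-7] before logs. The perceptual
term is a mean squared distance in the feature space of a **fixed,
seeded, randomly initialized** convolutional stack with VGG-style
topology (conv-conv-pool-conv-conv, features at the fourth
convolution's activation), evaluated on the normalized images shifted
to [0, 1]. The distance is well defined for any fixed feature map; a
hook accepts externally trained filters for users who want a
pretrained feature space. Random features keep the artifact fully
self-contained and seeded.

Optimization: Adam (β 0.9/0.999), learning rate 1e-3 — the printed
"1×10^3" rate is treated as a typo for 1e-3 — halved every 1,000
iterations (decay factor unstated; 0.5 chosen). Batch size 8, 200
epochs at full scale; slices are pooled and reshuffled each epoch with
the run seed. Everything is float64 numpy on one thread, so a fixed
seed reproduces training bit for bit.

The whole engine (`qmapsr.nn`) exposes explicit `forward`/`backward`
layers; every layer is verified against central finite differences in
the test suite. One analytic subtlety: a convolution bias feeding batch
norm has exactly zero gradient (the mean subtraction removes it), which
the tests handle with absolute rather than relative tolerance.

## Desk-scale study conditions

The shipped default experiment uses 12 subjects (8 train / 4 test,
subject-level split), 64-pixel high-resolution grids with
proportionally scaled acquisition matrices (routine 40×32 → 64 grid;
fast 24×16 → 32 grid), one slice per subject, base 16 generator
channels, batch 4, and 1,000 training iterations — about 7 minutes on
one CPU for the T1 model. These are the package's own desk-scale
choices: large enough for the qualitative claims below, small enough to
run anywhere. `full_scale_config()` carries the full-size settings
(151 subjects, 512 grids, batch 8, 200 epochs) but is not exercised by
the tests.

What the desk experiment shows, and what it does not: training
reduces the smoothed composite loss; the reconstruction beats zero-fill
upsampling on SSIM/PSNR against the reference on held-out subjects; and
mean NIQE orders the methods fast > DL > routine. These are qualitative
properties of the method under the simulator. Cohort-level clinical
numbers (tissue-value tables, per-region CVs, regression slopes on
patient data) depend on real scans and are **not** reproduced by the
synthetic cohort; the published tissue statistics enter only as
phantom parameters, and the published lesion table ships as data for
the statistics battery.

## Image quality metrics

Metrics run on the stored-intensity scale (physical × 10) so the
16-bit dynamic range L = 65,535 applies. PSNR = 10 log10(L²/MSE) (the
standard reading of the index; identical images return an infinity
sentinel). SSIM uses K1 = 0.01, K2 = 0.03 and local statistics from a
Gaussian window (σ = 1.5, truncated at 3.5 σ → 11×11), with the
window-radius border cropped before averaging; it matches the
scikit-image reference implementation to 1e-4 on seeded pairs.

NIQE: mean-subtracted contrast-normalized coefficients (local Gaussian
μ/σ, σ-field offset 1), generalized-Gaussian moment-matching fit (shape
grid 0.2–10, step 0.001) plus asymmetric-GGD fits of the four
neighbour products, 18 features per scale × 2 scales = 36. Pristine
patches are selected by mean local σ ≥ 0.75 × the sharpest patch (fit
time only). The score is the Mahalanobis-type distance between feature
Gaussians with the pooled covariance pseudo-inverted. The pristine
model is fitted on simulated routine maps — no external natural-image
model is downloaded — and the patch size scales with the grid (96 at
512, 16 at the desk scale) so the 36-dimensional covariance stays well
conditioned; fast scans are scored on their native display grid, as
acquired. NIQE magnitudes are therefore not comparable to
natural-image NIQE scores; only the ordering across methods is
meaningful here.

## Agreement battery

Per-subject regional means feed: two-sided paired t (df = n−1;
zero-variance differences are flagged degenerate rather than given a
p-value); TOST equivalence with ε = 5 % of the reference-method mean,
declared when the 90 % t-based CI of the mean difference lies inside
(−ε, ε); ordinary least squares of test on reference; Bland-Altman on
percent differences with the **pair mean** as denominator (the
standard ratio convention; configurable by computing from the returned
vectors), bias ± 1.96 SD limits; intragroup CV = 100 × SD/mean across
subjects within a method; intergroup CV = SD of the per-method means
over their grand mean — with two methods this is the literal
two-number CV and is accordingly noisy, which is documented rather
than hidden. GM and WM are pooled by concatenating per-subject tissue
means for the regression and Bland-Altman summaries. P-values are
rounded to two decimals only at report time.

The shipped 12-ROI lesion table reproduces its published T1 and T2
paired-test p-values (0.67, 0.73). The published PD value (0.75) is
reproduced by an *unpaired* two-sample test on the same columns, not
by the paired test the methods describe (which gives 0.017); the
package computes the paired test and `verify-published` reports the PD row
as failed — an intentional, honest discrepancy.

## Known limitations

* Procedural geometry: no gyri, no partial-volume mixing beyond
  truncation blur, one slice per subject by default — per-region CVs
  are driven by sampling noise, not anatomy.
* The degradation model shares its operator between "routine" and
  "fast"; real protocol differences (echo-space sampling, vendor
  zero-fill filtering) are not modelled, so systematic T2
  underestimation seen clinically has no synthetic counterpart.
* The perceptual loss uses random fixed features unless pretrained
  filters are supplied.
* Desk-scale GANs are partially converged by design; metric magnitudes
  depend on the training budget even though the tested orderings are
  stable across seeds.
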