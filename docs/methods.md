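# Methods

`vinotrace` implements a complete wine origin-traceability analysis for
near-infrared (NIR) spectra: metabolomics-guided selection of
characteristic wavelength bands, generalized two-dimensional correlation
spectroscopy (2D-COS), and image-based classification with a small CNN
against LDA/SVM baselines.  Because no public dataset with this design
exists, the package ships a first-class synthetic-data module that
emulates the study: six production regions, 30 bottles per region, each
measured by ten repeated NIR scans on a 900–2500 nm grid at 3.2 nm
resolution (501 grid points), plus a matched UPLC-Q-TOF-MS-style
metabolite peak-area table.

## The synthetic study

Each bottle's clean spectrum is a linear baseline plus five Gaussian
absorption peaks at 1123, 1281, 1592, 1650 and 1805 nm (default apex
amplitudes 0.30/0.25/0.35/0.30/0.28 absorbance units, FWHM 30 nm).  A
scan of sample *s* in class *c* at scan index *j* is

    x_sj(v) = a_s · [base(v) + Σ_p (A_p + δ·w_c[p]) G_p(v)] + b_s
              + j·d·S(v) + ε

* **Class effect** δ = `class_effect_size` (default 0.06 absorbance at
  the apex, i.e. ~20 % of a peak amplitude).  The unit pattern `w_c`
  assigns consecutive peak pairs `(cos θ_c, sin θ_c)` with
  θ_c = π·c/n_classes and a fixed π/4 offset per pair.  Two properties
  are deliberate: (i) inside each characteristic window (which holds two
  peaks) every class shifts the local amplitudes in a *distinct
  direction*, so classes remain separable after per-image contrast
  normalization; (ii) angles span only a half-turn, so no two classes
  are antipodal — the synchronous spectrum, whose leading term is an
  outer product and therefore blind to an overall sign, still
  distinguishes every pair.
* **Multiplicative scatter**: per sample, slope `a_s = exp(N(0, 0.05))`
  and offset `b_s = N(0, 0.02)` — an affine distortion by construction,
  so multiplicative scatter correction (MSC) is its exact inverse.
* **Scan-to-scan drift**: the perturbation that 2D-COS correlates.  It
  is modeled as a linear growth of the absorption peaks over the scan
  series (`d` = `drift_per_scan`, default 0.003 apex-absorbance per scan
  index, shape `S(v)` = unit-apex peak sum), the kind of gain drift
  temperature change or evaporation produces during a measurement
  session.  A wavelength-constant offset drift would be annihilated by
  the first-derivative step and leave the asynchronous spectra
  noise-driven; peak-shaped drift survives the preprocessing chain.
* **Noise**: white, sd 0.002 absorbance per grid point (the instrument
  class emulated here is specified at very high signal-to-noise).

The metabolite table draws peak areas (arbitrary units, base means
~79–93, sd 4) for the marker panel {indole, sulfacetamide, caffeine};
the *i*-th differential compound is elevated by 10 units (2.5 sd) in
class *i*.  With `differential=[]` the table is an exact null, used for
type-I calibration.

What the generator does **not** emulate: Beer–Lambert mixture physics,
wavelength-dependent pathlength effects, instrument line-shape
functions, correlated (pink) noise, or any real chemical assignment of
wine constituents.  Passing tests therefore demonstrate that the
*pipeline* recovers structure it is designed to detect under its own
stated noise model — not that the method would reach the same accuracy
on real wines.

## Preprocessing

The chain is MSC → Savitzky–Golay smoothing → first derivative, in that
order.  MSC regresses each spectrum on a reference by ordinary least
squares and applies `(x − b̂)/â`; the reference is the mean spectrum of
the data the chain is *fitted* on and is frozen for reuse on held-out
data, so no test-set information enters the correction.  S-G smoothing
uses an 11-point window and polynomial order 2 (standard chemometrics
defaults; both configurable), with edge points handled by polynomial
fits on the truncated window (`mode="interp"`).  The first derivative
uses the same S-G filter with `deriv=1`, scaled by the 3.2 nm grid step
(units: absorbance/nm).  Preprocessing is applied to the full grid
before band cutting, so the derivative sees no artificial band edges.

## Band selection

Each compound in the peak-area table is Welch-tested one region versus
the pooled rest (two-sided); the most extreme of the `n_classes`
contrasts is reported.  Because that contrast is *selected*, the raw
p-value is Šidák-adjusted, `p = 1 − (1 − p_min)^K` with `K = n_classes`
(K = 1 for two classes, where both contrasts coincide).  Null
simulation over hundreds of seeded replicates puts the per-compound
false-flag rate at ~0.049 for α = 0.05; the unadjusted selected p would
inflate it several-fold.  No across-compound multiple-testing
correction is applied by default (the screening stage treats each
compound as its own hypothesis); the adjusted and raw p-values are both
reported so any correction can be layered on.

Flagged compounds map to NIR windows through a compound → window lookup
shipped as data (CSV), defaulting to indole and sulfacetamide →
1000–1400 nm and caffeine → 1500–1800 nm, reflecting the functional-group
regions their structures absorb in.  Windows are merged when identical
and cut from the native grid as closed intervals, without interpolation.

## Generalized 2D correlation spectroscopy

For one sample the perturbation series is its m = 10 scans; the dynamic
spectrum is `y(v, t_j) = x(v, t_j) − x̄(v)`.  The default reference
`x̄` is the *grand mean* spectrum of the whole preprocessed sample set
within the band, so each sample's images encode how that sample's scan
series deviates from the population average — this is what makes the
images class-informative.  The textbook per-sample perturbation mean is
available via `reference_mode="perturbation_mean"`.

With `Y` the n × m dynamic matrix:

* synchronous: `Φ = Y Yᵀ / (m − 1)` — symmetric, positive semidefinite,
  diagonal auto-peaks are perturbation variances;
* asynchronous: `Ψ = Y N Yᵀ / (m − 1)` with the Hilbert–Noda matrix
  `N_jk = 1/(π(k−j))`, zero diagonal — antisymmetric, no auto-peaks.

The asynchronous formula is sometimes typeset as a product of two
independent full sums over the perturbation index; that form is
rank-one and violates the asynchronous spectrum's own defining
properties (zero diagonal, antisymmetry), so the standard single-sum
Noda form above is implemented.

An independent Fourier-domain route is kept as an oracle: the dynamic
spectrum is zero outside the observation window, so its transform is
computed as a zero-padded DFT (8× by default) and the one-sided
cross-spectrum's real/imaginary parts give Φ/Ψ.  The synchronous part
matches `Y Yᵀ/(m−1)` to machine precision (Parseval).  The asynchronous
parts differ by the truncated Hilbert kernel's gain rolloff — a
relative error of about `2f/m` for a component with `f` cycles over the
m-point window — so the two routes agree within a few percent for
slowly varying signals and converge as m grows.  The tests pin this at
< 5 % (Frobenius) for one-cycle signals at m = 64 and < 2 % at m = 200.

**Rendering.**  Each correlation matrix becomes a filled-contour raster:
bilinear resampling to 128 × 128, quantization into 16 level bands on a
diverging scale symmetric about zero with limits ±max|matrix|
(per-image normalization, recorded in the manifest), and colorization
through a fixed red–blue palette — no axes, labels or margins, so the
raster is a byte-deterministic function of (matrix, render config).
Per-image normalization maximizes contrast; it also means absolute
correlation magnitudes are not comparable across images, which is why
the generator guarantees classes differ in pattern *shape*, not only
scale.

## Classification

Samples are stratified-split 2/3 train / 1/3 test (120/60 samples, i.e.
480/240 images counting all four image types), repeatedly with seeded
splits; every model is refit per split and the mean train/test accuracy
per `model × band` cell is reported with all per-repeat values retained.
Splitting is at the sample level: all images of a sample stay on one
side, so sync/async or cross-band leakage is impossible.

* **CNN** (numpy implementation; no deep-learning framework is a
  dependency): three blocks of 3×3 convolution (8/16/32 channels) +
  ReLU + 2×2 max-pool, then a 64-unit dense layer and a softmax output
  trained with cross-entropy (Adam, learning rate 3·10⁻³, batch 32,
  20 epochs).  A softmax multi-class head is used rather than a single
  regression output neuron, which cannot represent six unordered
  classes.  Inputs are centered on the per-channel training mean
  (stored with the model and reapplied at prediction time); without
  centering, the background-dominated rasters destabilize training for
  a fraction of seeds.  Weight init and batch shuffling derive from one
  seed;
  training is bit-reproducible and single-CPU (im2col convolutions,
  float32, ~1 s/epoch on 120 contour images at 128 × 128).
* **Baselines**: LDA (SVD solver; lsqr + Ledoit–Wolf shrinkage when
  features ≥ samples or scatter is singular) and an RBF-kernel SVM
  (C = 1, γ = 1/(n_features · var), scikit-learn's `gamma="scale"`),
  both on 1-D features: the band-cut preprocessed spectra averaged over
  scans.

## Problem sizes and numerical choices

* Default study 6 × 30 × 10 scans; image generation for all 720 images
  takes ~2 s; one CNN repeat ~20 s on one CPU.
* Repeated-split counts: baselines 50 repeats; CNN cells 10 repeats
  (asynchronous) and 5 (synchronous) in the acceptance script — at these
  counts the cell means are stable to well under the differences of
  interest; the label-permutation check uses 3 repeats.
* Degenerate inputs are rejected loudly: constant MSC reference,
  non-uniform grid for derivatives, S-G window longer than the grid,
  single-scan perturbation series, non-square or non-finite matrices
  for rendering, classes too small to split or test.
* Ties in max-pooling resolve to the first maximal element (argmax),
  deterministically.

## Known limitations

* The CNN is deliberately small and trained to a fixed epoch budget; no
  early stopping, augmentation or hyperparameter search.
* The Fourier/Noda asynchronous comparison is an asymptotic agreement,
  not an identity; fast perturbation components (near Nyquist in the
  scan index) are attenuated by the Noda matrix relative to the Fourier
  definition.
* One-vs-rest screening reports a single contrast per compound; a
  full pairwise or omnibus design would detect patterns (e.g. two
  moderately elevated classes) that one-vs-rest can miss.
* With the grand-mean dynamic reference, images of all samples share
  one population mean computed over the full set; when strict
  train/test isolation of every statistic is required, the reference
  can be refit on training samples only (the API accepts any provided
  reference), at the cost of re-rendering images per split.
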