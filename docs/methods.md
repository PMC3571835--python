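# Methods

This note documents the models, conventions and numerical choices behind
hyperseed, in the spirit of a package reference manual: what each stage
assumes, which knobs matter, and what the synthetic benchmark does and
does not demonstrate.

## Hypercubes and calibration

A hypercube is stored as a `(rows, cols, bands)` float array with a
strictly increasing wavelength vector (nm). On disk the ENVI convention is
used (text header + raw binary; `bil`/`bip`/`bsq` interleaves; data types
restricted to unsigned 16-bit integers and little/big-endian 32-bit
floats — anything else is rejected loudly rather than guessed at).
Coordinates are 0-based and row-major with the origin at the image
top-left.

Reflectance calibration is `I = (I0 − B)/(W − B)` per voxel. Where
`W − B ≤ eps` (default `eps = 1e-8` on the raw-intensity scale) the output
is set to 0 and the voxel is recorded in a degenerate-denominator mask;
reflectance values outside `[0, 1.5]` are *kept* — clipping would distort
the min–max quantization that feeds the texture features — but counted in
a QC report carried in `cube.meta`. Calibration is invariant to scaling
`I0, W, B` by a common positive constant, which the suite checks as a
property.

Spectral cropping keeps the closed interval `lo ≤ λ ≤ hi`; the default
analysis window is 500–900 nm because the extremes of a VIS-NIR
spectrograph's range are low-signal. ROI extraction draws pairwise
non-overlapping square windows by seeded rejection sampling (cap: 10·n
proposals), falling back to a seeded shuffle of the non-overlapping grid
tiling so that every feasible request succeeds deterministically.
Non-overlap is deliberate: overlapping ROIs would duplicate texture
statistics across "samples".

## Spectral features

Each ROI contributes one sample: its per-band pixel mean. PCA is computed
by SVD of the centered data matrix (numerically preferable to an explicit
covariance eigendecomposition; the suite proves equivalence against that
oracle). Every loading column is sign-fixed so its largest-magnitude
element is positive, removing eigenvector sign ambiguity from downstream
comparisons.

Kernel PCA builds `K_ij = exp(−‖x_i − x_j‖²/(2σ_k²))`, double-centers it,
eigendecomposes, and rescales eigenvectors by `1/√λ` so feature-space
components have unit norm; out-of-sample projection reuses the stored
training centering statistics. `σ_k² = "auto"` applies the median
heuristic (median pairwise squared distance). If fewer than the requested
number of positive eigenvalues exist, `k` shrinks with a recorded
warning. A linear-kernel hook exists purely so tests can assert the
KPCA ≡ PCA identity on arbitrary data.

Both decompositions default to 3 retained components, the customary
choice when the first three components explain ≈99 % of spectral
variance, as they do for smooth reflectance data.

**Kernel parameterization caveat**: KPCA uses the `2σ²` divisor form
while the LS-SVM uses `exp(−‖u−v‖²/σ²)` so that its searched `σ²` matches
the convention of classical LS-SVM toolboxes. The two modules document
their own convention; do not exchange widths between them.

## Band selection

A pixel-level PCA (pixels as observations, bands as variables) is fitted
once on a montage of all *calibration* ROIs — a dataset-level fit gives a
single global band set. Because a 64×64 ROI already holds 4096 pixels,
the montage subsamples a seeded 512 pixels per ROI by default; the
loadings of a smooth spectral process are insensitive to this.

Local extrema of each loading are found with a centered odd window
(default 11 bands): a point qualifies if it attains the window maximum or
minimum, plateaus resolving to the lowest index; array endpoints are
eligible through truncated windows but are *excluded* from selection by
default since spectrum edges are noise-prone. Candidates from the first
three loadings are ranked by |loading| (ties by band index) and kept
greedily subject to a ≥10 nm pairwise separation until `k_bands` (default
3) are chosen. The rule is scale-free, deterministic, and permutation
invariant; a candidate shortfall returns all candidates with a warning
flag rather than failing.

## Texture

Band images are quantized by linear min–max binning to `Ng` levels
(default 8, an era-typical choice for co-occurrence analysis; constant
images map to level 0). The GLCM uses the 0°, distance-1 offset
`(dr, dc) = (0, 1)` and is symmetric by default (counts plus their
transpose), following the classical definition. Four features are
computed: contrast, homogeneity in the inverse-difference form
`1/(1+|i−j|)` (documented because common tools differ — e.g. some use
`1/(1+(i−j)²)`), energy as the sum of squared probabilities (some tools
report its square root), and marginal correlation with the convention
`corr = 0` when a marginal is degenerate so feature vectors stay numeric.
Features are invariant to adding a constant to the image, a direct
consequence of min–max binning.

## Classifiers

**LS-SVM.** Each one-vs-one pair solves the dense `(n+1)` system
`[[0, yᵀ],[y, Ω + I/γ]]·[b; α] = [0; 1]`, `Ω_ij = y_i y_j K(x_i, x_j)`.
The relative solve residual is stored and must be ≤ 1e-8; a singular
system raises with a suggestion to lower `γ` (i.e. increase the ridge).
Votes are tallied per class, zero decision values vote the earlier class,
and vote ties resolve to the earliest class in lexicographic class order.
One-vs-one was chosen over one-vs-rest because it keeps each linear
system small and matches the practice of classical LS-SVM toolboxes.

**Grid search.** Stratified k-fold (default 10) CV per `(γ, σ²)` over
`γ ∈ {2⁻¹ … 2¹⁰}`, `σ² ∈ {2¹ … 2¹⁵}` with integer exponent steps. The
selection criterion is RMSECV over integer class codes (first-appearance
order) of held-out predictions — a pragmatic way to give a classification
task a smooth CV loss. Ties break toward smaller `σ²`, then smaller `γ`.
Fold assignment deals each class's shuffled indices round-robin, so every
class appears in every fold.

**BPNN.** One hidden layer of 9 logistic-sigmoid nodes (interpreting the
traditional "9 hidden" recipe as nodes, not layers — a nine-hidden-layer
sigmoid network would not have been trainable by plain momentum descent),
sigmoid outputs against one-hot targets, batch gradient descent with
classical momentum 0.6 on the mean squared error, weights initialized
uniform(−0.5, 0.5) from a seeded generator, stopping at MSE ≤ 1e-5 or
1000 epochs. The learning rate defaults to 0.5: gradients are normalized
as the mean over all `n·C` output entries, and with that normalization a
0.1 step demonstrably stalls within the 1000-epoch budget on
standardized 3–15-dimensional inputs. Prediction applies the ±0.5 band
rule — class `c` only if output `c` is strictly within 0.5 of 1 *and*
every other output strictly within 0.5 of 0 — and unrecognized samples
count as errors. In evaluation reports the confusion matrix covers
recognized predictions and a separate per-class unrecognized tally keeps
row sums reconcilable with truth counts.

## Experimental design and leakage

The split is stratified per class with a seeded permutation; the default
calibration fraction scales the classic 40-of-55 design to the actual
class size (e.g. 15 of 20). All fitted stages — PCA, KPCA, montage PCA
and band selection, feature autoscaling (z-score on calibration
statistics), grid search, classifier training — see calibration samples
only; the run log records the sample ids each such stage touched and the
pipeline asserts they are a subset of the calibration set on every run.
Accuracies are reported to 2 decimals (full precision kept internally);
summaries are byte-identical across reruns with the same configuration
and seed.

## Synthetic data: what it emulates and what it does not

Each variety is a smooth reflectance signature on 380–1030 nm (baseline +
Gaussian bumps, values inside (0, 1)) modulated multiplicatively by a
spatial texture pattern (stripes, checker, or low-pass-filtered noise
"blobs"; zero-mean, amplitude below the signature minimum so reflectance
stays positive). Per-sample variability has three seeded components:
an illumination gain ~ N(1, 0.02), a jitter of each bump amplitude
~ N(0, 0.008) standing in for within-class biological variation, and
i.i.d. Gaussian pixel noise (sd 0.01). Raw cubes are produced by
inverting the calibration equation against shared reference frames
(white 0.95 with a mild sinusoidal spatial ripple, black 0.02), so the
calibration stage is exercised non-trivially and recovers the generated
reflectance exactly in the noiseless limit.

The roster of six varieties contains one deliberate twin pair (II and V):
signatures ~0.002 RMS apart — below the 0.008 amplitude jitter, hence
spectrally inseparable in principle — but with different texture
patterns. This encodes the qualitative phenomenon the pipeline targets:
varieties of similar colour need texture features for reliable
separation. All other pairs are ≥0.03 RMS apart and spectrally easy.

Default problem size is 20 samples per variety on 64×64×128 cubes, which
keeps a full experiment under half a minute on one CPU while leaving
every stage statistically meaningful; 100×100×512 generation is available
(`hyperseed simulate --full-size`) and scales linearly. What passing
tests on this generator do **not** show: radiometric realism of actual
seeds (no specular highlights, no seed-shape segmentation, no wavelength-
dependent noise), instrument effects (smile/keystone, stray light), or
that the specific accuracy numbers transfer to any real dataset — the
synthetic benchmark validates the machinery and the qualitative ordering
of feature sets, not field performance.

## Known limitations

* Only the 0°, d = 1 GLCM offset is wired into the pipeline (other
  offsets are available at the API level); no rotation-averaged texture.
* No spectral preprocessing beyond cropping (no SNV/MSC/derivatives).
* RMSECV on integer class codes penalizes confusions between
  distant-coded classes more than adjacent ones; with the default
  near-separable grids this has no practical effect, but it is a known
  quirk of using a regression loss for classification CV.
* The BPNN is a faithful period piece — batch momentum descent without
  early stopping or adaptive rates — and is expected to lose to the
  LS-SVM, which is part of the comparison's point.
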