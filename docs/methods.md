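# Methods

`weedspec` implements a complete proximal-hyperspectral pipeline for
discriminating rice from paddy weeds at species level: radiometric
calibration, exploratory spectral analysis, and a spectral–spatial
convolutional classifier (SS-CNN) with superpixel and channel-attention
modules, plus a synthetic scene generator so the whole pipeline is testable
without camera data.

## Radiometric model

Cameras record digital numbers, not reflectance. With a dark frame
`D_dark` (sensor offset) and a white frame `D_white` recorded over a
near-perfect (≈99 % reflective) diffuse reference panel, per-pixel, per-band
reflectance is the two-point calibration

    Re = (D_raw − D_dark) / (D_white − D_dark).

Dark/white frames may be per-band vectors or full frames; both broadcast.
`white == dark` anywhere is an error by default (`on_degenerate="mask"`
zeroes those pixels instead). Atmospheric correction is out of scope: at
proximal range the panel calibration is the documented radiometric path.

The working wavelength range is 397–982 nm. The instrument's long-wavelength
tail (982–1003 nm) is noise-dominated and trimmed with `drop_noisy_bands`,
which keeps bands whose centers fall inside a closed interval; the retained
count therefore depends on the instrument's band table, not on a hard-coded
number.

## Spectral analysis

Vegetation indices are standard normalized band combinations
(NDVI = (ρ_NIR−ρ_RED)/(ρ_NIR+ρ_RED), PRI = (ρ531−ρ570)/(ρ531+ρ570),
EVI = 2.5(ρ_NIR−ρ_RED)/(ρ_NIR+6ρ_RED−7.5ρ_BLUE+1)). Index bands are resolved
to the *nearest* grid band (ties to the lower wavelength) with defaults
NIR 800 nm, red 680 nm, blue 470 nm — the red chlorophyll-absorption valley
sits at 680 nm and the NIR plateau is fully developed by 800 nm. Per-cube
indices are computed per pixel and summarized over an ROI as the mean of the
per-pixel values (the alternative — index of the ROI-mean spectrum — is
available by combining `extract_roi_mean_spectrum` with the scalar ops).
Undefined pixels (zero denominators) propagate as NaN and are excluded from
ROI means.

PCA is mean-centered with no variance scaling (all bands share reflectance
units). Loading signs are fixed by forcing the largest-magnitude element of
each loading non-negative, so decompositions are reproducible across runs.

## Superpixelwise division

Two operations realize the "superpixelwise division" stage:

1. **Band reduction** `C → B` by per-pixel projection onto the top-B
   principal spectral components (default B = 25, matching the classifier's
   (25, 25, 25, 1) input). Loadings and mean are stored so the projection is
   invertible up to truncation error.
2. **Entropy-rate superpixels (ERS)**: pixels are nodes of a grid graph
   (8-neighbour by default, 4 available); edge similarity is a Gaussian
   kernel on feature distance with bandwidth equal to the median *positive*
   edge distance. Edges are selected greedily (lazy evaluation, max-heap,
   ties by edge index — fully deterministic) to maximize the entropy rate of
   a random walk on the selected subgraph plus λ times a balancing term that
   favours equal segment sizes, stopping at exactly K connected segments.
   Because the entropy term scales with edge weights while the balancing
   term is O(1) per merge, λ (default 0.5) is normalized by the ratio of the
   initial maximal gains of the two terms, making it dimensionless; without
   this the balance term dominates and segmentation ignores image content.
   Intra-segment (cycle) edges are selected only while their marginal gain
   is positive; the objective is non-decreasing along the greedy sequence.

`superpixel_smooth` replaces each pixel's reduced spectrum with its segment
mean — an idempotent projection that conserves per-band global means and
injects spatial context before window extraction. It is applied for the SS
and SD variants and skipped when the superpixel module is ablated.

**Segmentation features.** Superpixels are grown on the top-5 principal
components of *brightness-normalized* spectra (each spectrum divided by its
mean; `ers_features`), not on raw PC1. Canopy pixels of one species vary
strongly in albedo (leaf angle, illumination), so raw PC1 tracks brightness
and segments cut across species; normalizing first makes boundaries follow
spectral shape. On synthetic scenes this reduces class-impure segment pixels
from roughly 40 % to near zero at high difficulty. The default segment count
is ⌈MN/625⌉ (one 25×25 window per segment on average) and is configurable;
the scaled experiments below use K = 200 on 64×64 scenes (≈ 20 px/segment).

## Patch dataset

Each labeled pixel (label ≥ 1; 0 = background) yields one w×w×B window
centred on it (w odd, default 25), with the centre label as target. Borders
are edge-replicated (zero padding available) so all labeled pixels are
usable. Train/test splits draw a fraction Tr per class (round-half-up,
floor 1), seeded and deterministic; 10-fold stratified cross-validation is
available. Windows of nearby train/test samples overlap spatially — the
standard protocol in patch-based HSI classification, and a known source of
optimistic bias that we document rather than hide.

## The SS-CNN

The full network consumes (25, 25, 25, 1) patches: three 3-D convolutions
(kernels 3×3×7, 3×3×5, 3×3×3; 8/16/32 filters) learning joint
spectral–spatial features; a reshape folding the 13 remaining spectral
positions × 32 filters into 416 channels; two batch-normalization layers;
four 3×3 2-D convolutions (32/64/128/256 filters); a squeeze-and-excitation
(SE) gate (squeeze = global spatial mean per channel, excitation = bottleneck
MLP with reduction 16 and sigmoid output in (0,1) rescaling each channel);
flatten; dense 256 and 128 with dropout 0.4; and an n-class softmax head
(n = 36 for the full rice + 35-weed catalogue). All convolutions are valid
(no spatial padding), so each layer shrinks the map by kernel−1.
`build_model` derives every output shape and parameter count from first
principles and raises on any inconsistent chain; `build_network`
instantiates exactly that chain and cross-checks its parameter total.

Two documented source ambiguities are exposed as switches rather than
resolved silently: the activation (`relu` default, `softsign`
x/(1+|x|) selectable) and batch normalization (`use_bn`, default on).

Training: Adam (lr 1e-4), softmax cross-entropy, mini-batches of 32,
50 epochs, variance-scaling uniform weight initialization, no data
augmentation. A single integer seed determines initialization, batch order
and dropout masks, so runs are bit-reproducible in single-threaded
execution. The engine is pure numpy (channels-last, offset-loop
convolutions feeding BLAS matmuls); every layer's backward pass is verified
against central finite differences in the test suite.

Ablation variants: SS (everything), SD (no SE), SE (no superpixel
smoothing), CNN3D (3-D stack only), CNN2D (2-D stack on the reduced bands
as channels). `ablation_suite` trains every (variant, Tr, seed) cell and
tabulates OA/AA/Kappa and per-class PA/UA.

## Evaluation

Confusion matrices are rows = true, columns = predicted, labels 1..n,
background excluded upstream. OA = trace/N; AA = mean per-class recall;
Cohen's kappa = (N·trace − Σᵢ rowᵢ·colᵢ)/(N² − Σᵢ rowᵢ·colᵢ); PA = per-class
recall (row-normalized diagonal); UA = per-class precision
(column-normalized diagonal). Undefined per-class entries (empty row or
column, which occurs in few-shot regimes) are reported as NaN/null, never
coerced to 0; AA can either error on empty rows or drop them (both
conventions exposed). Metrics print as percentages to 3 decimals but are
stored at full precision.

## Synthetic scenes

Species signatures are smooth curves carrying the canonical vegetation
features: a green peak at 550 nm, a red valley at 680 nm, a logistic red
edge rising through 700–760 nm to a NIR plateau (760–930 nm), and a water
absorption dip at 935 nm, on a default grid of 197 evenly spaced bands over
397–982 nm (the post-trim working range). Per-class parameters occupy
shuffled even ladders over their ranges, so no two species are accidental
near-duplicates; a scalar `difficulty ∈ [0, 1]` shrinks between-class
spread by (1 − 0.95·difficulty) and grows within-class lognormal pixel
variability from 0.02 to 0.12. Scenes add per-band Gaussian noise
(default sd 0.01) and a low-rank spectrally correlated noise component;
background pixels follow a featureless soil ramp (NDVI < 0.4, vs > 0.4 for
canopy pixels by construction). Class layouts (compact claimed regions,
stripes, or Voronoi-like patches) hit requested pixel fractions exactly.
`make_calibration_frames` synthesizes dark/white/raw digital-number frames
whose calibration reproduces the cube to machine precision.

What the generator does *not* emulate: radiative-transfer effects
(leaf-angle distributions, specular glint, mixed boundary pixels,
illumination gradients), spatially correlated within-class texture, and
real spectral libraries. Passing tests on these scenes therefore
demonstrate correctness and qualitative behaviour of the pipeline, not
field-level accuracy on real paddies.

## Scaled reference experiments

The full 25×25×25 architecture (~8M parameters) is impractical to train in
pure numpy, so the packaged benchmarks (`weedspec.experiments`) use a
reduced-capacity configuration — 9×9 window, B = 8 reduced bands, 3-D
filters (4, 8) with kernels 3×3×5 and 3×3×3, 2-D filters (8, 16), one
32-unit dense layer, SE reduction 4, lr 1e-3 — while keeping scene
conditions at full size: 64×64 pixels, 6 species, ~70 % labeled pixels,
noise sd 0.01. Two regimes are exercised:

* **Recovery** (difficulty 0.3, Tr = 0.7, 20 epochs): the SS variant
  reaches ≥ 95 % held-out OA on every seed tested.
* **Few-shot ablation** (difficulty 0.7, Tr = 0.05, 40 epochs): the SS
  variant's mean OA exceeds the plain 2-D CNN's, reproducing the
  qualitative ordering that spectral–spatial feature extraction with
  superpixel smoothing matters most when labels are scarce.

## Numerical choices and edge cases

* Nearest-band lookup ties break to the lower wavelength; argmax label ties
  break to the lowest class index.
* Otsu masking on a constant image, empty ROIs, empty band selections,
  degenerate calibration references, zero index denominators and empty
  confusion matrices all raise typed errors instead of returning silent
  defaults.
* ERS similarity bandwidth uses the median of positive edge distances
  (constant images fall back to uniform weights).
* Softmax is computed with max-subtraction; sigmoid is evaluated in its
  numerically stable split form; cross-entropy clips probabilities at
  1e-300.

## Known limitations

* The numpy engine is CPU-bound; the full-scale architecture is buildable
  and checkable (`build_model`/`build_network`) but not practical to train.
* Patch-overlap between train and test windows inflates accuracy relative
  to image-level splits (documented above).
* ERS is greedy; it maximizes the entropy-rate objective approximately, not
  exactly (exactness holds on separable toys).
* Synthetic scenes are optimistic relative to field data in the ways listed
  above.
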