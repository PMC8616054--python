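# Methods

This note documents the models, algorithms, and design choices behind
`matriscope`, in the spirit of a methods supplement: what is computed, under
which assumptions, and where the synthetic data deliberately simplify
reality.

## 1. Synthetic fiber micrographs

The study system is the collagen-I microstructure of four polymerized
matrices imaged by immunofluorescence: a human breast-tissue matrix gel and
a porcine one (both interconnected fibrous networks, the human variant
denser), purified collagen I (very long straight fibers with minimal
crosslinking), and a basement-membrane-like matrix (short thick segments
forming honeycomb meshes). No raw micrographs are redistributable, so the
package generates seeded stand-ins with the same qualitative geometry and
verifiable quantitative contrasts.

Each image is built in two stages.

**Latent geometry.** A `FiberGraph` (nodes, width-annotated edges, derived
branch points = nodes of degree ≥ 3) is laid down per class:

* `long_fiber` — straight chords through the frame, each at least 80% of
  the image diagonal; no junction detection, so branch-point density is
  ~0 per 10⁵ px².
* `network_sparse` / `network_dense` — correlated random walks (step
  4 px, per-step turning angle ~ Normal(0, σ_turn) with σ_turn = 15° /
  25°), per-step branching probability 0.005 / 0.02 (side branches walk a
  shorter random length and do not branch again), and crosslinking: a
  walker passing within 2 px of previously laid fiber fuses to it, with a
  6-step refractory period so parallel-running fibers do not fuse at every
  step. Defaults (40 / 55 primary walkers × 200 steps) put branch-point
  densities at roughly 18–30 (sparse) and 120–220 (dense) per 10⁵ px², a
  robust ≥ 2× dense:sparse contrast at every seed tested.
* `honeycomb` — a centroidal Voronoi tessellation (~150 seeds, two Lloyd
  relaxation iterations, mirror-point reflection to close boundary
  cells), edges rendered at widths 2–4 px. Median edge length (~65 px) is
  far below 25% of the median straight-fiber length (~1470 px).

**Rendering.** Fibers are rasterized per width group: polyline pixels are
accumulated (each fiber contributes once per pixel; crossing fibers add),
then blurred with a Gaussian whose FWHM equals the fiber width, scaled so
an isolated fiber peaks near intensity 0.85. The signal goes to the green
channel (the fiber-stain channel by convention); all channels get a 0.02
baseline plus clipped additive Gaussian noise (sd 0.02). Frames are
1040 × 1440 px — the smallest size on which a 10 × 12 grid yields the
standard 120 tiles of 104 × 120 px — with a nominal 0.2 µm pixel.

Seeding: every fiber draws from its own child stream of the image seed, so
the first *k* fibers are identical when the fiber count grows — this makes
the rendered fiber-pixel fraction monotone in fiber count, a property the
tests exercise. Identical seeds give bit-identical rasters.

**What the generator does not model:** point-spread function, shot noise,
z-stack structure, fiber curvature of real collagen bundles, staining
heterogeneity, illumination gradients. Class differences are therefore
cleaner than in real micrographs; passing separation checks here shows the
pipeline can learn texture contrasts, not that it matches the published
feature indices (which depend on training randomness anyway).

## 2. Tiling and filtering

Frames are partitioned losslessly into a 10 × 12 grid (120 disjoint
104 × 120 × 3 tiles, row-major); non-divisible dimensions are rejected
rather than cropped. A tile's *fiber fraction* is the share of green-channel
pixels at or above an intensity threshold (default 0.1, i.e. ~4 noise SDs
above background). Tiles below a minimum fraction (default 0.01) are
dropped as "empty", above a maximum (default 0.60) as "over-dense";
survivors keep their order and every decision is logged in a filter report.
Filtering is idempotent. The thresholds are package defaults — the source
workflow removed "uninformative" tiles without publishing numbers.

## 3. Convolutional autoencoder

A 9-layer convolutional autoencoder maps 104 × 120 × 3 tiles to a
13 × 15 × 16 bottleneck and back:

* encoder (5 layers): conv3×3(3→8)+pool2, conv3×3(8→16)+pool2,
  conv3×3(16→32)+pool2, conv3×3(32→32), conv3×3(32→16) — three 2×
  max-poolings give exactly 104/8 = 13 and 120/8 = 15;
* decoder (4 layers): three upsample2+conv3×3 stages (16→32, 32→16,
  16→8) and a final conv3×3(8→3) with sigmoid output in (0, 1).

Hidden activations are rectified, so bottleneck maps are non-negative.
The loss is per-pixel binary cross-entropy between input and
reconstruction, averaged over pixels and batch; the optimizer is Adam
with decoupled weight decay 10⁻⁴ on convolution weights. Defaults:
batch 32, 50 epochs, learning rate 3 × 10⁻³. Kernel sizes and channel
widths are package choices (only the layer counts, bottleneck shape, and
loss family are externally fixed), and they matter at short training
budgets: with a narrow 8/16/16/16/16 encoder and mirrored decoder at
learning rate 10⁻³, the 16 bottleneck channels stay highly redundant
(mostly brightness-coded) after 25 epochs. Widening the mid-encoder to
32 channels, keeping the decoder's 52×60 stage at 32→16, raising the
learning rate, and adding mild weight decay lets channels specialize
into texture detectors (junction and orientation sensitivity), which is
what makes the per-tile feature vectors class-informative rather than
density-coded.

The implementation is NumPy plus numba-compiled stencil kernels
(channels-first layout; forward conv, transposed-conv input gradient,
weight gradient, pool/upsample pairs), each verified against independent
oracles (scipy correlation, einsum contractions) in the test suite.
Max-pool gradients split ties evenly; weights use He/Glorot init from a
seeded generator; training shuffles with a separate seeded stream.
Training is bit-reproducible for a fixed seed on a fixed build (fastmath
compilation fixes the summation order per binary, not across CPU
architectures).

**Features and masks.** Each tile's 16-value feature vector is the spatial
mean of its 16 bottleneck maps, accumulated in float64 so a constant map's
mean is exact. Feature mask *k* marks where map *k* meets or exceeds the
tile's own mean value of that feature — pixels strictly below the
threshold are filtered out, ties are kept. Masks live at bottleneck
resolution (13 × 15); ×8 nearest-neighbour upsampling is for overlay
display only. Thresholding is per tile and per feature, matching a
per-tile reading of the source workflow.

## 4. Embedding and separation scoring

PCA on the (n × 16) feature matrix is mean-centered, with a deterministic
sign convention (largest-magnitude loading positive). The source work
judged class separation visually from scatter plots; as quantitative
stand-ins this package uses (a) the silhouette score of labeled tiles on
any feature subset, and (b) leave-one-out 1-nearest-neighbour accuracy.
These are artifact metrics, not published claims. Features are ranked by
single-feature silhouette (ties broken by ascending index); learned
feature *indices* are not comparable across training runs, so only the
existence of a small discriminative subset is a stable property.

The end-to-end expectation mirrors the study's qualitative result: long
straight fibers versus honeycomb separate well, while the two network
classes are structurally similar and may overlap. Notably, tile-level
fiber *density* alone cannot pass the separation check — the generated
long-fiber and honeycomb tiles overlap heavily in fiber fraction, with a
1-D density silhouette well below 0.2 (the test suite computes this) —
so the check genuinely requires learned texture features, not brightness.

## 5. Hertz-model AFM analysis

For a rigid conical indenter (half-angle α) on an elastic half-space,
F = (2/π)·tan(α)·E/(1−ν²)·δ². Defaults: ν = 0.5 (incompressible soft
tissue/hydrogel convention) and α = 18° (typical for the sharp silicon
conical probes named in the source protocol); both configurable. Curves
are assumed pre-baselined (δ = 0 at contact, force in newtons);
deflection-sensitivity and spring-constant calibration happen upstream on
the instrument. The fit is linear least squares of F on δ² through the
origin; an optional flag co-fits a contact-point offset via
F = c·E·max(δ−δ₀, 0)². All-zero force traces return modulus 0 with a
warning flag; negative fitted moduli raise. Per-sample summaries report
mean ± SD in kPa (SD with ddof = 1, 0 for a single spot; a warning below
7 spots) and a fold-change matrix of means, reported rounded half-up to
one decimal — the convention that reproduces the published "approximately
2.4 / 5.7 / 2.3-fold" figures from the published mean moduli. Published
moduli are inputs to fold computation, not fit-reproduction targets,
since ν, α, and the fitted indentation ranges behind them are unpublished.

## 6. Spheroid morphometry statistics

Aggregate volume uses the caliper formula V = (length × width²)/2, in the
cube of the input unit (units are carried, never converted). Group
comparisons are one-way ANOVA (scipy) with all-pairs Tukey HSD
(statsmodels, Tukey–Kramer for unbalanced designs such as 4–17 cells per
group) at α = 0.05. Degenerate inputs are handled explicitly: identical
constant groups give F = 0, p = 1; zero within-group variance with
unequal means is reported as p = 0 with a flag.

The synthetic morphometry generator draws per-group lognormal volumes
with geometric means control × fold (defaults: the published 1.92 / 2.68 /
2.74 fold effects of E2, IGF-1, and E2+IGF-1 on spheroid size, n = 15 per
group) and coefficient of variation 0.3 — the source reports folds but no
dispersions, so cv = 0.3 is a package assumption typical of such
measurements. At cv = 0 every volume equals its group mean exactly.
Length and width are back-solved from volume with a random aspect ratio
in [1, 1.5]. Under these conditions the global ANOVA and the
control-vs-IGF-1 Tukey comparison are significant in ≥ 95% of seeded
replicates, and the type-I error under the null stays near 0.05.

## 7. Problem sizes and numerical conventions

* End-to-end featurization checks train 25 epochs on 2,000 filtered tiles
  subsampled (seeded) from 48 frames; the acceptance script reruns a
  reduced configuration (6 frames/class, 1,200 tiles, 15 epochs) chosen
  to keep the from-scratch rerun short.
* Monte-Carlo checks use 100–200 replicates for power, 500–1,000 for
  type-I error, and 20–100 seeds for Hertz noise recovery.
* Float32 throughout the network; float64 for feature summaries, PCA,
  statistics. BCE probabilities are clipped at 10⁻⁷.
* Rounding of reported folds: decimal half-up to one decimal place.
* Seeds: every stochastic component takes an explicit integer seed and
  derives independent substreams (`SeedSequence` spawn keys); no global
  RNG state is used.

## 8. Known limitations

* The autoencoder is CPU-sized (tens of thousands of parameters); it
  demonstrates the featurization mechanism, not state-of-the-art
  reconstruction.
* Learned feature indices are permutation-unstable across seeds/builds;
  analyses should treat features as an unordered set.
* The fiber simulator is 2-D and noise-simplified (see section 1); silhouette
  and accuracy numbers on synthetic data do not transfer quantitatively
  to real micrographs.
* Hertz fitting assumes the conical contact law over the full indentation
  range; substrate effects, adhesion, and viscoelasticity are out of
  scope.
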