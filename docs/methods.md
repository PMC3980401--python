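# Methods

`skinmil` annotates histopathology-style images with a set of binary terms
by treating each image as a *bag* of segmented regions and each term as an
independent multi-instance classification problem: an image carries a term
if and only if at least one of its regions exhibits the corresponding
tissue pattern.  This note records the models, the numerical choices, and
the limits of what the synthetic benchmark can show.

## Region bags

**Normalized-Cut segmentation.** An image (rescaled to a working
resolution, 200×150 for full-size slides) becomes a weighted graph: pixels
are vertices and pairs closer than `radius` (default 5 px) are joined with
the Shi–Malik affinity

    w(u,v) = exp(−‖F(u)−F(v)‖² / σ_i²) · exp(−‖X(u)−X(v)‖² / σ_x²),

with colour bandwidth `σ_i = 0.1` (RGB in [0,1]) and spatial bandwidth
`σ_x = 4` px.  The normalized cut of a bipartition (A,B),
`cut/assoc(A) + cut/assoc(B)`, is minimised through the second-smallest
generalized eigenvector of `(D−W)y = λDy`, computed as the second-largest
eigenvector of the normalized affinity `D^{-1/2} W D^{-1/2}` (numerically
far better conditioned), followed by an exhaustive threshold sweep over the
eigenvector.  The sweep is incremental — moving one vertex at a time across
the threshold and updating cut and association in O(deg) — so it is exact
over all distinct eigenvector values at O(|E|) total cost; above 5000
vertices it restricts to 50 quantiles.  Disconnected graphs short-circuit
to a zero-cut component split.

Exactly `p` regions are produced by recursive two-way cuts, always
splitting the segment whose best cut has the lowest value.  Because the
recursion is greedy and deterministic, the partition at a smaller `p` is a
prefix of the one at a larger `p`; `segment_hierarchy` exploits this to
serve several granularities from a single cut sequence.  After the cuts,
segments are split into 4-connected components and the smallest components
are merged into the neighbour with the longest shared boundary until
exactly `p` regions remain.  The eigensolver start vector is fixed, so
segmentation is reproducible bit for bit.

Known limitation: a single eigenvector threshold cannot express every
two-way split, so a high-contrast patch occasionally stays merged with its
surrounding band at one granularity while being isolated at the others;
the majority-vote ensemble over `p ∈ {8, 10, 12}` exists precisely to
absorb such single-granularity artefacts.

**Region descriptors.** Each region is stored as its axis-aligned minimum
covering rectangle with non-region pixels set to exact black and a mask
distinguishing region from padding.  The 9-dimensional descriptor is:

- f1–f3: mean L\*, u\*, v\* (CIE 1976, D65) over region pixels only.
  Padding is excluded outright rather than merely "mostly removed" — the
  padding is an artefact of rectangle storage, not of the tissue.
- f4–f6: the rectangle's luminance channel is tiled into m×m blocks
  (default m = 4); each block undergoes a one-level 2-D Haar transform and
  contributes t_x = (1/4)·Σ(coefficients²) for the LH, HL and HH detail
  bands; f4–f6 average t_LH, t_HL, t_HH over kept blocks.  A block is kept
  only when *all* its pixels belong to the region: a block straddling the
  padding boundary sees an artificial step edge of ~70 L\* units, an
  energy far larger than any real texture, so partially padded blocks are
  noise, not signal.  When full coverage would eliminate every block (very
  thin regions) the filter falls back to keeping any block with at least
  one region pixel, and a region with no usable blocks reports zero
  texture energy.  The keep rule is exposed as `min_coverage`.
- f7–f9: normalized inertia of orders γ = 1, 2, 3 of the pixel set,
  `l(γ) = Σ((x−x̄)²+(y−ȳ)²)^γ / N^{1+γ}`, divided by the same moment of a
  discrete disc of N pixels, so a compact round region scores ≈ 1.  The
  disc is the N lattice points nearest the origin; its moments are cached
  per N.

f1–f3 and f7–f9 are invariant to translation and 90° rotation; under a 90°
rotation f4 and f5 swap and f6 is unchanged (Haar sub-band symmetry).

The alternative descriptor averages the 128-dimensional SIFT vectors
(4×4 spatial bins × 8 orientations) of keypoints detected on the
rectangle's luminance channel, keeping only keypoints on region pixels;
regions smaller than 16 px a side, or with no keypoints, yield a zero
vector with a warning.

## Learners

**Citation-KNN.** Bags are compared with the average Hausdorff distance

    AHD(A,B) = [Σ_a min_b d(a,b) + Σ_b min_a d(b,a)] / (|A|+|B|),

d Euclidean in instance space.  AHD is symmetric and zero on identical
bags but not a metric; nothing downstream assumes the triangle inequality.
Because the nine descriptor dimensions live on incommensurate scales
(L\* spans [0,100], sub-band energies sit near zero), a per-dimension
z-scoring fitted on the training bags can be enabled (`standardize=True`,
recommended and used by the evaluation protocol); the statistics are
stored with the model.

A test bag is voted on by its R nearest training bags (*references*,
default R = 3) and by every training bag that would rank the test bag
among its own C nearest neighbours (*citers*, default C = R + 2).  The
prediction is positive only when positive votes strictly outnumber
negative ones — ties go negative, favouring annotation precision.

To avoid computing AHD to every stored bag at test time, the training set
is clustered by k-medoids (PAM-style, on the precomputed AHD matrix;
medoids must be actual bags since no mean bag exists) and an s×K locality
matrix lists each medoid's K nearest training bags.  At test time only the
s medoid distances are computed; the ⌈q·s⌉ nearest medoids contribute
their rows and the vote runs on the union.  With q = 1 and K = n this is
provably identical to the naive vote.  Defaults: s = ⌈√n⌉, K = min(25, n).
The matrix costs O(n²) AHD evaluations, built once.

**GPMIL.** Each instance x carries a latent f(x) with a zero-mean GP prior
(RBF kernel; lengthscale = median pairwise instance distance, variance 1,
jitter 1e-6) and an instance score g(x) = logistic(f(x)) ∈ (0,1).  The bag
probability is the soft maximum

    s(B) = (1/α)·log[(1/|B|)·Σ_j exp(α·g_j)],  clipped to [0,1],

which tends to max_j g_j as α → ∞; positive bags contribute log s and
negative bags log(1−s) to a Bernoulli likelihood.  The posterior over
latents is approximated by Laplace expansion at the mode.

Numerics of the mode search: the RBF Gram matrix of clustered MIL
instances is ill-conditioned (condition numbers ~1e8 are routine), so the
ascent runs in dual coordinates f = K·a, where the prior penalty is
½·aᵀKa and the Newton direction solves `(I + W K)·δ = ∇L − a` without ever
inverting K.  The line search falls back to the gradient direction when
the Newton step points downhill (the surface is a saddle at the symmetric
start f = 0).  Because the sharp soft-max makes the posterior surface
multimodal, the target α is reached by continuation: the mode at α = 2
warm-starts α = 5, then 10, 20, and the target.  Convergence is declared
when the gradient ∞-norm drops below `tol` (default 1e-5); a fit that
stops early carries `converged=False` and a warning.  The predictive
variance correction uses `B = W(I + K W)^{-1}` — algebraically
`(K + W^{-1})^{-1}` — with symmetrization and a regularized solve, since W
need not be positive under this likelihood.

Prediction: the GP conditional gives each test instance's latent mean and
variance; the instance with the highest mean score is pushed through the
bag soft-max by 32-node Gauss–Hermite quadrature with the remaining
instances held at their posterior-mean scores (full multivariate
quadrature over all instances was rejected on cost; the error of the
one-dimensional scheme against dense quadrature is below 0.01 on toy
problems and is asserted in the tests).  The binary decision is
b = 1 iff r > 0.5.

**Choosing α.** The log-mean-exp soft-max underestimates the true maximum
by up to log|B|/α.  This matters because the decision threshold is fixed
at 0.5: with image bags of |B| ≈ 8–12 regions, α = 10 leaves a bias of
0.21–0.25 on the probability scale — the same order as the decision
margin — and produces fits that rank perfectly yet classify at chance.
The evaluation protocol therefore sizes α so the bias stays well inside
the margin: its default α = 30 gives log(12)/30 ≈ 0.08.  `fit_gpmil`
itself defaults to α = 10, appropriate for small bags.

## Evaluation protocol

Per-term *precision* (zero-one score) is the fraction of test images whose
predicted bit matches the truth; *Hamming loss* is the fraction of wrong
image-term pairs over the whole matrix and equals the mean over terms of
(1 − precision) — an identity asserted in the tests.  Lower Hamming loss
is better; 0 is perfect.  The standard run draws a random 3:7
train:test split, trains one model per term at each p, majority-votes the
per-p binary predictions (an odd number of p values is required), and
averages everything over n_trials splits, each derived from a master seed.
A term whose training split is single-class falls back to predicting that
constant class.  Imbalance experiments resample one term at a chosen
positive ratio r and report FP/negatives and FN/positives.

## The synthetic benchmark

The real annotated-biopsy corpus this kind of system is built for is
hospital data and not distributable, so the package ships a generator that
reproduces the *statistical* structure the method assumes rather than the
appearance of histology:

- Three horizontal bands with distinct base colours stand in for the
  anatomical layering of skin (epidermis / dermis / subcutaneous fat).
- Each annotation term corresponds to a texture motif (oriented stripes,
  checkerboard, blob field — each with its own colour cast and period);
  an image positive for a term contains that motif in at least one local
  patch, so the image-level bit is exactly the OR of its regions' bits.
- Patches occupy a fixed grid of non-overlapping slots (two per band);
  each positive term's motif lands in a uniformly random slot, so *where*
  a term manifests is unknown — the spatial ambiguity that motivates the
  MIL formulation — while patches can never overwrite each other's
  witness (which would silently corrupt the labels).  Unused slots get a
  neutral filler motif tied to no term, mirroring real images in which
  some regions carry no annotation; it also keeps the natural segment
  count (3 bands + 5 patches = 8) aligned with the evaluated
  p range {8, 10, 12}.
- Motif interiors use mild contrast (dark phase = 0.85 × colour): the
  colour-sensitive affinity would otherwise slice a harsh texture into
  separate flat-colour combs, leaving no single region carrying the
  motif's wavelet signature.
- Benchmark conditions: 80 images of 64×48 px, 4 terms at prevalence 0.5,
  12×18 px patches, pixel noise σ = 0.02.  The image size is the smallest
  at which 12-region cuts still resolve bands plus patches, keeping the
  full pipeline fast enough to rerun from scratch in every test session.

What passing tests do and do not show: the benchmark verifies that the
pipeline recovers term–motif associations when the MIL assumption holds
exactly, textures are separable in the descriptor space, and annotation
noise is absent.  Real biopsy images violate all three to varying degrees
(stain variation, terms with diffuse rather than local support, inter-rater
noise), so benchmark precision is an upper bound on, not an estimate of,
clinical performance.

A second generator (`generate_bags`) skips imaging entirely: negative
instances are N(0, I) draws, positive bags replace each instance with
probability `witness_rate` by a draw centred at a vector of norm
`separation` (redrawing the mask until at least one witness exists).  It
supplies exact planted structure for learner-level tests: with separation
6 and witness rate 0.3, both learners exceed 90% test accuracy; with
separation 0 they hover at chance.

## Reproducibility

Every stochastic step (splits, clustering initialisation, generators) is
driven by explicit integer seeds; segmentation and both fits are
deterministic given their inputs.  Serialized bag archives carry the
feature scheme, region count and standardization statistics needed to
reproduce a model's decisions.
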