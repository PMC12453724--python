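# Methods

This note documents the models implemented in `leafseg`, the parameters
that matter, the numerical choices made where the design was genuinely
open, and what the synthetic test conditions do and do not establish.

## Entropy-adaptive equalization (CEAHE)

The enhancer is a contrast-limited adaptive histogram equalizer whose tile
size is a function of the image's global Shannon entropy
`E = -Σ_{x=0}^{255} P_x log2 P_x` (bits; `0·log 0 := 0`). The tile rule

    s(E) = 8 · 2^((E − 8) / 7),  rounded to the nearest even integer,
                                 floored at min_tile (default 2)

is the exponential-decay curve through two anchor points: full-entropy
images (E = 8) get 8×8 tiles, and at E = 1 the tile is halved to 4. The
even rounding keeps tile grids symmetric; monotonicity in E is preserved by
construction. Intuition: the lower the entropy, the flatter the image, and
the smaller the neighbourhood over which equalization must act to amplify
what little structure there is.

Per tile, the histogram is clipped at `clip_limit` × mean bin count
(default 2.0 — "adaptive histogram equalization" without clipping amplifies
sensor noise), the excess redistributed uniformly, and the mapping built
from the cumulative distribution **normalized over the tile's occupied
intensity range** (lowest occupied level → 0, highest → 255). This is the
convention of the field's reference adaptive-equalization implementations;
it guarantees genuine range expansion on low-contrast inputs, while the
clip limit still bounds the mapping's slope within the range. Single-level
tiles map through the identity (no contrast to redistribute; avoids the 0/0
in the CDF normalization), which also makes constant images exact fixed
points of the enhancer. Pixels are remapped by bilinear interpolation
between the four neighbouring tile mappings, with clamping at borders.

## Gravity-kernel density clustering (GWKDC)

**Histogram polynomial.** The 256 points (k, m_k) are fitted with a
polynomial of degree n (default 6) by least squares. The intensity axis is
rescaled to [0, 1] internally; a raw Vandermonde system on 0..255 with
degree 6 spans ~14 orders of magnitude and destroys the fit's conditioning.
Coefficients are reported on the rescaled axis with the scale recorded.
Degree 6 is the smallest degree whose derivative admits three concave
maxima — one per expected mode (background, leaf tissue, lesion) — while
remaining too stiff to chase bin-level noise. Degrees outside [2, 12] are
rejected.

**Peak detection.** The fitted polynomial's derivative is evaluated on a
4096-point grid over [0, 255]; sign changes bracket roots refined by
bisection to |dy/dr| < 1e-9 on the rescaled axis, and roots are kept only
where d²y/dr² < 0. An empty peak set is legal (monotone fits).

**Clustering.** Similarity between a pixel and a center is the gravity
kernel `G = exp(-d_space²/B1) · exp(-ΔI²/B2)` — a product of spatial and
intensity Gaussian kernels, symmetric, in (0, 1], and 1 only for
coincident pixels. Assignment maximizes G (equivalently, minimizes the
kernel-induced distance 1 − G); log-similarities are compared internally so
far pixels never underflow to an uninformative 0.

Each validated peak seeds one center. The seed intensity is the peak
location **snapped to the nearest occupied histogram level**: polynomial
smoothing biases peak locations into intensity ranges where no pixel
actually lives (most visibly on noise-free images whose histogram is a few
isolated spikes), and a center seeded in such a dead zone can lose the
tug-of-war for its own mode. The seed position is the Q_k-weighted centroid
of pixels within ±10 levels of the seed intensity (whole-image weighted
centroid when that window is empty). Assignment and center updates
(spatial centroid, mean intensity) alternate until labels stabilize or 50
iterations pass; clusters that capture no pixels are dropped. When no peak
validates at all, two fallback centers at the 25th/75th intensity
percentiles guarantee a mask is always produced.

After convergence, center pairs closer than `merge_tau_space` × image
diagonal (default 0.05) in space **and** `merge_tau_int` levels (default
10) in mean intensity are merged (union-find), labels are relabeled
contiguously from 0, and the **lesion** is flagged as the cluster whose
mean intensity lies farthest from the global histogram mode — on a leaf
photograph the mode belongs to background or healthy tissue, and diseased
tissue is the outlier.

**Automatic bandwidths.** `segment` defaults to B2 = (0.1 × 255)² on the
intensity axis and B1 = (0.3 × image diagonal)² in space. The spatial scale
is deliberately of the order of the object extent: the spatial kernel
should act as a gentle locality prior, not override a clear intensity
contrast. Quantitatively, a center's spatial advantage overcomes a ΔI
intensity deficit only beyond distances d with d² > (ΔI²/B2)·B1; with a
60-level contrast and B1 at 10% of the diagonal that crossover sits at
~125 px on a 380×380 frame — inside the leaf — so peripheral leaf pixels
near the lesion centroid would be captured by the lesion cluster and its
center would drift (measured: mean lesion IoU drops from 1.0 to 0.79 at
noise σ = 5, with catastrophic single-seed failures). At 30% of the
diagonal the crossover leaves the frame and the spatial term only breaks
ties between intensity-equivalent clusters.

## The TCPSAO optimizer

A population of N particles (positions X_i, personal bests O_i, global
best O) minimizes an objective over a box [lb, ub]. Per iteration h:

* the population is randomly partitioned into an exploration set (size
  N_a) and an exploitation set (N_b), with N_b shrinking linearly from N/2
  to 1 over the run — early exploitation pressure fades as the search
  localizes;
* exploration rows move to `Elite + RB ⊗ (r1·(O_i − X_i) + (1−r1)·(X̄ − X_i))`
  where Elite is drawn uniformly from {global best, second best, third
  best, centroid of the top half by fitness}, RB is an i.i.d.
  standard-normal (Brownian) vector, r1 ~ U[0,1], and X̄ is the population
  mean;
* exploitation rows contract: `M(h)·O_i + RB ⊗ (r2·(O_i − X_i) + (1−r2)·(X̄ − X_i))`,
  r2 ~ U[−1,1], with the melting rate
  `M(h) = (0.35 + 0.25·(e^{h/h_max} − 1)/(e − 1)) · e^{−h/h_max}`
  (0.35 at h = 0, 0.6/e ≈ 0.2207 at h = h_max, positive throughout);
* a particle-swarm velocity is added to the proposal, positions are
  clamped to the bounds, and personal/global bests are updated (the global
  best is therefore non-increasing by construction).

**Velocity form.** The velocity is memoryless and computed at the proposal
it is applied to:

    V(h+1) = χ · [c1·u1 ⊗ (O_i − x(h+1)) + c2·u2 ⊗ (O − x(h+1))],
    χ = 0.729, c1 = c2 = 1.49445, u1, u2 ~ U[0,1]^dim.

A classical inertia-accumulated PSO velocity is a second-order oscillator
whose stability relies on the position integrating the velocity; here the
base position is regenerated by the ablation dynamics every iteration, so
an accumulated velocity degenerates into a random walk amplified by
1/(1 − w) and destroys convergence (measured on the 10-dimensional sphere:
median final fitness 7.3 with accumulation vs 1.6e-12 without, N = 30,
h_max = 200, 20 seeds; with accumulation the hybrid was also beaten by pure
random search on Rastrigin). The memoryless constriction form keeps the
cognitive/social pulls of PSO while respecting the resampling structure.

**Initialization.** The start population is uniform in the box, passed once
through the tent map `F(x) = x/α` for x < α else `(1−x)/(1−α)` (α = 0.5)
on the unit-normalized coordinates, then mapped affinely back into
[lb, ub] — so bounds with negative or nonzero lower limits are respected.
The tent map's invariant density at α = 0.5 is uniform; the chained-orbit
helper `tent_iterates` exists for verifying this empirically. One numerical
caveat: in double precision the α = 0.5 orbit loses one mantissa bit per
step and collapses onto the fixed point 0 after ~50 iterations (the map is
conjugate to a binary shift); the iterator therefore reseeds the orbit from
the RNG whenever it degenerates to an endpoint. A Kolmogorov–Smirnov check
on 10,000 iterates gives D ≈ 0.014 against the uniform distribution.

**Variants.** `sao` drops the tent pass and the velocity term; `pso` is a
canonical constriction particle swarm. One caveat when reading benchmark
comparisons: the melting contraction `M·O_i` pulls exploitation rows toward
a scaled-down personal best, which is systematically helpful on test
functions whose optimum sits at the origin (sphere, Rastrigin) — the `sao`
variant's striking results on those functions partly reflect this
origin bias, not pure search power.

All randomness flows from one seeded generator per `optimize` call: fixed
seed ⇒ bit-identical trajectories.

## Mask metrics

With TP/FP/FN pixel counts between binary masks: IoU = TP/(TP+FP+FN),
Dice = 2TP/(2TP+FP+FN), precision = TP/(TP+FP), recall = TP/(TP+FN). Two
empty masks score 1 on every metric (a correctly predicted lesion-free leaf
is a perfect prediction); any other 0/0 ratio scores 0. Dice and IoU obey
Dice = 2·IoU/(1 + IoU) exactly. Multi-label masks are scored one-vs-rest
per label and macro-averaged.

## Synthetic leaf generator

`make_leaf` renders a bright background (level 220), a centered elliptical
leaf (semi-axes 0.40/0.27 of the side, level 120) and n non-overlapping
elliptical lesions (default 3, semi-axes drawn from side/32..side/13,
level 60, clipped to the leaf raster), then applies Gaussian noise (σ in
intensity levels; the σ = 0.01 of normalized-scale camera-noise studies
corresponds to 2.55 levels), an optional k-tap Gaussian blur (σ_kernel =
(k−1)/4) and a brightness factor (0.6 emulates a 40% light reduction). The
returned mask reflects the exact noise-free geometry; a fixed seed
reproduces everything bit for bit. Default working resolution is 380×380,
the pipeline's standard frame.

What the generator does **not** emulate: leaf texture and venation, colour,
specular highlights, shadows, curled or occluded leaves, multiple leaves
per frame, and lesions with diffuse (non-step) boundaries. Tests passing on
these fixtures therefore establish the internal correctness and noise
robustness of the algorithms — exact mode recovery, monotone degradation
with noise — not field performance on photographs.

## Problem sizes and tolerances in the test suite

The accuracy studies run at the standard 380×380 frame: 20 seeds at noise
σ = 5 for the headline lesion-IoU check (mean ≥ 0.85) and 10 seeds per
noise level σ ∈ {0, 5, 10, 20} for the monotone-degradation check. The
optimizer studies use dim 10, N = 30, h_max = 200, 20 seeds, against
uniform random search at the same evaluation budget. Entropy and metric
identities are asserted to 1e-12; peak locations to 0.1 intensity level;
melting-rate anchors to 1e-12. At σ = 20 the lesion/leaf intensity gap is
3σ and pixel-level misassignment becomes unavoidable by any
intensity-driven method; accuracy drops steeply there, which the monotone
check records deliberately.

## Known limitations

* Segmentation is single-channel; colour information is discarded by the
  BT.601 conversion.
* One spatial center per intensity mode: strongly disconnected lesion
  fields are represented by a single centroid, which the wide spatial
  bandwidth tolerates but does not model.
* The histogram polynomial resolves at most three modes at degree 6;
  images with more than three distinct intensity populations need a higher
  degree (supported up to 12).
* The optimizer handles box bounds only (hard clamping); no general
  constraints, no parallel objective evaluation.
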