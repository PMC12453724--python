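# leafseg

Classical (non-learned) image analysis for plant-lesion photographs, built
around three cooperating pieces:

1. **CEAHE** — contrast-enhanced adaptive histogram equalization whose tile
   size is chosen from the image's global Shannon entropy
   `E = -Σ P_x log2 P_x`: information-rich images are equalized over 8×8
   tiles, low-entropy (dim, flat) images over smaller tiles via the
   exponential-decay rule `s(E) = 8·2^((E-8)/7)` (so `s(8) = 8`,
   `s(1) = 4`), with standard clip-limited histograms and bilinear blending
   between tile mappings.
2. **GWKDC** — gravity-weighted kernelized density clustering. A degree-n
   polynomial is least-squares fitted to the 256-bin intensity histogram;
   its concave critical points (`dy/dr = 0`, `d²y/dr² < 0`) seed one
   cluster per histogram mode; every pixel is then assigned to the center
   maximizing the gravity kernel similarity
   `G = exp(-d_space²/B1)·exp(-ΔI²/B2)`, with centroid/mean updates until
   convergence, near-duplicate cluster merging, and lesion flagging (the
   cluster whose mean intensity lies farthest from the histogram mode).
3. **TCPSAO** — a bound-constrained population minimizer hybridizing
   snow-ablation dynamics (elite-guided Brownian exploration plus
   melting-rate contraction `M(h) = (0.35 + 0.25·(e^{h/h_max}-1)/(e-1))·e^{-h/h_max}`)
   with tent-chaotic-map initialization and a constriction-form PSO
   velocity term; `sao` and `pso` ablation variants are included for
   comparison studies.

Alongside these: mask overlap metrics (IoU, Dice, precision, recall) and a
seeded synthetic leaf-image generator that renders background / leaf /
lesion regions with exact per-pixel ground truth plus Gaussian noise, blur
and brightness perturbations — so every component is testable at desk scale
without any photographic dataset.

**Who it is for:** plant-pathology image-analysis work that needs a
lightweight, fully reproducible lesion segmenter and optimizer baseline, or
a reference implementation of the entropy-adaptive CLAHE / kernel-gravity
clustering / chaotic swarm-hybrid family of methods.

## Worked example

```bash
python examples/segment_leaf.py
```

prints (exact numbers, fixed seed):

```
histogram polynomial : degree 6, residual SSE 3.62e+08
validated peaks (r)  : [ 14.9 111.1 228.2]
  (three modes ~ lesion, leaf tissue and background intensities)
clusters found       : 3
cluster centers (row, col, mean intensity):
  (162.2, 153.4, 60.1)
  (192.3, 193.1, 120.0)
  (189.5, 189.5, 220.0)
lesion label         : 0 (farthest mean from histogram mode)
lesion IoU           : 1.000   Dice: 1.000
```

The polynomial smooths the spiky histogram, so the detected peak locations
are biased (14.9 / 111.1 / 228.2 for true modes at 60 / 120 / 220) — the
iterative kernel-clustering refinement then pulls the cluster mean
intensities onto the true modes (60.1 / 120.0 / 220.0) and recovers the
lesion pixels exactly (IoU = 1.0 against the generator's ground truth).

Other examples: `enhance_contrast.py` (entropy → tile size → contrast
gain), `optimize_benchmarks.py` (TCPSAO vs SAO vs PSO on sphere and
Rastrigin), `evaluate_masks.py` (metric identities), `generate_fixtures.py`
(perturbed fixture sets).

There is also a thin CLI:

```bash
leafseg synth --out fixtures --n 5 --sigma 5
leafseg run --in fixtures/img_0000.png --out results --truth fixtures/mask_0000.png
leafseg optimize-demo --objective rastrigin --variant tcpsao --out history.csv
```

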