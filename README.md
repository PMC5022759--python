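# gaseg

Brain-MRI tissue segmentation by seeded region growing, with the seed
points chosen automatically by a genetic algorithm.

Region growing segments an image by expanding from initial seed pixels
("grains"), accepting each frontier neighbor whose intensity is close
enough to the region accumulated so far. It is simple and effective on
high-contrast tissue like T1-weighted brain MR — but its output depends
strongly on *where* the seeds are planted, and manual seed picking is
slow and irreproducible. `gaseg` turns seed selection into an
optimization problem: when a reference segmentation is available (as it
is for simulated-MRI databases that ship exact tissue maps), a genetic
algorithm searches for the seed set whose grown segmentation best
matches the reference. The package targets the three standard brain
tissue classes — gray matter (GM), white matter (WM) and cerebrospinal
fluid (CSF) — plus background.

## Method

**Growing.** A region starts from one seed pixel with mean
μ₁ = I(seed) and standard deviation σ₁ = 0. The frontier is explored
breadth-first over a configurable neighborhood (4, diagonal-4 or
8 neighbors); a candidate pixel *p* joins the region iff

    |I_p − μ_N| ≤ max(k_σ · σ_N, t_min)

where μ_N, σ_N are the running mean and standard deviation of the N
pixels accepted so far, updated incrementally on every acceptance
(Welford's recurrence: μ_N = ((N−1)μ_{N−1} + I_N)/N with a numerically
stable variance update). The floor tolerance `t_min` keeps the band
open during the cold start while σ is still zero. Growth stops when the
frontier empties; classes are grown one after another, each restricted
to pixels not yet claimed.

**Seed search.** Candidate seeds per class come from simple intensity
thresholding (one disjoint window per class). A GA chromosome is one
(row, col) seed per class; fitness of a chromosome is the cost

    Cost = Σ_c Σ_pixels (pred_c − ref_c)²    over c ∈ {GM, WM, CSF}

of the segmentation grown from it, i.e. the total per-class binary
mismatch count against the reference (0 iff exact). Tournament
selection, per-class uniform crossover, candidate-constrained mutation
and elitism evolve the population; elitism makes the best cost
non-increasing, and runs are bit-reproducible given a seed.

**Evaluation.** RMS error `sqrt(Σ(P_i−G_i)²/N)` over per-class binary
maps (averaged across classes) plus per-class Dice overlap.

**Phantoms.** A built-in generator renders simulated slices with exact
ground truth: nested ellipses (CSF ring ⊃ GM ring ⊃ WM core, T1-like
default means 60/120/200 over background 0) or Voronoi blobs, with
Gaussian noise and an optional smooth multiplicative bias field.

## Worked example

```python
from gaseg import (GAConfig, GrowConfig, PhantomSpec, candidate_seeds,
                   evaluate, ga_optimize, generate_phantom, naive_seeds,
                   segment, windows_from_reference)

spec = PhantomSpec(shape=(64, 64), noise_sigma=10.0, rng_seed=2)
image, ref = generate_phantom(spec)

grow = GrowConfig(neighborhood="eight", k_sigma=2.5, t_min=10.0)
windows = windows_from_reference(image, ref)

manual = naive_seeds(image, windows, class_order=grow.class_order)
manual_report = evaluate(segment(image, manual, grow), ref)
print(f"manual seeds {manual.coords_by_class()}: RMS {manual_report.rms:.4f}")

ga = GAConfig(population_size=12, generations=15, stall_generations=5, rng_seed=2)
best, history = ga_optimize(image, ref, candidate_seeds(image, windows), grow, ga)
report = evaluate(segment(image, best, grow), ref)
print(f"GA seeds     {best.coords_by_class()}: RMS {report.rms:.4f}")
```

prints

```
manual seeds {1: (3, 28), 2: (7, 24), 3: (18, 28)}: RMS 0.3465
GA seeds     {1: (39, 55), 2: (44, 25), 3: (28, 20)}: RMS 0.0692
```

The naive "manual" pick (the first thresholded pixel per class, a
boundary pixel) grows poorly on a noisy phantom; the GA finds interior
seeds whose grown segmentation cuts the RMS error by ~5× (per-class
Dice ≈ 0.98–0.99). The GA's best cost per generation fell
87 → 68 → 65 → 59 before the stall criterion stopped the run. Classes
are labeled CSF = 1, GM = 2, WM = 3.

Note the supervised framing: GA seeding needs a reference and is a
calibration mode. Seeds found on a reference-bearing image can then be
applied to sibling images (same subject/protocol) via `gaseg segment`.

## Command line

```sh
gaseg simulate --out-dir phantom --shape 64 64 --noise-sigma 10 --seed 1
gaseg optimize --image phantom/image.png \
    --ref-gm phantom/mask_gm.png --ref-wm phantom/mask_wm.png \
    --ref-csf phantom/mask_csf.png --out-dir opt --seed 1
gaseg compare  --image phantom/image.png \
    --ref-gm phantom/mask_gm.png --ref-wm phantom/mask_wm.png \
    --ref-csf phantom/mask_csf.png --out-dir cmp --seed 1
```

`simulate | segment | optimize | evaluate | compare` read/write
grayscale PNG or NIfTI-1, honor `--seed` for byte-identical reruns, and
write a provenance JSON beside their outputs. Exit codes: 0 OK, 1 data
error, 2 configuration error.

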