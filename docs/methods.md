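# Methods

## Region growing

A region is the connected set of pixels accepted from a seed under the
running-statistics criterion |I_p − μ_N| ≤ max(k_σ·σ_N, t_min). Design
choices that the bare criterion leaves open, and how this package fixes
them:

* **Incremental statistics.** Mean and variance are updated by
  Welford's recurrence (μ_N = μ_{N−1} + (I_N − μ_{N−1})/N;
  M2_N = M2_{N−1} + (I_N − μ_{N−1})(I_N − μ_N), σ² = M2/N). The
  population convention (divide by N) is used because the region *is*
  the population of accepted pixels, and it honors the σ₁ = 0
  initialization at the seed. An alternative "printed" dispersion
  recurrence V_N = ((N−2)V_{N−1} + I_N)/N is retained behind
  `update_stats(..., scheme="printed")` for comparison only: it mixes
  intensity and intensity² units, does not converge to a variance, and
  is never used by the grower.
* **Live vs frozen statistics.** The grower evaluates the acceptance
  band against the *live* statistics, as incremental updating implies.
  `frozen_stats=True` instead freezes the band at the seed statistics
  (μ = I_seed, σ = 0, so the band is just ± t_min), which makes the
  region exactly the flood fill of |I − I_seed| ≤ t_min — a closed-form
  oracle that the test suite checks against an independent
  connected-component labeling.
* **Frontier discipline.** FIFO queue (breadth first); a pixel's
  neighbors are enqueued in row-major offset order, and a pixel is
  enqueued at most once per region. A pixel rejected once is not
  revisited for that region: with live statistics a later retry could
  succeed, but re-enqueueing makes termination and determinism harder
  to guarantee, and the sequential multi-class pass below gives
  rejected pixels a second chance under their own class anyway.
* **Multi-class growth.** Classes grow sequentially in
  `class_order`; each class only sees still-unassigned pixels, so
  assignment is first-come with no re-assignment pass. Contested pixels
  therefore belong to the class grown first — deterministic and
  documented, and exercised by a two-plateau toy test where swapping
  the order flips ownership. A seed swallowed by an earlier class
  yields an empty region rather than an error, so a seed-search
  iteration cannot crash mid-run; the resulting huge cost removes such
  chromosomes from the gene pool naturally.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `neighborhood` | eight | – | frontier connectivity (4, diagonal-4, 8) |
| `k_sigma` | 2.5 | – | acceptance band width in region standard deviations |
| `t_min` | 10 | intensity (0–255 scale) | floor tolerance; breaks the σ=0 cold start |
| `class_order` | (1, 2, 3) = CSF, GM, WM | – | sequential growth order |

`k_sigma` = 2.5 accepts ≈ 98.8 % of in-class pixels once σ has
converged on Gaussian-noise data; `t_min` = 10 equals the default noise
σ, well below the ≥ 60 inter-class contrast, so the band cannot bridge
classes. Both are exposed in `GrowConfig` and on the CLI.

## Seed selection by genetic algorithm

Chromosome: one (row, col) per class, drawn from per-class candidate
masks produced by intensity thresholding with pairwise-disjoint
windows. Because the windows are disjoint, the masks are pixel-disjoint
and chromosomes are distinct-by-construction — no repair operator is
needed. Fitness is the total per-class binary mismatch count of the
grown segmentation against the reference (squared differences of 0/1
maps are mismatches; whether one writes Σ(pred−ref)² per pixel or per
class map is therefore the same number). Operators:

* tournament selection, size 3, entrants drawn uniformly **with
  replacement**, ties to the lower population index;
* per-class uniform crossover (each class's gene swapped between the
  two children with probability 0.5), applied with probability 0.9;
* mutation: each gene independently resampled uniformly from its
  class's candidate mask with probability 0.1;
* elitism: the best 2 individuals copied unchanged, which makes the
  best-cost history non-increasing (asserted at run time every
  generation);
* termination: generation budget (50), stall patience (10 generations
  without improvement), or cost 0 (the global lower bound — nothing
  better exists, so the run stops immediately).

Defaults (population 30) are engineering choices; batch experiments in
`gaseg.experiments` use population 12 / 15 generations / stall 5, which
converges on 64×64 phantoms in well under a second per replicate while
leaving the comparison's outcome unchanged. Fitness values are memoized
per chromosome within a run, so elites are not re-segmented each
generation.

GA seeding is supervised: it needs a reference segmentation
(simulated-MRI databases provide exact tissue maps). The intended use
of the optimum is transfer — segmenting sibling images with the seeds
(or seed neighborhoods) found on the reference-bearing image.

## Evaluation

RMS error sqrt(Σ_i (P_i − G_i)²/N) over all N pixels. The headline
score binarizes each class map and averages the three per-class RMS
values; on 0/1 maps RMS²·N is the Hamming distance, giving the
dimensionless sub-1 magnitudes one expects from mismatch fractions. The
RMS over the raw integer label maps is reported alongside, as is
per-class Dice (2|A∩B|/(|A|+|B|), defined as 1 for two empty masks).

## Synthetic phantoms

The generator emulates simulated-MRI ground-truth databases:
piecewise-constant tissue intensities (defaults 0/60/120/200 for
background/CSF/GM/WM, the T1-weighted ordering), i.i.d. additive
Gaussian noise, and an optional multiplicative bias field (a
second-order polynomial surface rescaled to exactly 1 ± amplitude,
modeling MRI coil non-uniformity). Geometries: nested ellipses with
fixed semi-axis fractions (analytically checkable; CSF ring outside GM
ring outside WM core, mimicking cortical topology) and per-class
Voronoi blobs for irregular shapes. Identical spec + seed reproduce the
phantom bit for bit.

What the phantom does **not** emulate: partial-volume voxels, Rician
noise statistics, anatomical shape variability, 3-D continuity across
slices, or pulse-sequence contrast physics. Results on phantoms
therefore demonstrate algorithmic correctness (exact recovery in the
noise-free limit, graceful degradation under Gaussian noise, the
manual-vs-automatic seeding ordering) — not clinical performance on
real MR volumes.

## Numerical and degenerate-input choices

* Intensities are float64 throughout; label maps int32 (int16 in
  NIfTI, raw uint8 values in PNG) and never rescaled floats, keeping
  cost/RMS arithmetic exact after round trips.
* k_σ = 0 and t_min = 0 degenerate to an exact-match grower (accept
  only I = μ); a uniform image under any positive tolerance fills its
  whole eligible connected component.
* Candidate windows are closed intervals; window construction at class
  mean midpoints nudges the lower edge by 1e-9 so adjacent windows
  stay disjoint.
* All randomness flows through `numpy.random.default_rng` with
  explicit seeds; batch experiments derive per-replicate sub-seeds
  (< 2³¹) from one base seed.

## Experiment problem sizes

The paired manual-vs-GA comparison uses 20 replicates of 64×64
phantoms at noise σ = 10 with the small GA settings above; the
noise-free recovery protocol uses a 128×128 phantom. These sizes give
stable medians (manual ≈ 0.16–0.22, GA ≈ 0.07 across base seeds) at a
few hundred milliseconds per replicate.

## Known limitations

* One rejection is final within a region's growth; heavily textured
  regions can end up with pinholes that a re-visit policy would fill.
* Sequential class growth is order-dependent on ambiguous boundaries;
  the order is a documented parameter, not an inferred quantity.
* The GA optimizes seed *positions* only; k_σ and t_min are not part
  of the chromosome.
* 3-D volumes are processed slice-wise (2-D neighborhoods); volumetric
  6/18/26-neighborhoods are not implemented.
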