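# Methods

## Problem and model

`pixelattack` studies the robustness of image classifiers — in particular
medical-imaging classifiers (dermatoscopy, chest radiography, OCT) — against
sparse, L0-bounded adversarial perturbations. Given an image
`x` and a classifier `f` exposed only through its confidence outputs
(black-box, query access), the attack searches for a perturbation `e(x)`
with `‖e(x)‖₀ ≤ L` (at most `L` pixels changed, `L = 1` for the classic
one-pixel attack) such that the predicted label of `x + e(x)` differs from
the clean prediction (untargeted) or equals a chosen target (targeted).

The discrete search space is enormous — `H·W·V^C` candidates for one pixel
(≈ 8.4 × 10¹¹ for a 224×224 RGB image at 8-bit depth) — so the search is
performed by differential evolution (DE) over a real-valued relaxation of
the candidate encoding.

## Candidate encoding and quantization

A candidate ("gene") is a flat real vector of `L` pixel edits, each
`(X, Y, I)` for greyscale or `(X, Y, R, G, B)` for colour, `X` indexing
columns and `Y` rows, 0-based. Evolution operates on unconstrained reals;
every evaluation projects the gene onto the image grid by rounding
half-away-from-zero and clipping coordinates to `[0, dim−1]` and intensities
to `[0, 255]`. Keeping the genome continuous and quantizing only at
evaluation is standard DE practice and makes the difference-vector mutation
meaningful. Duplicate coordinates within one gene are legal; the later edit
wins, which keeps application deterministic and order-stable.

## Fitness

* **Multiclass.** The fitness is a single coordinate of the confidence
  vector: the clean-prediction class (minimized, untargeted) or the target
  class (maximized, targeted).
* **Multi-label.** All classes must be scored at once, so the fitness is the
  cosine similarity between a reference binary label vector and the model's
  confidence vector, `dot(a, b) / max(‖a‖·‖b‖, δ)`, with both operands
  first rescaled element-wise from `[0, 1]` to `[−1, 1]`. The rescaling is
  essential: the empty ("Normal", no-disease) label would otherwise be the
  zero vector and the similarity identically zero. After rescaling it is the
  all-(−1) vector with positive norm, so minimizing similarity against the
  original label remains informative. `δ = 10⁻⁵` guards the denominator for
  the remaining degenerate case (a confidence vector of exactly all 0.5
  rescales to zero; the numerator is then also zero and the fitness is 0).
  The guard is applied to the product of the rescaled norms, not to each
  norm separately.
* Multi-label membership uses a strict threshold `cl_i > γ` with `γ = 0.5`;
  the boundary value counts as "absent", and the all-zero result is the
  Normal label.

The untargeted reference is always the model's **clean prediction**, not the
dataset ground truth: the attack minimizes what the model believes.
Campaign runs exclude images the clean model already misclassifies (reported
separately), since "changing the label" would be ill-defined for them.

## Differential evolution

DE/rand/1 without crossover:

* **Initial population** — `population_size = 100` genes drawn uniformly
  over the relaxed box (coordinates in `[0, dim−1]`, intensities in
  `[0, 255]`).
* **Mutation** — per slot, `offspring = g[r1] + F·(g[r2] − g[r3])` with
  mutant factor `F = 0.5` and `r1, r2, r3` mutually distinct donor indices
  (they may coincide with the slot's own index; distinctness avoids
  degenerate zero-difference donors). Offspring may leave the box;
  quantization clips them at evaluation.
* **Selection** — pairwise parent/offspring survival: the child replaces its
  parent only on strict fitness improvement (tie tolerance 0); ties preserve
  the parent.
* **Termination** — after `max_iterations = 100` generations, or early once
  the surviving population holds at least
  `max(1, ceil(early_stop_fraction · population_size))` members whose
  quantized, applied image satisfies the success predicate. With the default
  1% fraction and population 100 this threshold is exactly one adversarial
  image, reconciling the "stop at the first flipped image" and the
  "surpassed 1% of the population" formulations of the stopping rule.

Parent fitnesses are cached, so each generation costs `population_size`
adapter queries, all batched in one call. Pairwise elitism makes the
best-so-far fitness monotone in the optimization direction, which the tests
assert on every seeded run. All randomness flows from a single
`numpy.random.Generator` seeded from the attack configuration, making whole
campaigns bit-reproducible; campaign experiments use derived seeds
(master seed + experiment ordinal) so they are independent yet replayable.

## Evaluation statistics

For a campaign with `K` origin classes and transformation counts
`n[ori, adv]` (diagonal zero by definition — staying put is a failure):

* **success rate** = successes / trials, per origin class;
* **row ratios** `r[ori, adv] = n[ori, adv] / Σ_adv n[ori, adv]` (all-zero
  rows are flagged as failed classes and contribute nothing);
* **per-class transformation ratio**
  `T[adv] = Σ_ori r[ori, adv] / (K − F)`, with `F` the number of origin
  classes whose attacks all failed. Without the correction each dead row
  would still inflate the denominator and the `T` values would no longer
  sum to 1; with it, `Σ T[adv] = 1` holds exactly, which the suite verifies
  in rational arithmetic (`fractions.Fraction`) on random matrices and on
  the bundled reference table;
* **conversion summary** — transitions between the clinical Normal/Disease
  class types; percentages are taken over the cross-type total only
  (Disease→Normal + Normal→Disease), with same-type transitions counted but
  excluded from the base;
* **average confidence** — the mean target-class confidence over successful
  adversarial images.

Multi-label campaigns key transformation-matrix rows/columns by the full
label set rendered as a sorted, comma-joined class-name string, with the
empty set rendered as "Normal"; the disease-type map then derives
automatically (empty set → Normal, anything else → Disease).

Two published reference tables (a seven-class dermatoscopy campaign and a
five-origin multi-label chest campaign) are bundled in
`pixelattack.reference_tables` as fixed inputs: feeding them through the
pipeline reproduces their published ratio and conversion tables to the
printed two decimals, which is the package's strongest end-to-end check and
what `scripts/acceptance.py` recomputes.

## Exhaustive oracle

`exhaustive_one_pixel_oracle` enumerates every discrete one-pixel candidate
(in lexicographic `(y, x, value)` order, ties keeping the earliest) and is
the independent ground truth for the DE search. A `levels` parameter shrinks
the intensity grid to `levels` evenly spaced values including both
endpoints, so tests can run the full enumeration on 3×3 / 8-level instances
(72 candidates). A budget cap (default 10⁶ candidates) rejects full-scale
inputs, reporting the candidate count. The equivalence suite runs DE with
the production budget (population 100 × 100 generations, no early stop) on
toy models whose fitness landscape is a step or monotone function of the
edited pixel — for those families the 8-level optimum equals the 256-level
optimum, so DE can tie the oracle but never beat it; measured attainment is
40/40 seeded trials.

## Synthetic fixtures

The fixture module stands in for trained CNNs and clinical data so the whole
package runs offline and deterministically:

* **images** — flat and gradient calibration patterns; a single-blob pattern
  whose super-threshold set is exactly one connected disc by construction
  (bounded noise, truncated bump tail); an `xray_like` greyscale field
  (low-frequency modes plus a bright central ellipse); and a `lesion_like`
  colour disc on a skin-toned background. Side length is a free parameter;
  tests use 3–32 px, production images are conventionally 224.
* **toy classifiers** — pure functions of the pixels implementing the
  adapter contract (batch of images → per-class confidences): `constant`
  (unattackable), `linear_multiclass` (softmax of per-class linear scores of
  the mean intensity; monotone per-pixel), `fragile_pixel` (class decided by
  whether a watched pixel — or any pixel — exceeds a threshold, default
  200; one-pixel-attackable by construction whenever the threshold is below
  255), and `multilabel_sigmoid` (per-vertical-band logistic confidences
  that do not sum to 1).

These fixtures deliberately lack everything that makes real medical models
hard: no texture statistics, no learned invariances, no calibration error,
no inter-class similarity structure. Passing tests therefore demonstrate the
correctness of the search, scoring and bookkeeping machinery — not that any
particular clinical model is vulnerable; attacking a real model requires
wrapping it in the adapter contract (any callable from an image batch to
confidences, e.g. a thin closure over a torch or sklearn model) and is
intentionally outside the test surface.

## Numerical choices and edge cases

* Rounding is half-away-from-zero; out-of-range values clip (never wrap).
* Multiclass argmax ties break to the lowest class index.
* `max_iterations = 0` is legal and returns the evaluated initial
  population's best.
* A targeted attack whose target equals the clean prediction is rejected as
  a no-op.
* Ratio tables are computed exactly and rendered at two decimals; JSON
  output is key-sorted so identical runs are byte-identical on disk.
* File input is decoded with Pillow; resizing uses bilinear interpolation
  (recorded in results metadata), RGB→grey uses the standard luma weights,
  grey→RGB replicates. An optional 20% center-crop preprocessing flag is
  available for datasets with burnt-in annotations near the borders.

## Known limitations

* The multi-pixel (`L > 1`) search is supported by the genome, engine and
  oracle accounting, but the exhaustive oracle enumerates one-pixel edits
  only; multi-pixel optima are not independently verifiable at desk scale.
* Early stopping counts successes among the *surviving* population; an
  offspring that flips the label but is rejected by pairwise selection in
  the same generation does not trigger the stop. In practice a label flip
  and a fitness improvement coincide for the fitness functions used here.
* No defense mechanisms (adversarial training, input preprocessing,
  ensembling) and no victim-model training are included.
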