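# pixelattack

Black-box **k-pixel adversarial attacks** on image classifiers via
differential evolution, with a cosine-similarity fitness for multi-label
tasks and the full attack-evaluation statistics suite. The package is aimed
at researchers probing the robustness of (medical) image classifiers —
dermatoscopy, chest radiography, OCT — where a single corrupted pixel can
flip a computer-aided diagnosis.

## The attack

Given an image `x` and a classifier `f` queried only for its per-class
confidences, the attack searches for a perturbation `e(x)` with
`‖e(x)‖₀ ≤ L` (at most `L` pixels changed; `L = 1` is the one-pixel attack)
that changes the predicted label (untargeted) or forces a chosen label
(targeted):

```
max_{e(x)}  f_adv(x + e(x))    subject to  ‖e(x)‖₀ ≤ L
```

Exhausting the discrete space is hopeless at production scale
(`224·224·256³ ≈ 8.4 × 10¹¹` candidates for one RGB pixel), so candidates —
encoded as `(X, Y, I)` or `(X, Y, R, G, B)` tuples — are evolved with
DE/rand/1: a population of 100 genes, mutation
`g[r1] + F·(g[r2] − g[r3])` with `F = 0.5`, no crossover, pairwise
parent/offspring survival, and early stop once 1% of the population crosses
the decision boundary (at most 100 generations).

For multiclass models the fitness is the confidence of the original class
(minimized) or the target class (maximized). For **multi-label** models —
where an image may carry several findings at once and the empty label set
means "Normal" — the fitness is the cosine similarity between label and
confidence vectors, both rescaled from `[0, 1]` to `[−1, 1]` so the Normal
label keeps a nonzero norm, with a `δ = 10⁻⁵` guard on the denominator.

Campaign statistics include the per-class success rate, the transformation
matrix `n[ori, adv]`, the failure-corrected per-class transformation ratio
`T[adv] = Σ_ori r[ori, adv] / (K − F)` (which sums to exactly 1), the
Normal↔Disease conversion summary, and the mean target-class confidence of
successful attacks. An exhaustive-search oracle provides ground truth on
tiny instances, and synthetic images plus deterministic toy classifiers
make everything runnable offline.

## Worked example

Attack a "fragile" toy classifier that flips its prediction whenever any
pixel exceeds intensity 200:

```python
import numpy as np
from pixelattack import AttackConfig, make_synthetic_image, make_toy_classifier, run_attack

model = make_toy_classifier("fragile_pixel", 2, threshold=200)
image = make_synthetic_image(32, 32, 1, "uniform", value=60)
result = run_attack(image, model, AttackConfig(pixels=1, seed=7))
print("success:", result.success)
print("clean prediction:", result.original_prediction, "-> label", result.original_label)
print("adversarial prediction:", result.adversarial_prediction, "-> label", result.adversarial_label)
print("edited pixel (x, y, intensity):", result.gene.edits[0].astype(int))
print("generations used:", result.iterations_used)
```

prints

```
success: True
clean prediction: [0.9 0.1] -> label 0
adversarial prediction: [0.1 0.9] -> label 1
edited pixel (x, y, intensity): [  7   9 223]
generations used: 0
```

i.e. writing intensity 223 at pixel (7, 9) already flips the model from
class 0 (confidence 0.9) to class 1; the random initial population alone
contained a winning gene, so zero DE generations were needed. Real models
plug in the same way: any callable mapping an image batch `(N, H, W, C)` to
confidences `(N, K)` is a valid adapter.

The same machinery is available from the shell:

```
$ pixelattack metrics --builtin dermatoscopy
Transformation ratio:
  Benign Keratosis: 21.25%
  Melanocytic Nevi: 37.52%
  Dermatofibroma: 3.53%
  Melanoma: 5.17%
  Vascular Skin Lesions: 0.00%
  Basal Cell Carcinoma: 27.57%
  Actinic Keratoses: 4.96%
Class conversion:
  Disease to Normal: 61 (42.36%)
  Normal to Disease: 83 (57.64%)
```

This recomputes, from the bundled seven-class dermatoscopy
transformation-count table, how strongly each lesion class attracts
adversarial transformations (benign "Melanocytic Nevi" absorbs 37.5% of
them) and how often attacks convert diseased findings to normal-looking
ones and vice versa. `pixelattack attack`, `pixelattack campaign` and
`pixelattack oracle` run single attacks, multi-image campaigns on synthetic
fixtures, and exhaustive searches on tiny inputs; see `--help` on each.

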