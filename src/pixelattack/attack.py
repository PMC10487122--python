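"""Attack orchestration: single attacks, campaigns, transformation counts.

An attack is a success when the predicted label of the perturbed image
differs from the clean prediction (untargeted) or equals the requested target
exactly (targeted).  For multi-label tasks "differs" means any class added or
removed — drifting from {Effusion} to {Effusion, Infiltration} counts.

Campaigns run many attacks per origin class and accumulate a transformation
matrix of counts ``n[ori, adv]``: how many successful attacks carried an
image from origin class *ori* to adversarial class *adv*.  Staying put is by
definition a failure, so the matrix diagonal is zero.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .core import AttackConfig, AttackResult, quantize_gene, validate_image
from .de import evolve
from .fitness import FitnessSpec, labels_from_confidence
from .metrics import TransformationMatrix

__all__ = [
    "predict_label",
    "is_success",
    "label_set_name",
    "run_attack",
    "attack_campaign",
    "CampaignRecord",
    "CampaignResult",
]

NORMAL_NAME = "Normal"


def predict_label(
    confidences: np.ndarray, task: str, gamma: float = 0.5
) -> int | np.ndarray:
    """Decode a confidence vector into a label.

    Multiclass: argmax, ties broken by the lowest index.  Multi-label: strict
    thresholding at *gamma* (the all-zero vector is the "Normal" label).
    """
    cl = np.asarray(confidences, dtype=float)
    if task == "multiclass":
        return int(np.argmax(cl))
    if task == "multilabel":
        return labels_from_confidence(cl, gamma)
    raise ValueError(f"unknown task {task!r}")


def _labels_equal(a, b) -> bool:
    if isinstance(a, (int, np.integer)) and isinstance(b, (int, np.integer)):
        return int(a) == int(b)
    return bool(np.array_equal(np.asarray(a), np.asarray(b)))


def is_success(original_label, adversarial_label, mode: str, target=None) -> bool:
    """Decide success: labels differ (untargeted) or match the target (targeted)."""
    if mode == "untargeted":
        return not _labels_equal(original_label, adversarial_label)
    if mode == "targeted":
        if target is None:
            raise ValueError("targeted success check requires a target")
        return _labels_equal(adversarial_label, target)
    raise ValueError(f"unknown mode {mode!r}")


def label_set_name(label, class_names: Sequence[str]) -> str:
    """Render a label as a class-name key for transformation matrices.

    Multiclass labels map to their class name; multi-label vectors map to the
    sorted, comma-joined names of the present classes, or ``"Normal"`` for
    the empty set.
    """
    if isinstance(label, (int, np.integer)):
        return class_names[int(label)]
    vec = np.asarray(label).astype(int)
    present = sorted(class_names[i] for i in np.flatnonzero(vec))
    return ", ".join(present) if present else NORMAL_NAME


def run_attack(
    image: np.ndarray,
    model_adapter: Callable[[np.ndarray], np.ndarray],
    config: AttackConfig,
    rng: np.random.Generator | None = None,
) -> AttackResult:
    """Attack a single image and report the outcome.

    The clean prediction defines the untargeted reference (we attack what the
    model believes, not the dataset truth).  A targeted attack whose target
    equals the clean label is rejected as a no-op.
    """
    arr = validate_image(image)
    clean = np.asarray(model_adapter(arr[None, ...]), dtype=float)
    if clean.ndim != 2 or clean.shape[0] != 1:
        raise ValueError(f"adapter returned shape {clean.shape} for a single image")
    clean = clean[0]
    original_label = predict_label(clean, config.task, config.gamma)

    if config.mode == "untargeted":
        reference = original_label
    else:
        target = config.target
        if config.task == "multilabel":
            target = np.asarray(target).astype(int)
        if _labels_equal(original_label, target):
            raise ValueError(
                "targeted attack is a no-op: target equals the clean prediction"
            )
        reference = target
    spec = FitnessSpec(
        task=config.task, mode=config.mode, reference=reference, delta=config.delta
    )

    def succeeded(cl: np.ndarray) -> bool:
        label = predict_label(cl, config.task, config.gamma)
        return is_success(original_label, label, config.mode, config.target)

    outcome = evolve(arr, model_adapter, config, spec, succeeded, rng)

    h, w, c = arr.shape
    if outcome.success_flags.any():
        # Winner: the success with the best fitness, ties to the lowest slot.
        idx = np.flatnonzero(outcome.success_flags)
        fit = outcome.population.fitnesses[idx]
        pick = idx[np.argmax(fit) if spec.direction == "maximize" else np.argmin(fit)]
        gene = quantize_gene(
            type(outcome.best_gene)(outcome.population.genes[int(pick)].copy(), c),
            h, w, c,
        )
        adv_conf = outcome.confidences[int(pick)]
        success = True
    else:
        gene = quantize_gene(outcome.best_gene, h, w, c)
        best = outcome.population.best_index(spec.direction)
        adv_conf = outcome.confidences[best]
        success = False
    adversarial_label = predict_label(adv_conf, config.task, config.gamma)
    return AttackResult(
        success=success,
        gene=gene,
        original_prediction=clean,
        adversarial_prediction=np.asarray(adv_conf, dtype=float),
        original_label=original_label,
        adversarial_label=adversarial_label,
        iterations_used=outcome.generations,
        best_fitness_trace=outcome.best_fitness_trace,
    )


@dataclass
class CampaignRecord:
    """One experiment within a campaign."""

    class_name: str
    image_index: int
    seed: int
    result: AttackResult


@dataclass
class CampaignResult:
    """Aggregate of a multi-image campaign."""

    records: list[CampaignRecord]
    matrix: TransformationMatrix
    trials: dict[str, int]
    excluded: dict[str, int]
    config: AttackConfig
    class_names: tuple[str, ...]

    def successes(self, class_name: str | None = None) -> list[AttackResult]:
        return [
            r.result
            for r in self.records
            if r.result.success and (class_name is None or r.class_name == class_name)
        ]

    def success_rates(self) -> dict[str, float]:
        from .metrics import success_rate

        return {
            name: success_rate(
                sum(1 for r in self.records if r.class_name == name and r.result.success),
                n,
            )
            for name, n in self.trials.items()
            if n > 0
        }


def attack_campaign(
    images: Sequence[np.ndarray],
    labels: Sequence,
    model_adapter: Callable[[np.ndarray], np.ndarray],
    config: AttackConfig,
    experiments_per_class: int,
    class_names: Sequence[str] | None = None,
    allow_repeats: bool = False,
) -> CampaignResult:
    """Attack many images grouped by their true class and count transformations.

    Each experiment runs with a derived seed (master seed + global experiment
    ordinal) so the whole campaign is reproducible and experiments stay
    independent.  Images the clean model already misclassifies are excluded
    from the trial counts and reported separately — an untargeted "success"
    on them would be ill-defined.  By default classes with fewer images than
    *experiments_per_class* are sampled without replacement until exhausted;
    ``allow_repeats=True`` recycles them instead.
    """
    if experiments_per_class < 1:
        raise ValueError("experiments_per_class must be >= 1")
    if len(images) != len(labels):
        raise ValueError("images and labels must have equal length")
    master = config.seed if config.seed is not None else 0

    if class_names is None:
        n_classes = np.asarray(model_adapter(validate_image(images[0])[None, ...])).shape[1]
        class_names = tuple(f"class_{i}" for i in range(n_classes))
    else:
        class_names = tuple(class_names)

    groups: dict[str, list[int]] = defaultdict(list)
    for i, lab in enumerate(labels):
        groups[label_set_name(lab, class_names)].append(i)

    counts: dict[tuple[str, str], int] = defaultdict(int)
    records: list[CampaignRecord] = []
    trials: dict[str, int] = {}
    excluded: dict[str, int] = defaultdict(int)
    origin_names: list[str] = []
    adv_names: set[str] = set()
    ordinal = 0
    for name in sorted(groups):
        indices = groups[name]
        if allow_repeats:
            chosen = [indices[k % len(indices)] for k in range(experiments_per_class)]
        else:
            chosen = indices[:experiments_per_class]
        origin_names.append(name)
        trials[name] = 0
        for img_idx in chosen:
            seed = master + ordinal
            ordinal += 1
            run_cfg = config.replace(seed=seed)
            # Exclude images the clean model gets wrong from the start.
            clean = np.asarray(model_adapter(validate_image(images[img_idx])[None, ...]))[0]
            clean_name = label_set_name(
                predict_label(clean, config.task, config.gamma), class_names
            )
            if clean_name != name:
                excluded[name] += 1
                continue
            result = run_attack(images[img_idx], model_adapter, run_cfg)
            records.append(CampaignRecord(name, img_idx, seed, result))
            trials[name] += 1
            if result.success:
                adv_name = label_set_name(result.adversarial_label, class_names)
                counts[(name, adv_name)] += 1
                adv_names.add(adv_name)

    all_adv = sorted(set(origin_names) | adv_names)
    matrix = TransformationMatrix.from_counts(
        counts, origin_classes=origin_names, adv_classes=all_adv
    )
    return CampaignResult(
        records=records,
        matrix=matrix,
        trials=dict(trials),
        excluded=dict(excluded),
        config=config,
        class_names=class_names,
    )
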