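"""Fitness scores steering the differential-evolution search.

Multiclass attacks read a single class confidence: the original class is
minimized (untargeted) or the target class maximized (targeted).  Multi-label
attacks score the whole confidence vector at once with a cosine similarity
between the (rescaled) reference label vector and the model's confidences:

    similarity(l, cl) = (l . cl) / max(||l|| * ||cl||, delta)

Both operands are first mapped element-wise from [0, 1] to [-1, 1] so that
the all-zero "Normal" label (no disease present) has a nonzero norm and the
fitness stays informative; ``delta`` (default 1e-5) guards the denominator
when a rescaled vector vanishes, e.g. a confidence vector of all 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "FitnessSpec",
    "multiclass_fitness",
    "multilabel_fitness",
    "rescale_unit_to_signed",
    "labels_from_confidence",
]


@dataclass(frozen=True)
class FitnessSpec:
    """What the optimizer scores and in which direction it pushes.

    ``reference`` is a class index for multiclass tasks, or a binary label
    vector for multi-label tasks (the original label when untargeted, the
    target label when targeted).  Untargeted attacks minimize the score,
    targeted attacks maximize it.
    """

    task: str  # "multiclass" | "multilabel"
    mode: str  # "untargeted" | "targeted"
    reference: int | np.ndarray
    delta: float = 1e-5

    def __post_init__(self) -> None:
        if self.task not in ("multiclass", "multilabel"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.mode not in ("untargeted", "targeted"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.task == "multilabel":
            ref = np.asarray(self.reference, dtype=float)
            object.__setattr__(self, "reference", ref)
        if self.delta <= 0:
            raise ValueError("delta must be > 0")

    @property
    def direction(self) -> str:
        """"minimize" for untargeted attacks, "maximize" for targeted ones."""
        return "minimize" if self.mode == "untargeted" else "maximize"

    def score(self, confidences: np.ndarray) -> float:
        if self.task == "multiclass":
            return multiclass_fitness(confidences, self)
        return multilabel_fitness(self.reference, confidences, self.delta)


def multiclass_fitness(confidences: np.ndarray, spec: FitnessSpec) -> float:
    """Confidence of the reference class — a coordinate projection."""
    cl = np.asarray(confidences, dtype=float)
    idx = int(spec.reference)
    if not 0 <= idx < cl.size:
        raise IndexError(f"class index {idx} out of range for {cl.size} classes")
    return float(cl[idx])


def rescale_unit_to_signed(v):
    """Map values element-wise from [0, 1] onto [-1, 1] via ``2v - 1``."""
    arr = np.asarray(v, dtype=float)
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("values must lie in [0, 1]")
    out = 2.0 * arr - 1.0
    return float(out) if np.isscalar(v) or arr.ndim == 0 else out


def multilabel_fitness(
    reference: np.ndarray, confidences: np.ndarray, delta: float = 1e-5
) -> float:
    """Guarded cosine similarity between rescaled label and confidence vectors.

    Returns an exact cosine in ``[-1, 1]`` whenever both rescaled vectors are
    nonzero; if either vanishes the numerator is zero and the guard yields 0.
    """
    ref = np.asarray(reference, dtype=float)
    cl = np.asarray(confidences, dtype=float)
    if ref.shape != cl.shape:
        raise ValueError(
            f"label vector has length {ref.size} but confidences have {cl.size}"
        )
    if delta <= 0:
        raise ValueError("delta must be > 0")
    a = rescale_unit_to_signed(ref)
    b = rescale_unit_to_signed(cl)
    denom = max(float(np.linalg.norm(a)) * float(np.linalg.norm(b)), delta)
    return float(np.dot(a, b) / denom)


def labels_from_confidence(confidences: np.ndarray, gamma: float = 0.5) -> np.ndarray:
    """Threshold multi-label confidences into a binary label vector.

    Entry *i* is 1 iff ``cl[i] > gamma`` (strictly).  The all-zero output is
    the "Normal" (no-disease) label.
    """
    if not 0.0 < gamma < 1.0:
        raise ValueError("gamma must lie in (0, 1)")
    cl = np.asarray(confidences, dtype=float)
    return (cl > gamma).astype(int)
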