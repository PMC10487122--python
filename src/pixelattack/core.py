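"""Core data model: images, perturbation genomes, and attack configuration.

Images are plain ``numpy`` arrays of shape ``(height, width, channels)`` with
integer intensities in ``[0, 255]`` and either 1 (greyscale) or 3 (RGB)
channels.  A candidate perturbation ("gene") is a flat real vector holding
``L`` pixel edits, each edit being ``(X, Y, I)`` for greyscale or
``(X, Y, R, G, B)`` for colour, where ``X`` indexes columns and ``Y`` rows,
both 0-based.  The genome stays real-valued during evolution; it is projected
onto the discrete image grid (rounded and clipped) every time it is applied.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "validate_image",
    "PerturbationGene",
    "AttackConfig",
    "AttackResult",
    "quantize_gene",
    "apply_perturbation",
]


def validate_image(image: np.ndarray) -> np.ndarray:
    """Coerce *image* to a ``(H, W, C)`` uint8 array and check its invariants.

    2-D input is treated as a single-channel image.  Intensities must already
    lie in ``[0, 255]``; floating-point substrates are rejected.
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    if arr.ndim != 3:
        raise ValueError(f"image must be 2-D or 3-D, got shape {arr.shape}")
    if arr.shape[2] not in (1, 3):
        raise ValueError(f"image must have 1 or 3 channels, got {arr.shape[2]}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have positive height and width")
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"image intensities must be integer, got {arr.dtype}")
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError("image intensities must lie in [0, 255]")
    return arr.astype(np.uint8, copy=False)


@dataclass(frozen=True)
class PerturbationGene:
    """A candidate perturbation: ``L`` pixel edits as one flat real vector.

    The vector layout is ``(X1, Y1, I1..., X2, Y2, I2..., ...)`` with
    ``2 + channels`` slots per edit.
    """

    vector: np.ndarray
    channels: int

    def __post_init__(self) -> None:
        vec = np.asarray(self.vector, dtype=float)
        object.__setattr__(self, "vector", vec)
        if self.channels not in (1, 3):
            raise ValueError(f"channels must be 1 or 3, got {self.channels}")
        stride = 2 + self.channels
        if vec.ndim != 1 or vec.size == 0 or vec.size % stride:
            raise ValueError(
                f"gene vector length {vec.size} is not a positive multiple of {stride}"
            )

    @property
    def n_pixels(self) -> int:
        """The pixel budget ``L`` encoded by this gene."""
        return self.vector.size // (2 + self.channels)

    @property
    def edits(self) -> np.ndarray:
        """View of the vector as ``(L, 2 + channels)`` rows ``(X, Y, *values)``."""
        return self.vector.reshape(self.n_pixels, 2 + self.channels)


def _round_half_away(v: np.ndarray) -> np.ndarray:
    # numpy's rint rounds half-to-even; the genome projection rounds half
    # away from zero so e.g. 2.5 -> 3 regardless of parity.
    return np.copysign(np.floor(np.abs(v) + 0.5), v)


def quantize_vector(
    vector: np.ndarray, height: int, width: int, channels: int
) -> np.ndarray:
    """Project a raw gene vector onto the discrete image grid (array form)."""
    stride = 2 + channels
    edits = np.asarray(vector, dtype=float).reshape(-1, stride).copy()
    edits = _round_half_away(edits)
    edits[:, 0] = np.clip(edits[:, 0], 0, width - 1)
    edits[:, 1] = np.clip(edits[:, 1], 0, height - 1)
    edits[:, 2:] = np.clip(edits[:, 2:], 0, 255)
    return edits.reshape(-1)


def quantize_gene(
    gene: PerturbationGene, height: int, width: int, channels: int
) -> PerturbationGene:
    """Round coordinates/intensities half-away-from-zero and clip into range.

    Coordinates are clipped to ``[0, dim - 1]`` and intensities to
    ``[0, 255]``.  The input gene is untouched; quantization is a projection
    (applying it twice equals applying it once).
    """
    if gene.channels != channels:
        raise ValueError(
            f"gene encodes {gene.channels}-channel edits but image has {channels}"
        )
    return PerturbationGene(
        quantize_vector(gene.vector, height, width, channels), channels
    )


def apply_perturbation(image: np.ndarray, gene: PerturbationGene) -> np.ndarray:
    """Return a copy of *image* with the gene's pixel edits written in.

    The gene is quantized internally, so raw (real-valued) genes are accepted.
    At most ``L`` pixel positions differ from the input; when two edits target
    the same pixel the later edit in the sequence wins.
    """
    arr = validate_image(image)
    h, w, c = arr.shape
    q = quantize_gene(gene, h, w, c)
    out = arr.copy()
    for edit in q.edits:
        x, y = int(edit[0]), int(edit[1])
        out[y, x, :] = edit[2:].astype(np.uint8)
    return out


@dataclass(frozen=True)
class AttackConfig:
    """Attack configuration: pixel budget, mode, and DE hyperparameters.

    Defaults follow the standard one-pixel-attack setup: population of 100,
    mutant factor ``F = 0.5``, at most 100 generations, early stop once 1% of
    the population has crossed the decision boundary, label threshold
    ``gamma = 0.5`` for multi-label tasks and denominator guard
    ``delta = 1e-5`` in the cosine fitness.
    """

    pixels: int = 1
    mode: str = "untargeted"  # "untargeted" | "targeted"
    task: str = "multiclass"  # "multiclass" | "multilabel"
    target: int | Sequence[int] | None = None
    population_size: int = 100
    mutant_factor: float = 0.5
    max_iterations: int = 100
    early_stop_fraction: float = 0.01
    gamma: float = 0.5
    delta: float = 1e-5
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pixels < 1:
            raise ValueError("pixel budget must be >= 1")
        if self.mode not in ("untargeted", "targeted"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.task not in ("multiclass", "multilabel"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.mode == "targeted" and self.target is None:
            raise ValueError("targeted attacks require a target")
        if self.population_size < 4:
            # DE mutation draws three mutually distinct donors per slot.
            raise ValueError("population_size must be >= 4")
        if not 0.0 <= self.mutant_factor <= 1.0:
            raise ValueError("mutant_factor must lie in [0, 1]")
        if self.max_iterations < 0:
            raise ValueError("max_iterations must be >= 0")
        if self.early_stop_fraction < 0:
            raise ValueError("early_stop_fraction must be >= 0")
        if not 0.0 < self.gamma < 1.0:
            raise ValueError("gamma must lie in (0, 1)")
        if self.delta <= 0:
            raise ValueError("delta must be > 0")

    def replace(self, **kwargs) -> "AttackConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class AttackResult:
    """Outcome of a single attack on one image.

    ``success`` implies the adversarial label differs from the original
    (untargeted) or matches the target exactly (targeted).  The winning gene
    is stored quantized; ``best_fitness_trace`` holds the population-best
    fitness after each generation, starting with the initial population.
    """

    success: bool
    gene: PerturbationGene | None
    original_prediction: np.ndarray
    adversarial_prediction: np.ndarray
    original_label: int | np.ndarray
    adversarial_label: int | np.ndarray
    iterations_used: int
    best_fitness_trace: list[float] = field(default_factory=list)
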