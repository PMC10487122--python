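"""Exhaustive-search oracle and search-space accounting.

The discrete one-pixel attack space for an ``H x W`` image with ``C``
channels and ``V`` intensity levels holds ``H * W * V**C`` candidates — over
8.4e11 for a 224x224 RGB image at 8-bit depth, which is why the production
search is evolutionary.  On tiny instances, however, the space can be
enumerated outright, giving an independent ground truth the DE results are
checked against in the test suite.
"""

from __future__ import annotations

import itertools
from typing import Callable

import numpy as np

from .core import PerturbationGene, validate_image
from .fitness import FitnessSpec

__all__ = ["search_space_size", "exhaustive_one_pixel_oracle", "intensity_grid"]


def search_space_size(
    height: int, width: int, channels: int, levels: int, pixels: int
) -> int:
    """Exact number of discrete candidate perturbations.

    For one pixel this is ``height * width * levels**channels``; for larger
    budgets the per-edit count is raised to the ``pixels`` power (a
    feasibility guard, not an enumeration plan).
    """
    if min(height, width, channels, levels, pixels) < 1:
        raise ValueError("all search-space arguments must be >= 1")
    per_edit = height * width * levels**channels
    return per_edit**pixels


def intensity_grid(levels: int) -> np.ndarray:
    """*levels* integer intensities evenly spread over [0, 255], endpoints included."""
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if levels == 1:
        return np.array([0], dtype=int)
    return np.rint(np.linspace(0.0, 255.0, levels)).astype(int)


def exhaustive_one_pixel_oracle(
    image: np.ndarray,
    model_adapter: Callable[[np.ndarray], np.ndarray],
    fitness_spec: FitnessSpec,
    levels: int = 256,
    budget_cap: int = 10**6,
    batch_size: int = 4096,
) -> tuple[PerturbationGene, float]:
    """Brute-force the best single-pixel edit by trying every candidate.

    Candidates are enumerated in lexicographic ``(y, x, value)`` order and
    evaluated in batches; ties keep the earliest candidate, so a constant
    model returns the edit at ``(0, 0)`` with the lowest intensity.  Inputs
    whose candidate count exceeds *budget_cap* are rejected, reporting the
    count.
    """
    arr = validate_image(image)
    h, w, c = arr.shape
    size = search_space_size(h, w, c, levels, 1)
    if size > budget_cap:
        raise ValueError(
            f"exhaustive search over {size} candidates exceeds the budget cap "
            f"of {budget_cap}"
        )
    values = intensity_grid(levels)
    combos = list(itertools.product(values, repeat=c))

    candidates = np.empty((size, 2 + c))
    k = 0
    for y in range(h):
        for x in range(w):
            for combo in combos:
                candidates[k, 0] = x
                candidates[k, 1] = y
                candidates[k, 2:] = combo
                k += 1

    maximize = fitness_spec.direction == "maximize"
    best_fit = -np.inf if maximize else np.inf
    best_idx = -1
    for start in range(0, size, batch_size):
        chunk = candidates[start : start + batch_size]
        batch = np.repeat(arr[None, ...], chunk.shape[0], axis=0)
        rows = chunk[:, 1].astype(int)
        cols = chunk[:, 0].astype(int)
        batch[np.arange(chunk.shape[0]), rows, cols, :] = chunk[:, 2:].astype(np.uint8)
        confs = np.asarray(model_adapter(batch), dtype=float)
        for i, cl in enumerate(confs):
            fit = fitness_spec.score(cl)
            if (maximize and fit > best_fit) or (not maximize and fit < best_fit):
                best_fit = fit
                best_idx = start + i
    gene = PerturbationGene(candidates[best_idx].copy(), c)
    return gene, float(best_fit)
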