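"""Attack-evaluation statistics.

Given a transformation-count matrix ``n[ori, adv]`` from a campaign, this
module computes:

* the per-class success rate (successes / trials);
* row transformation ratios ``r[ori, adv] = n[ori, adv] / sum_adv n[ori, adv]``;
* the failure-corrected per-class transformation ratio
  ``T[adv] = sum_ori r[ori, adv] / (K - F)``, where ``K`` is the number of
  origin classes and ``F`` the number of origin classes with no successful
  attack at all (their rows contribute nothing, so leaving them in the
  denominator would deflate every ratio; with the correction the ``T`` values
  sum to exactly 1);
* disease-type conversion summaries (Disease→Normal vs Normal→Disease counts
  and their percentages over the cross-type total);
* the mean target-class confidence over successful adversarial images.

Ratios are accumulated in exact rational arithmetic (``fractions.Fraction``)
and only converted to floats at the edge, so the sum-to-one identity holds
exactly and printed two-decimal percentages are stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TransformationMatrix",
    "success_rate",
    "row_transform_ratios",
    "transformation_ratio",
    "transformation_ratio_exact",
    "conversion_summary",
    "ConversionSummary",
    "derive_multilabel_disease_map",
    "avg_confidence",
    "render_table",
]


@dataclass(frozen=True)
class TransformationMatrix:
    """Counts of successful class transformations, origin rows x adversarial columns.

    Origin and adversarial class sets may differ (multi-label campaigns map a
    handful of origin labels onto many composite adversarial label sets).
    Wherever an origin name equals an adversarial name the count is zero:
    landing on your own class is not a transformation.
    """

    origin_classes: tuple[str, ...]
    adv_classes: tuple[str, ...]
    counts: np.ndarray  # int array, shape (len(origin_classes), len(adv_classes))

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "origin_classes", tuple(self.origin_classes))
        object.__setattr__(self, "adv_classes", tuple(self.adv_classes))
        if counts.shape != (len(self.origin_classes), len(self.adv_classes)):
            raise ValueError(
                f"counts shape {counts.shape} does not match class axes "
                f"({len(self.origin_classes)}, {len(self.adv_classes)})"
            )
        if (counts < 0).any():
            raise ValueError("transformation counts must be non-negative")
        for i, ori in enumerate(self.origin_classes):
            for j, adv in enumerate(self.adv_classes):
                if ori == adv and counts[i, j] != 0:
                    raise ValueError(
                        f"diagonal entry ({ori!r}) must be zero: "
                        "ori == adv is a failed attack"
                    )

    @classmethod
    def from_counts(
        cls,
        counts: Mapping[tuple[str, str], int],
        origin_classes: Sequence[str],
        adv_classes: Sequence[str] | None = None,
    ) -> "TransformationMatrix":
        if adv_classes is None:
            adv_classes = origin_classes
        arr = np.zeros((len(origin_classes), len(adv_classes)), dtype=int)
        ori_idx = {c: i for i, c in enumerate(origin_classes)}
        adv_idx = {c: j for j, c in enumerate(adv_classes)}
        for (ori, adv), n in counts.items():
            arr[ori_idx[ori], adv_idx[adv]] = n
        return cls(tuple(origin_classes), tuple(adv_classes), arr)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "TransformationMatrix":
        return cls(tuple(df.index), tuple(df.columns), df.to_numpy(dtype=int))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.origin_classes), columns=list(self.adv_classes)
        )

    @property
    def is_square(self) -> bool:
        return self.origin_classes == self.adv_classes

    def row_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def failed_classes(self) -> list[str]:
        """Origin classes with no successful attack (all-zero rows)."""
        return [c for c, s in zip(self.origin_classes, self.row_sums()) if s == 0]


def success_rate(successes: int, trials: int) -> float:
    """Fraction of experiments that produced a successful adversarial image."""
    if trials < 1:
        raise ValueError("trials must be >= 1")
    if not 0 <= successes <= trials:
        raise ValueError("successes must lie in [0, trials]")
    return successes / trials


def row_transform_ratios(matrix: TransformationMatrix) -> pd.DataFrame:
    """Each origin row normalized by its own sum; failed rows stay all-zero.

    The list of failed (all-zero) origin classes is attached as
    ``df.attrs["failed_classes"]``.
    """
    sums = matrix.row_sums()
    ratios = np.zeros(matrix.counts.shape, dtype=float)
    nonzero = sums > 0
    ratios[nonzero] = matrix.counts[nonzero] / sums[nonzero, None]
    df = pd.DataFrame(
        ratios, index=list(matrix.origin_classes), columns=list(matrix.adv_classes)
    )
    df.attrs["failed_classes"] = matrix.failed_classes()
    return df


def transformation_ratio_exact(matrix: TransformationMatrix) -> dict[str, Fraction]:
    """Failure-corrected transformation ratio per adversarial class, exact."""
    if len(matrix.origin_classes) < 2:
        raise ValueError("transformation ratios need at least 2 origin classes")
    sums = matrix.row_sums()
    n_failed = int((sums == 0).sum())
    denom = len(matrix.origin_classes) - n_failed
    if denom == 0:
        raise ValueError("every origin class failed; the ratio is undefined")
    out: dict[str, Fraction] = {}
    for j, adv in enumerate(matrix.adv_classes):
        col = Fraction(0)
        for i in range(len(matrix.origin_classes)):
            if sums[i] > 0:
                col += Fraction(int(matrix.counts[i, j]), int(sums[i]))
        out[adv] = col / denom
    return out


def transformation_ratio(matrix: TransformationMatrix) -> pd.Series:
    """Float view of :func:`transformation_ratio_exact`, indexed by class."""
    exact = transformation_ratio_exact(matrix)
    return pd.Series({k: float(v) for k, v in exact.items()}, name="transform_ratio")


@dataclass(frozen=True)
class ConversionSummary:
    """Cross-type conversion counts and percentages.

    Percentages are taken over the cross-type total only
    (``disease_to_normal + normal_to_disease``); same-type transitions are
    counted but excluded from the percentage base.  When the base is zero the
    percentages are ``None``.
    """

    disease_to_normal: int
    normal_to_disease: int
    disease_to_disease: int
    normal_to_normal: int
    disease_to_normal_pct: float | None
    normal_to_disease_pct: float | None


def derive_multilabel_disease_map(class_names: Iterable[str]) -> dict[str, str]:
    """Disease-type map for label-set classes: empty set ("Normal") vs the rest."""
    return {name: ("Normal" if name == "Normal" else "Disease") for name in class_names}


def conversion_summary(
    matrix: TransformationMatrix, disease_map: Mapping[str, str]
) -> ConversionSummary:
    """Tally transformations between the Normal and Disease class types."""
    for name in (*matrix.origin_classes, *matrix.adv_classes):
        if name not in disease_map:
            raise KeyError(f"class {name!r} missing from the disease-type map")
        if disease_map[name] not in ("Normal", "Disease"):
            raise ValueError(f"disease type for {name!r} must be 'Normal' or 'Disease'")
    tallies = {"DN": 0, "ND": 0, "DD": 0, "NN": 0}
    for i, ori in enumerate(matrix.origin_classes):
        for j, adv in enumerate(matrix.adv_classes):
            key = ("D" if disease_map[ori] == "Disease" else "N") + (
                "D" if disease_map[adv] == "Disease" else "N"
            )
            tallies[key] += int(matrix.counts[i, j])
    base = tallies["DN"] + tallies["ND"]
    return ConversionSummary(
        disease_to_normal=tallies["DN"],
        normal_to_disease=tallies["ND"],
        disease_to_disease=tallies["DD"],
        normal_to_normal=tallies["NN"],
        disease_to_normal_pct=100.0 * tallies["DN"] / base if base else None,
        normal_to_disease_pct=100.0 * tallies["ND"] / base if base else None,
    )


def avg_confidence(results: Sequence, target_class: int) -> float:
    """Mean target-class confidence over successful adversarial images."""
    if len(results) == 0:
        raise ValueError("avg_confidence is undefined for an empty result set")
    vals = []
    for r in results:
        if not r.success:
            raise ValueError("avg_confidence expects successful results only")
        vals.append(float(np.asarray(r.adversarial_prediction)[int(target_class)]))
    return float(np.mean(vals))


def render_table(df: pd.DataFrame, percent: bool = False) -> str:
    """Aligned-text rendering of a metrics table (two-decimal percentages)."""
    if percent:
        df = df.map(lambda v: f"{100.0 * v:.2f}%" if isinstance(v, float) else v)
    return df.to_string()
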