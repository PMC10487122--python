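"""Bundled reference campaign tables for one-pixel attacks on medical imagery.

Two published transformation-count tables ship with the package as worked
examples and as fixed inputs for validating the metrics pipeline end to end:

* a seven-class dermatoscopy campaign (pigmented skin lesions, 100 untargeted
  one-pixel attacks per class) with the clinical Normal/Disease type of each
  class; and
* a five-origin multi-label chest X-ray campaign whose successful attacks
  land on composite label sets (e.g. "Atelectasis, Effusion"), with the
  empty label set rendered as "Normal".

Counts are successful transformations from the origin class (rows) to the
adversarial class (columns); origins that keep their own class are failures
and appear as zeros.
"""

from __future__ import annotations

import numpy as np

from .metrics import TransformationMatrix, derive_multilabel_disease_map

__all__ = [
    "DERMATOSCOPY_CLASSES",
    "DERMATOSCOPY_DISEASE_TYPES",
    "dermatoscopy_transformations",
    "CHEST_ORIGIN_CLASSES",
    "chest_transformations",
    "chest_disease_types",
]

DERMATOSCOPY_CLASSES: tuple[str, ...] = (
    "Benign Keratosis",
    "Melanocytic Nevi",
    "Dermatofibroma",
    "Melanoma",
    "Vascular Skin Lesions",
    "Basal Cell Carcinoma",
    "Actinic Keratoses",
)

# Clinical grouping: benign/naevoid lesions count as Normal, carcinomas and
# other pathology as Disease.
DERMATOSCOPY_DISEASE_TYPES: dict[str, str] = {
    "Benign Keratosis": "Normal",
    "Melanocytic Nevi": "Normal",
    "Dermatofibroma": "Normal",
    "Melanoma": "Disease",
    "Vascular Skin Lesions": "Disease",
    "Basal Cell Carcinoma": "Disease",
    "Actinic Keratoses": "Disease",
}

_DERMATOSCOPY_COUNTS = np.array(
    [
        #  BK  MN  DF Mel VSL BCC  AK
        [   0, 18,  1,  8,  0,  9,  5],  # Benign Keratosis
        [   3,  0,  0,  0,  0,  1,  0],  # Melanocytic Nevi
        [   2, 18,  0,  0,  0, 57,  3],  # Dermatofibroma
        [   4, 11,  0,  0,  0,  1,  0],  # Melanoma
        [   0,  9,  0,  0,  0,  1,  0],  # Vascular Skin Lesions
        [   7, 12,  4,  3,  0,  0,  6],  # Basal Cell Carcinoma
        [  10,  0,  4,  3,  0, 24,  0],  # Actinic Keratoses
    ],
    dtype=int,
)


def dermatoscopy_transformations() -> TransformationMatrix:
    """The seven-class dermatoscopy transformation-count matrix."""
    return TransformationMatrix(
        DERMATOSCOPY_CLASSES, DERMATOSCOPY_CLASSES, _DERMATOSCOPY_COUNTS.copy()
    )


CHEST_ORIGIN_CLASSES: tuple[str, ...] = (
    "Normal",
    "Infiltration",
    "Atelectasis",
    "Effusion",
    "Nodule",
)

# Adversarial label sets observed in the chest campaign and the counts per
# origin class, stored origin x adversarial.
_CHEST_ADV_SETS: tuple[str, ...] = (
    "Atelectasis",
    "Atelectasis, Effusion",
    "Atelectasis, Effusion, Infiltration",
    "Atelectasis, Infiltration",
    "Atelectasis, Nodule",
    "Cardiomegaly",
    "Effusion",
    "Effusion, Infiltration",
    "Effusion, Mass",
    "Effusion, Mass, Pleural Thickening",
    "Infiltration",
    "Infiltration, Edema",
    "Infiltration, Nodule",
    "Mass",
    "Mass, Nodule",
    "Nodule",
    "Normal",
    "Pneumothorax",
)

_CHEST_COUNTS_BY_ADV = np.array(
    [
        # Normal Infiltration Atelectasis Effusion Nodule   (origins)
        [13, 3, 0, 3, 5],     # Atelectasis
        [0, 1, 7, 15, 0],     # Atelectasis, Effusion
        [0, 0, 1, 0, 0],      # Atelectasis, Effusion, Infiltration
        [2, 9, 15, 2, 0],     # Atelectasis, Infiltration
        [0, 0, 0, 0, 1],      # Atelectasis, Nodule
        [1, 1, 1, 0, 0],      # Cardiomegaly
        [8, 1, 6, 0, 4],      # Effusion
        [1, 4, 0, 19, 0],     # Effusion, Infiltration
        [0, 0, 0, 1, 1],      # Effusion, Mass
        [0, 0, 0, 2, 0],      # Effusion, Mass, Pleural Thickening
        [51, 0, 17, 13, 17],  # Infiltration
        [0, 6, 0, 0, 0],      # Infiltration, Edema
        [2, 5, 0, 0, 21],     # Infiltration, Nodule
        [13, 1, 2, 2, 0],     # Mass
        [1, 0, 0, 0, 14],     # Mass, Nodule
        [2, 0, 0, 0, 0],      # Nodule
        [0, 54, 44, 30, 28],  # Normal
        [1, 0, 1, 0, 0],      # Pneumothorax
    ],
    dtype=int,
)


def chest_transformations() -> TransformationMatrix:
    """The multi-label chest X-ray transformation matrix, origin x label set."""
    return TransformationMatrix(
        CHEST_ORIGIN_CLASSES, _CHEST_ADV_SETS, _CHEST_COUNTS_BY_ADV.T.copy()
    )


def chest_disease_types() -> dict[str, str]:
    """Disease-type map for the chest campaign: empty label set vs the rest."""
    return derive_multilabel_disease_map(CHEST_ORIGIN_CLASSES + _CHEST_ADV_SETS)
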