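"""Synthetic images and deterministic toy classifiers.

Real victim models are deep CNNs trained on clinical datasets; everything in
this package is testable without them thanks to two stand-ins:

* synthetic rasters — flat/gradient calibration patterns plus two loosely
  medical-looking families: ``xray_like`` greyscale fields with a bright
  ellipse (chest-film flavour) and ``lesion_like`` colour discs on a
  skin-toned background (dermatoscopy flavour);
* toy classifiers — tiny pure functions of the pixel values that expose the
  behaviours the attack needs to exercise: an unattackable constant model, a
  softmax-of-mean-intensity linear model, a "fragile" threshold-pixel model
  that is one-pixel-attackable by construction, and a per-region sigmoid
  model producing multi-label confidences.

Both are deterministic given their seed/parameters, so every test and every
campaign built on them reproduces exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import validate_image

__all__ = ["make_synthetic_image", "make_toy_classifier", "ToyClassifier"]

PATTERNS = ("uniform", "gradient", "blob", "xray_like", "lesion_like")


def make_synthetic_image(
    height: int,
    width: int,
    channels: int = 1,
    pattern: str = "xray_like",
    rng: np.random.Generator | None = None,
    value: int = 128,
) -> np.ndarray:
    """Generate a deterministic synthetic test image.

    ``uniform`` fills with *value*; ``gradient`` ramps 0..255 left to right;
    ``blob`` places one bright Gaussian bump on a noisy dark background;
    ``xray_like`` overlays a bright ellipse on a smooth low-frequency field;
    ``lesion_like`` draws a dark-brown disc on a skin-toned background.
    """
    if pattern not in PATTERNS:
        raise ValueError(f"pattern must be one of {PATTERNS}, got {pattern!r}")
    if rng is None:
        rng = np.random.default_rng(0)
    yy, xx = np.mgrid[0:height, 0:width].astype(float)

    if pattern == "uniform":
        img = np.full((height, width), float(value))
    elif pattern == "gradient":
        img = 255.0 * xx / max(width - 1, 1)
    elif pattern == "blob":
        cy = rng.uniform(0.3, 0.7) * height
        cx = rng.uniform(0.3, 0.7) * width
        sigma = max(min(height, width) / 8.0, 1.0)
        bump = 180.0 * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sigma**2))
        # truncated noise and a truncated bump tail keep the set of pixels
        # above background + 3 sigma exactly one disc: noise alone never
        # crosses it and the bump region clears it everywhere
        bump = np.where(bump >= 30.0, bump, 0.0)
        noise = np.clip(rng.normal(0.0, 5.0, size=(height, width)), -10.0, 10.0)
        img = 40.0 + noise + bump
    elif pattern == "xray_like":
        # Smooth anatomical-looking field: a couple of low-frequency modes
        # plus a bright ellipse roughly where a mediastinum would sit.
        phase1, phase2 = rng.uniform(0, 2 * np.pi, size=2)
        img = (
            90.0
            + 35.0 * np.cos(2 * np.pi * yy / height + phase1)
            + 25.0 * np.cos(2 * np.pi * xx / width + phase2)
        )
        cy, cx = 0.5 * height, 0.5 * width
        ell = ((yy - cy) / (0.45 * height)) ** 2 + ((xx - cx) / (0.22 * width)) ** 2
        img = img + 90.0 * (ell < 1.0)
        img += rng.normal(0.0, 4.0, size=(height, width))
    else:  # lesion_like
        base = np.array([224.0, 172.0, 150.0])  # skin tone
        img3 = np.empty((height, width, 3))
        img3[:] = base + rng.normal(0.0, 6.0, size=(height, width, 1))
        cy = rng.uniform(0.35, 0.65) * height
        cx = rng.uniform(0.35, 0.65) * width
        radius = 0.22 * min(height, width)
        disc = ((yy - cy) ** 2 + (xx - cx) ** 2) < radius**2
        lesion = np.array([101.0, 67.0, 50.0])  # dark brown
        img3[disc] = lesion + rng.normal(0.0, 8.0, size=(int(disc.sum()), 3))
        out = np.clip(np.rint(img3), 0, 255).astype(np.uint8)
        if channels == 1:
            out = np.rint(out @ np.array([0.299, 0.587, 0.114]))[..., None]
            out = np.clip(out, 0, 255).astype(np.uint8)
        return validate_image(out)

    out = np.clip(np.rint(img), 0, 255).astype(np.uint8)[..., None]
    if channels == 3:
        out = np.repeat(out, 3, axis=2)
    return validate_image(out)


@dataclass(frozen=True)
class ToyClassifier:
    """A pure, deterministic classifier adapter for tests and demos.

    Instances are callables mapping a batch ``(N, H, W, C)`` of images to a
    ``(N, K)`` array of confidences — the same adapter contract real victim
    models are wrapped into.
    """

    kind: str
    n_classes: int
    task: str = "multiclass"
    params: dict = field(default_factory=dict)

    def __call__(self, batch: np.ndarray) -> np.ndarray:
        batch = np.asarray(batch)
        if batch.ndim != 4:
            raise ValueError("expected a batch of shape (N, H, W, C)")
        x = batch.astype(float)
        if self.kind == "constant":
            conf = np.asarray(self.params["confidences"], dtype=float)
            return np.tile(conf, (batch.shape[0], 1))
        if self.kind == "linear_multiclass":
            weights = np.asarray(self.params["weights"], dtype=float)
            biases = np.asarray(self.params["biases"], dtype=float)
            means = x.mean(axis=(1, 2, 3)) / 255.0
            scores = means[:, None] * weights[None, :] + biases[None, :]
            z = np.exp(scores - scores.max(axis=1, keepdims=True))
            return z / z.sum(axis=1, keepdims=True)
        if self.kind == "fragile_pixel":
            threshold = self.params["threshold"]
            pixel = self.params["pixel"]
            confident = self.params["confidence"]
            if pixel is None:
                hot = (x > threshold).any(axis=(1, 2, 3))
            else:
                py, px = pixel
                hot = (x[:, py, px, :] > threshold).any(axis=1)
            rest = (1.0 - confident) / (self.n_classes - 1)
            out = np.full((batch.shape[0], self.n_classes), rest)
            cls = np.where(hot, self.params["above_class"], self.params["below_class"])
            out[np.arange(batch.shape[0]), cls] = confident
            return out
        if self.kind == "multilabel_sigmoid":
            # One vertical band per class; confidence is a logistic function
            # of the band's mean intensity around the chosen midpoint.
            midpoint = self.params["midpoint"]
            scale = self.params["scale"]
            bands = np.array_split(np.arange(batch.shape[2]), self.n_classes)
            means = np.stack(
                [x[:, :, b, :].mean(axis=(1, 2, 3)) for b in bands], axis=1
            )
            return 1.0 / (1.0 + np.exp(-scale * (means - midpoint)))
        raise ValueError(f"unknown toy classifier kind {self.kind!r}")


def make_toy_classifier(
    kind: str,
    n_classes: int = 2,
    task: str = "multiclass",
    **params,
) -> ToyClassifier:
    """Build a toy classifier adapter.

    Kinds
    -----
    ``constant``
        Always returns the same confidence vector (``confidences=...``,
        default one-hot-ish on class 0).  Unattackable by construction.
    ``linear_multiclass``
        Softmax over per-class linear scores of the mean image intensity
        (``weights``, ``biases``; defaults spread the weights over [-2, 2]).
        Fitness is monotone in any single pixel's value.
    ``fragile_pixel``
        Predicts ``above_class`` when the watched pixel (or, with
        ``pixel=None``, any pixel) exceeds ``threshold`` (default 200), else
        ``below_class`` — guaranteed one-pixel-attackable whenever the
        threshold is below 255.
    ``multilabel_sigmoid``
        Splits the image into ``n_classes`` vertical bands and returns a
        logistic confidence per band mean (``midpoint`` default 127.5,
        ``scale`` default 0.08); confidences do not sum to 1.
    """
    if kind == "constant":
        conf = params.pop("confidences", None)
        if conf is None:
            conf = np.full(n_classes, 0.1 / max(n_classes - 1, 1))
            conf[0] = 0.9
        conf = np.asarray(conf, dtype=float)
        if conf.size != n_classes:
            raise ValueError("confidences length must equal n_classes")
        params = {"confidences": conf, **params}
    elif kind == "linear_multiclass":
        params.setdefault("weights", np.linspace(-2.0, 2.0, n_classes))
        params.setdefault("biases", np.zeros(n_classes))
    elif kind == "fragile_pixel":
        params.setdefault("threshold", 200)
        params.setdefault("pixel", None)
        params.setdefault("below_class", 0)
        params.setdefault("above_class", 1)
        params.setdefault("confidence", 0.9)
    elif kind == "multilabel_sigmoid":
        task = "multilabel"
        params.setdefault("midpoint", 127.5)
        params.setdefault("scale", 0.08)
    else:
        raise ValueError(f"unknown toy classifier kind {kind!r}")
    return ToyClassifier(kind=kind, n_classes=n_classes, task=task, params=params)
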