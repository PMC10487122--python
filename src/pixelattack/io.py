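"""Image reading/writing and campaign-result serialization.

Raster input goes through Pillow (PNG/TIFF/JPEG), with optional bilinear
resizing to a square side (classifiers in this space conventionally consume
224x224) and channel coercion (RGB->grey via the standard luma weights,
grey->RGB via replication).  Campaign output is plain JSON + CSV plus one PNG
per successful adversarial image.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

from .attack import CampaignRecord, CampaignResult
from .core import AttackConfig, AttackResult, PerturbationGene, validate_image
from .metrics import (
    TransformationMatrix,
    conversion_summary,
    transformation_ratio,
)

__all__ = ["read_image", "write_image", "write_results", "load_results"]

SUPPORTED_SUFFIXES = {".png", ".tif", ".tiff", ".jpg", ".jpeg"}


def read_image(
    path: str | Path,
    resize_side: int | None = None,
    force_channels: int | None = None,
) -> np.ndarray:
    """Decode an image file into a ``(H, W, C)`` uint8 array.

    ``resize_side`` rescales to a square with bilinear interpolation;
    ``force_channels`` coerces to greyscale (1) or RGB (3).  Without it,
    native greyscale stays 1-channel and everything else becomes RGB.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    if path.suffix.lower() not in SUPPORTED_SUFFIXES:
        raise ValueError(f"unsupported image format {path.suffix!r} for {path}")
    try:
        img = Image.open(path)
        img.load()
    except Exception as exc:  # pragma: no cover - PIL error classes vary
        raise ValueError(f"could not decode image {path}: {exc}") from exc
    if force_channels == 1:
        mode = "L"
    elif force_channels == 3:
        mode = "RGB"
    elif force_channels is None:
        mode = "L" if img.mode in ("L", "1", "I", "I;16") else "RGB"
    else:
        raise ValueError("force_channels must be 1, 3 or None")
    if img.mode != mode:
        img = img.convert(mode)
    if resize_side is not None and img.size != (resize_side, resize_side):
        img = img.resize((resize_side, resize_side), Image.Resampling.BILINEAR)
    arr = np.asarray(img)
    if arr.ndim == 2:
        arr = arr[:, :, None]
    return validate_image(arr)


def write_image(image: np.ndarray, path: str | Path) -> None:
    arr = validate_image(image)
    if arr.shape[2] == 1:
        Image.fromarray(arr[:, :, 0], mode="L").save(path)
    else:
        Image.fromarray(arr, mode="RGB").save(path)


def _label_to_json(label):
    if isinstance(label, (int, np.integer)):
        return int(label)
    return [int(v) for v in np.asarray(label).ravel()]


def _label_from_json(obj):
    if isinstance(obj, int):
        return obj
    return np.asarray(obj, dtype=int)


def _result_to_dict(result: AttackResult) -> dict:
    return {
        "success": bool(result.success),
        "gene": None
        if result.gene is None
        else {
            "vector": [float(v) for v in result.gene.vector],
            "channels": int(result.gene.channels),
        },
        "original_prediction": [float(v) for v in result.original_prediction],
        "adversarial_prediction": [float(v) for v in result.adversarial_prediction],
        "original_label": _label_to_json(result.original_label),
        "adversarial_label": _label_to_json(result.adversarial_label),
        "iterations_used": int(result.iterations_used),
        "best_fitness_trace": [float(v) for v in result.best_fitness_trace],
    }


def _result_from_dict(d: dict) -> AttackResult:
    gene = d["gene"]
    return AttackResult(
        success=d["success"],
        gene=None
        if gene is None
        else PerturbationGene(np.asarray(gene["vector"], dtype=float), gene["channels"]),
        original_prediction=np.asarray(d["original_prediction"], dtype=float),
        adversarial_prediction=np.asarray(d["adversarial_prediction"], dtype=float),
        original_label=_label_from_json(d["original_label"]),
        adversarial_label=_label_from_json(d["adversarial_label"]),
        iterations_used=d["iterations_used"],
        best_fitness_trace=list(d["best_fitness_trace"]),
    )


def campaign_to_dict(campaign: CampaignResult) -> dict:
    cfg = dataclasses.asdict(campaign.config)
    if isinstance(cfg.get("target"), np.ndarray):
        cfg["target"] = [int(v) for v in cfg["target"]]
    return {
        "config": cfg,
        "class_names": list(campaign.class_names),
        "trials": campaign.trials,
        "excluded": campaign.excluded,
        "matrix": {
            "origin_classes": list(campaign.matrix.origin_classes),
            "adv_classes": list(campaign.matrix.adv_classes),
            "counts": campaign.matrix.counts.tolist(),
        },
        "records": [
            {
                "class_name": r.class_name,
                "image_index": r.image_index,
                "seed": r.seed,
                "result": _result_to_dict(r.result),
            }
            for r in campaign.records
        ],
    }


def campaign_from_dict(d: dict) -> CampaignResult:
    cfg = dict(d["config"])
    if isinstance(cfg.get("target"), list):
        cfg["target"] = np.asarray(cfg["target"], dtype=int)
    return CampaignResult(
        records=[
            CampaignRecord(
                class_name=r["class_name"],
                image_index=r["image_index"],
                seed=r["seed"],
                result=_result_from_dict(r["result"]),
            )
            for r in d["records"]
        ],
        matrix=TransformationMatrix(
            tuple(d["matrix"]["origin_classes"]),
            tuple(d["matrix"]["adv_classes"]),
            np.asarray(d["matrix"]["counts"], dtype=int),
        ),
        trials=dict(d["trials"]),
        excluded=dict(d["excluded"]),
        config=AttackConfig(**cfg),
        class_names=tuple(d["class_names"]),
    )


def write_results(
    campaign: CampaignResult,
    outdir: str | Path,
    disease_map: dict[str, str] | None = None,
    images: list[np.ndarray] | None = None,
) -> dict[str, Path]:
    """Serialize a campaign: results.json, matrix.csv, tables.csv, adv PNGs.

    ``tables.csv`` stacks the per-class success rates and the per-class
    transformation ratios, plus the disease-type conversion summary when a
    *disease_map* is supplied.  If the original *images* are passed, one PNG
    per successful attack is written with the edited pixel coordinates in
    the filename.  JSON output is key-sorted so identical campaigns are
    byte-identical on disk.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    results_path = outdir / "results.json"
    results_path.write_text(
        json.dumps(campaign_to_dict(campaign), indent=2, sort_keys=True) + "\n"
    )
    paths["results"] = results_path

    matrix_path = outdir / "matrix.csv"
    campaign.matrix.to_dataframe().to_csv(matrix_path)
    paths["matrix"] = matrix_path

    rows: list[dict] = []
    for name, rate in sorted(campaign.success_rates().items()):
        rows.append({"table": "success_rate", "class": name, "value": rate})
    if len(campaign.matrix.origin_classes) >= 2:
        for name, ratio in transformation_ratio(campaign.matrix).items():
            rows.append({"table": "transform_ratio", "class": name, "value": ratio})
    if disease_map is not None:
        summary = conversion_summary(campaign.matrix, disease_map)
        rows.append(
            {
                "table": "conversion",
                "class": "Disease to Normal",
                "value": summary.disease_to_normal,
            }
        )
        rows.append(
            {
                "table": "conversion",
                "class": "Normal to Disease",
                "value": summary.normal_to_disease,
            }
        )
    tables_path = outdir / "tables.csv"
    pd.DataFrame(rows, columns=["table", "class", "value"]).to_csv(
        tables_path, index=False
    )
    paths["tables"] = tables_path

    if images is not None:
        from .core import apply_perturbation

        for k, rec in enumerate(campaign.records):
            if not rec.result.success or rec.result.gene is None:
                continue
            adv = apply_perturbation(images[rec.image_index], rec.result.gene)
            coords = "_".join(
                f"x{int(e[0])}y{int(e[1])}" for e in rec.result.gene.edits
            )
            name = rec.class_name.replace(", ", "+").replace(" ", "-")
            png = outdir / f"adv_{k:04d}_{name}_{coords}.png"
            write_image(adv, png)
            paths[f"adv_{k}"] = png
    return paths


def load_results(path: str | Path) -> CampaignResult:
    """Read a ``results.json`` back into a :class:`CampaignResult`."""
    return campaign_from_dict(json.loads(Path(path).read_text()))
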