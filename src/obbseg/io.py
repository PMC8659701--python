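"""Annotation / prediction serialization.

The on-disk dialect is COCO-style JSON with a rotated-box field:

* ``categories``: ``[{"id": int, "name": str}, ...]`` (nine bone-like classes)
* ``images``: ``[{"id", "file_name", "width", "height", "split"}, ...]``
* ``annotations``: ``[{"id", "image_id", "category_id",
  "rbbox": [xc, yc, w, h, theta_degrees], "segmentation": {"size": [h, w],
  "counts": [...]}, "area", ("score")}, ...]``

``segmentation`` is an uncompressed run-length encoding in column-major
(Fortran) order, counts alternating runs of 0s and 1s and starting with a
run of 0s.  Angles are stored in degrees in [-90, 90); geometry in memory is
radians.  Images are 8-bit PNG, grayscale replicated to three channels.
"""

from __future__ import annotations

import json
import math
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .geometry import OrientedBox
from .synth import CATEGORY_NAMES, GeneratedExample


def rle_encode(mask: np.ndarray) -> dict:
    """Uncompressed column-major RLE of a binary mask."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    flat = mask.flatten(order="F").astype(np.int8)
    if flat.size == 0:
        return {"size": [h, w], "counts": []}
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate([[0], change, [flat.size]])
    counts = np.diff(bounds).tolist()
    if flat[0] == 1:  # counts must start with a zero-run
        counts = [0] + counts
    return {"size": [h, w], "counts": counts}


def rle_decode(rle: dict) -> np.ndarray:
    h, w = rle["size"]
    flat = np.zeros(h * w, dtype=bool)
    pos = 0
    val = False
    for c in rle["counts"]:
        if val:
            flat[pos:pos + c] = True
        pos += c
        val = not val
    return flat.reshape((h, w), order="F")


def obb_to_rbbox(b: OrientedBox) -> list[float]:
    bc = b.canonical()
    return [float(bc.xc), float(bc.yc), float(bc.wr), float(bc.hr),
            float(math.degrees(bc.theta))]


def rbbox_to_obb(rbbox: list[float]) -> OrientedBox:
    xc, yc, w, h, deg = rbbox
    return OrientedBox(xc, yc, w, h, math.radians(deg)).canonical()


def image_to_uint8_rgb(img: np.ndarray) -> np.ndarray:
    """Float [0,1] grayscale -> 8-bit 3-channel (radiograph-as-RGB input)."""
    u8 = np.clip(np.asarray(img) * 255.0, 0, 255).astype(np.uint8)
    if u8.ndim == 2:
        u8 = np.repeat(u8[:, :, None], 3, axis=2)
    return u8


def write_dataset(examples: list[GeneratedExample], outdir: str | Path,
                  manifest_extra: dict | None = None) -> dict:
    """Write PNGs plus one annotation JSON per split; returns the manifest."""
    outdir = Path(outdir)
    (outdir / "images").mkdir(parents=True, exist_ok=True)
    categories = [{"id": i, "name": n} for i, n in enumerate(CATEGORY_NAMES)]
    per_split: dict[str, dict] = {}
    ann_id = 0
    for img_id, ex in enumerate(examples):
        split = ex.split or "train"
        doc = per_split.setdefault(split, {
            "categories": categories, "images": [], "annotations": []})
        fname = f"scene_{img_id:05d}.png"
        iio.imwrite(outdir / "images" / fname, image_to_uint8_rgb(ex.image))
        h, w = ex.image.shape[:2]
        doc["images"].append({"id": img_id, "file_name": f"images/{fname}",
                              "width": w, "height": h, "split": split})
        for a in ex.annotations:
            doc["annotations"].append({
                "id": ann_id, "image_id": img_id, "category_id": a.category,
                "rbbox": obb_to_rbbox(a.obb),
                "segmentation": rle_encode(a.mask),
                "area": int(np.count_nonzero(a.mask)),
            })
            ann_id += 1
    for split, doc in per_split.items():
        with open(outdir / f"annotations_{split}.json", "w") as fh:
            json.dump(doc, fh)
    manifest = {
        "n_examples": len(examples),
        "splits": {s: len(d["images"]) for s, d in sorted(per_split.items())},
        "categories": list(CATEGORY_NAMES),
    }
    if manifest_extra:
        manifest.update(manifest_extra)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_annotations(path: str | Path) -> dict:
    """Load an annotation/prediction JSON; decodes masks and rotated boxes.

    Returns ``{"categories": [...], "images": {id: meta},
    "by_image": {id: [record, ...]}}`` where each record carries ``category``,
    ``obb``, ``mask`` and optionally ``score``.
    """
    with open(path) as fh:
        doc = json.load(fh)
    images = {im["id"]: im for im in doc["images"]}
    by_image: dict[int, list[dict]] = {im_id: [] for im_id in images}
    for ann in doc["annotations"]:
        rec = {
            "category": ann["category_id"],
            "obb": rbbox_to_obb(ann["rbbox"]),
            "mask": rle_decode(ann["segmentation"]),
        }
        if "score" in ann:
            rec["score"] = float(ann["score"])
        by_image[ann["image_id"]].append(rec)
    return {"categories": [c["name"] for c in doc["categories"]],
            "images": images, "by_image": by_image}


def read_image(path: str | Path) -> np.ndarray:
    """Load a PNG as float [0,1] grayscale."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return (arr / 255.0).astype(np.float32)


def write_predictions(records: list[dict], categories: list[str],
                      images: list[dict], path: str | Path) -> None:
    """Write detector+segmenter outputs in the annotation dialect with scores.

    Each record: ``{"image_id", "category", "score", "obb", "mask"}``.
    """
    doc = {
        "categories": [{"id": i, "name": n} for i, n in enumerate(categories)],
        "images": images,
        "annotations": [],
    }
    for i, r in enumerate(records):
        doc["annotations"].append({
            "id": i, "image_id": r["image_id"], "category_id": r["category"],
            "score": float(r["score"]), "rbbox": obb_to_rbbox(r["obb"]),
            "segmentation": rle_encode(r["mask"]),
            "area": int(np.count_nonzero(r["mask"])),
        })
    with open(path, "w") as fh:
        json.dump(doc, fh)
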