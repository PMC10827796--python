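"""Dataset and prediction I/O.

On disk a dataset is a directory of 8-bit grayscale PNGs plus one
``annotations.json``:

    [{"file": "AB_0000.png", "label": "AB",
      "lesions": [{"class": "AB", "bbox": [x0, y0, x1, y1],
                   "mask_file": "AB_0000_mask0.png"}]}, ...]

Boxes are 0-based and half-open with x rightward and y downward; masks are
0/255 PNGs of the image size.  Round-trips are stable up to 8-bit image
quantization (masks and boxes exactly).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image

from .heads import Diagnosis
from .phantom import Lesion, RadiographSample, tight_bbox

__all__ = ["write_dataset", "read_dataset", "write_prediction", "read_annotations"]


def _save_gray(path: Path, arr: np.ndarray) -> None:
    arr8 = np.clip(np.asarray(arr, np.float32) * 255.0 + 0.5, 0, 255).astype(np.uint8)
    Image.fromarray(arr8, mode="L").save(path)


def _load_gray(path: Path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L"), np.float32) / 255.0


def write_dataset(samples, out_dir, manifest: dict | None = None) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for i, s in enumerate(samples):
        stem = s.meta.get("id", f"sample_{i:04d}")
        fname = f"{stem}.png"
        _save_gray(out_dir / fname, s.image)
        lesions = []
        for j, lesion in enumerate(s.lesions):
            mname = f"{stem}_mask{j}.png"
            Image.fromarray((lesion.mask * np.uint8(255)), mode="L") \
                 .save(out_dir / mname)
            lesions.append({"class": lesion.cls, "bbox": list(lesion.bbox),
                            "mask_file": mname})
        records.append({"file": fname, "label": s.label, "lesions": lesions,
                        "provenance": s.provenance})
    with open(out_dir / "annotations.json", "w") as fh:
        json.dump(records, fh, indent=1)
    if manifest is not None:
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)
    return out_dir


def read_annotations(path) -> list[dict]:
    path = Path(path)
    with open(path if path.name.endswith(".json") else path / "annotations.json") as fh:
        records = json.load(fh)
    for rec in records:
        for key in ("file", "label", "lesions"):
            if key not in rec:
                raise ValueError(f"annotation record missing field {key!r}: {rec}")
    return records


def read_dataset(in_dir) -> list[RadiographSample]:
    in_dir = Path(in_dir)
    records = read_annotations(in_dir)
    samples = []
    for rec in records:
        img_path = in_dir / rec["file"]
        if not img_path.exists():
            raise FileNotFoundError(f"missing image file {img_path}")
        img = _load_gray(img_path)
        h, w = img.shape
        lesions = []
        for lrec in rec["lesions"]:
            mpath = in_dir / lrec["mask_file"]
            if not mpath.exists():
                raise FileNotFoundError(f"missing mask file {mpath}")
            with Image.open(mpath) as im:
                mask = np.asarray(im.convert("L")) > 127
            x0, y0, x1, y1 = lrec["bbox"]
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ValueError(f"bbox {lrec['bbox']} outside image bounds "
                                 f"({w}x{h}) in {rec['file']}")
            if tuple(lrec["bbox"]) != tight_bbox(mask):
                raise ValueError(f"bbox is not tight for mask {lrec['mask_file']}")
            lesions.append(Lesion(mask=mask, bbox=tuple(lrec["bbox"]),
                                  cls=lrec["class"]))
        samples.append(RadiographSample(
            image=img.astype(np.float32), label=rec["label"], lesions=lesions,
            provenance=rec.get("provenance", "real"),
            meta={"id": Path(rec["file"]).stem}).validate())
    return samples


def write_prediction(diag: Diagnosis, out_dir, stem: str) -> dict:
    """Exports one prediction: JSON record + heatmap and segmentation PNGs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    heat_file = f"{stem}_heatmap.png"
    seg_file = f"{stem}_seg.png"
    _save_gray(out_dir / heat_file, diag.heatmap)
    Image.fromarray(diag.segmentation.astype(np.uint8) * 255, mode="L") \
         .save(out_dir / seg_file)
    record = {"label": diag.label, "scores": diag.class_scores,
              "heatmap_file": heat_file, "segmentation_file": seg_file,
              "heatmap_ignorable": diag.heatmap_ignorable}
    with open(out_dir / f"{stem}_prediction.json", "w") as fh:
        json.dump(record, fh, indent=1)
    return record
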