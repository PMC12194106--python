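"""Dataset persistence: paired image/mask PNG files plus a JSON manifest.

Masks are stored as 8-bit PNGs with 0/255 semantics and coerced back to
{0,1} on load. Real annotated data laid out the same way (image_*.png /
mask_*.png) loads through the same path.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
from PIL import Image

from .synthetic import SyntheticSample

__all__ = ["save_dataset", "load_dataset"]


def save_dataset(samples, root) -> Path:
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    manifest = []
    for i, s in enumerate(samples):
        img_name, mask_name = f"image_{i:05d}.png", f"mask_{i:05d}.png"
        Image.fromarray(s.image).save(root / img_name)
        Image.fromarray((s.mask.astype(np.uint8) * 255)).save(root / mask_name)
        manifest.append({
            "image": img_name,
            "mask": mask_name,
            "class_id": int(s.class_id),
            "provenance": _jsonable(s.provenance),
        })
    (root / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return root


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def load_dataset(root) -> list:
    """Load paired samples; skips (with a warning) images lacking a mask."""
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory {root} does not exist")
    manifest_path = root / "manifest.json"
    if manifest_path.exists():
        entries = json.loads(manifest_path.read_text())
    else:
        entries = []
        for img in sorted(root.glob("image_*.png")) + sorted(root.glob("image_*.jpg")):
            mask = img.with_name(img.name.replace("image_", "mask_"))
            entries.append({"image": img.name, "mask": mask.name,
                            "class_id": 0, "provenance": {}})
    if not entries:
        raise FileNotFoundError(f"no samples found under {root}")

    samples = []
    for e in entries:
        img_path, mask_path = root / e["image"], root / e["mask"]
        if not mask_path.exists():
            warnings.warn(f"skipping {e['image']}: mask {e['mask']} missing")
            continue
        if not img_path.exists():
            warnings.warn(f"skipping pair: image {e['image']} missing")
            continue
        image = np.asarray(Image.open(img_path).convert("RGB"))
        mask = np.asarray(Image.open(mask_path).convert("L"))
        mask = (mask > 127).astype(np.uint8) if mask.max() > 1 else mask.astype(np.uint8)
        if image.shape[:2] != mask.shape:
            warnings.warn(f"skipping {e['image']}: image/mask size mismatch")
            continue
        samples.append(SyntheticSample(image=image, mask=mask,
                                       class_id=int(e.get("class_id", 0)),
                                       provenance=e.get("provenance", {})))
    if not samples:
        raise FileNotFoundError(f"no valid image/mask pairs under {root}")
    return samples
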