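"""Procedural field-scene generator with exact pixel masks.

Emulates the properties that make field rice-pest segmentation hard:
multi-scale pests (from a few pixels to a quarter of the frame), elongated
bodies with thin leg/antenna polylines, pests whose luminance nearly
matches the background (low-contrast mode), cluttered vegetation textures,
partial occlusion, and class imbalance. Pests are rasterized with
scikit-image draw primitives, so the ground-truth mask is *exactly* the set
of drawn pest pixels — no annotation noise.

Class identity maps to a shape family (capsule / segmented / winged
silhouette), giving per-class APs a meaning in evaluation. Also provides
the preprocessing pipeline (random 640x640 crop, resize to 256x256 with a
nearest-neighbour mask) and augmentation that can emit 14 distinct variants
per source image for balancing small classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as _ellipse
from skimage.draw import line as _line
from skimage.transform import resize as _resize

from .config import ConfigurationError, SceneParams

__all__ = [
    "SyntheticSample", "generate_pest_scene", "augment_sample",
    "augment_variants", "preprocess", "build_dataset",
]

SHAPE_FAMILIES = ("capsule", "segmented", "winged")


@dataclass
class SyntheticSample:
    """One image/mask pair with its generation lineage."""

    image: np.ndarray          # (H, W, 3) uint8 RGB
    mask: np.ndarray           # (H, W) uint8 in {0, 1}
    class_id: int = 0
    provenance: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Background textures
# ---------------------------------------------------------------------------

def _value_noise(rng, size, octaves=4):
    """Multi-octave value noise in [0, 1]."""
    out = np.zeros((size, size), dtype=np.float64)
    amp, total = 1.0, 0.0
    for o in range(octaves):
        cells = max(2, 2 ** (o + 2))
        grid = rng.random((cells, cells))
        out += amp * _resize(grid, (size, size), order=3, mode="reflect",
                             anti_aliasing=False)
        total += amp
        amp *= 0.55
    out /= total
    lo, hi = out.min(), out.max()
    return (out - lo) / max(hi - lo, 1e-9)


def _stripe_field(rng, size, n_fields=1):
    """Oriented sinusoidal stripes (leaf veins / blades)."""
    yy, xx = np.mgrid[0:size, 0:size].astype(np.float64)
    out = np.zeros((size, size))
    for _ in range(n_fields):
        theta = rng.uniform(0, np.pi)
        freq = rng.uniform(4, 14) / size
        phase = rng.uniform(0, 2 * np.pi)
        warp = _value_noise(rng, size, octaves=3) * rng.uniform(2, 8)
        proj = xx * np.cos(theta) + yy * np.sin(theta) + warp
        out += 0.5 * (1 + np.sin(2 * np.pi * freq * proj + phase))
    return out / n_fields


def _background(rng, size, style):
    noise = _value_noise(rng, size)
    if style == "leaf_stripes":
        stripes = _stripe_field(rng, size)
        lum = 0.35 + 0.45 * (0.6 * stripes + 0.4 * noise)
        base = np.stack([0.45 * lum, lum, 0.35 * lum], axis=-1)
    elif style == "soil_texture":
        lum = 0.25 + 0.5 * noise
        base = np.stack([lum, 0.75 * lum, 0.5 * lum], axis=-1)
    else:  # clutter: overlapping stripe fields + blotches
        stripes = _stripe_field(rng, size, n_fields=3)
        lum = 0.3 + 0.5 * (0.5 * stripes + 0.5 * noise)
        base = np.stack([0.55 * lum, 0.9 * lum, 0.4 * lum], axis=-1)
    grain = rng.normal(0, 0.02, size=base.shape)
    return np.clip(base + grain, 0, 1)


# ---------------------------------------------------------------------------
# Pest rasterization
# ---------------------------------------------------------------------------

def _draw_ellipse(mask, cy, cx, ra, rb, rot):
    rr, cc = _ellipse(cy, cx, max(ra, 1.0), max(rb, 1.0), shape=mask.shape,
                     rotation=rot)
    mask[rr, cc] = True


def _draw_polyline(mask, start, angle, length, rng, width=1):
    """A thin bent polyline (leg or antenna) of 2-3 segments."""
    y, x = start
    seg = max(2, int(length / rng.integers(2, 4)))
    remaining = length
    while remaining > 0:
        step = min(seg, remaining)
        ny = y + step * np.sin(angle)
        nx = x + step * np.cos(angle)
        y0, x0 = int(round(y)), int(round(x))
        y1, x1 = int(round(ny)), int(round(nx))
        h, w = mask.shape
        y0, y1 = np.clip([y0, y1], 0, h - 1)
        x0, x1 = np.clip([x0, x1], 0, w - 1)
        rr, cc = _line(y0, x0, y1, x1)
        mask[rr, cc] = True
        if width > 1:
            rr2 = np.clip(rr + 1, 0, h - 1)
            mask[rr2, cc] = True
        y, x = ny, nx
        angle += rng.uniform(-0.6, 0.6)
        remaining -= step


def _pest_mask(rng, size, scale, aspect, n_appendages, family):
    """Rasterize one pest; returns its boolean mask."""
    mask = np.zeros((size, size), dtype=bool)
    a = max(1.5, scale * size / 2.0)          # semi-major axis
    b = max(1.0, a / aspect)                  # semi-minor axis
    rot = rng.uniform(0, np.pi)
    margin = int(np.ceil(a)) + 2
    cy = rng.uniform(margin, size - margin) if size > 2 * margin else size / 2
    cx = rng.uniform(margin, size - margin) if size > 2 * margin else size / 2

    if family == "capsule":
        _draw_ellipse(mask, cy, cx, a, b, rot)
    elif family == "segmented":
        for k in (-0.6, 0.0, 0.6):            # chain of overlapping segments
            oy = cy + k * a * np.sin(rot + np.pi / 2)
            ox = cx + k * a * np.cos(rot + np.pi / 2)
            _draw_ellipse(mask, oy, ox, 0.55 * a, b, rot)
    else:  # winged: body + two slanted wings
        _draw_ellipse(mask, cy, cx, a, b, rot)
        for sgn in (-1, 1):
            wy = cy + sgn * b * 1.2 * np.cos(rot)
            wx = cx - sgn * b * 1.2 * np.sin(rot)
            _draw_ellipse(mask, wy, wx, 0.8 * a, 0.5 * b, rot + sgn * 0.4)

    axis = rot + np.pi / 2
    length = max(2, int(a * rng.uniform(0.6, 1.2)))
    width = 1 if a < 12 else 2
    for _ in range(int(n_appendages)):
        t = rng.uniform(-1, 1)
        sy = cy + t * a * np.sin(axis)
        sx = cx + t * a * np.cos(axis)
        _draw_polyline(mask, (sy, sx), rng.uniform(0, 2 * np.pi), length, rng,
                       width=width)
    return mask


def _pest_color(rng, bg, mask, contrast_level):
    """Pick an RGB pest color; in low-contrast mode stay within +-10% of the
    local background luminance."""
    local = bg[mask].mean(axis=0) if mask.any() else bg.mean(axis=(0, 1))
    local_lum = float(local @ (0.299, 0.587, 0.114))
    if contrast_level == "low":
        lum = local_lum * rng.uniform(0.9, 1.1)
        tint = rng.uniform(0.9, 1.1, size=3)
    else:
        lum = np.clip(local_lum + rng.choice((-1, 1)) * rng.uniform(0.25, 0.45),
                      0.05, 0.95)
        tint = rng.uniform(0.7, 1.3, size=3)
    color = np.clip(lum * tint, 0, 1)
    return color


def generate_pest_scene(params: SceneParams, rng=None,
                        class_id: int = 0) -> SyntheticSample:
    """Render one field scene with its exact binary pest mask.

    A fixed ``params.seed`` (with ``rng=None``) makes the output a pure
    function of the parameters.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    size = params.canvas_size
    bg = _background(rng, size, params.background_style)
    image = bg.copy()
    mask = np.zeros((size, size), dtype=bool)

    family = SHAPE_FAMILIES[class_id % len(SHAPE_FAMILIES)]
    n_pests = int(rng.integers(params.n_pests[0], params.n_pests[1] + 1))
    lo, hi = params.pest_scale_range
    for _ in range(n_pests):
        scale = float(rng.uniform(lo, hi))
        aspect = float(rng.uniform(*params.body_aspect_range))
        n_app = int(rng.integers(params.n_appendages[0],
                                 params.n_appendages[1] + 1))
        pm = _pest_mask(rng, size, scale, aspect, n_app, family)
        if params.occlusion_prob > 0 and rng.random() < params.occlusion_prob:
            # a band of vegetation hides part of the pest: those pixels are
            # neither drawn nor labelled
            band = np.zeros_like(pm)
            y0 = int(rng.uniform(0, size))
            h = max(1, int(0.15 * size))
            band[y0:y0 + h] = True
            pm &= ~band
        color = _pest_color(rng, bg, pm, params.contrast_level)
        speck = rng.normal(0, 0.03, size=(int(pm.sum()), 3))
        image[pm] = np.clip(color + speck, 0, 1)
        mask |= pm

    return SyntheticSample(
        image=(image * 255).astype(np.uint8),
        mask=mask.astype(np.uint8),
        class_id=class_id,
        provenance={"params": params.__dict__.copy(), "class_id": class_id,
                    "ops": []},
    )


# ---------------------------------------------------------------------------
# Augmentation and preprocessing
# ---------------------------------------------------------------------------

def _apply_rigid(sample: SyntheticSample, k_rot: int, flip: bool):
    img, msk = sample.image, sample.mask
    if k_rot:
        img, msk = np.rot90(img, k_rot, axes=(0, 1)), np.rot90(msk, k_rot)
    if flip:
        img, msk = img[:, ::-1], msk[:, ::-1]
    return np.ascontiguousarray(img), np.ascontiguousarray(msk)


def _with_ops(sample, image, mask, ops):
    prov = dict(sample.provenance)
    prov["ops"] = list(prov.get("ops", [])) + ops
    return SyntheticSample(image=image, mask=mask, class_id=sample.class_id,
                           provenance=prov)


def augment_sample(sample: SyntheticSample, rng) -> SyntheticSample:
    """One random flip/rotation/brightness variant (mask kept aligned)."""
    k = int(rng.integers(0, 4))
    flip = bool(rng.integers(0, 2))
    img, msk = _apply_rigid(sample, k, flip)
    ops = [f"rot90x{k}", f"hflip={flip}"]
    if rng.random() < 0.5:
        factor = float(rng.uniform(0.7, 1.3))
        img = np.clip(img.astype(np.float32) * factor, 0, 255).astype(np.uint8)
        ops.append(f"brightness={factor:.3f}")
    return _with_ops(sample, img, msk, ops)


def augment_variants(sample: SyntheticSample, n: int = 14,
                     seed: int = 0) -> list:
    """``n`` distinct variants of one source image (default 14).

    The first seven are the non-identity rigid transforms (three rotations,
    and the four flipped orientations), which conserve mask area exactly;
    the remainder add brightness jitter on top of rigid transforms.
    """
    rng = np.random.default_rng(seed)
    rigid = [(k, f) for f in (False, True) for k in range(4)][1:]  # skip identity
    out = []
    for i in range(n):
        k, f = rigid[i % len(rigid)]
        img, msk = _apply_rigid(sample, k, f)
        ops = [f"rot90x{k}", f"hflip={f}"]
        if i >= len(rigid):
            factor = float(rng.uniform(0.7, 1.3))
            img = np.clip(img.astype(np.float32) * factor, 0, 255).astype(np.uint8)
            ops.append(f"brightness={factor:.3f}")
        out.append(_with_ops(sample, img, msk, ops + [f"variant={i}"]))
    return out


def preprocess(sample: SyntheticSample, target_size: int = 256,
               crop_size: int = 640, rng=None) -> SyntheticSample:
    """Random ``crop_size`` square crop, then resize to ``target_size``.

    The image is resized with bilinear interpolation, the mask with
    nearest-neighbour so it stays strictly binary.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    img, msk = sample.image, sample.mask
    h, w = msk.shape
    if h < crop_size or w < crop_size:
        if h < target_size or w < target_size:
            raise ValueError(
                f"sample {h}x{w} smaller than target {target_size}")
        crop = min(h, w)
    else:
        crop = crop_size
    y0 = int(rng.integers(0, h - crop + 1))
    x0 = int(rng.integers(0, w - crop + 1))
    img = img[y0:y0 + crop, x0:x0 + crop]
    msk = msk[y0:y0 + crop, x0:x0 + crop]
    img_r = _resize(img, (target_size, target_size), order=1,
                    preserve_range=True, anti_aliasing=True).astype(np.uint8)
    msk_r = _resize(msk, (target_size, target_size), order=0,
                    preserve_range=True, anti_aliasing=False).astype(np.uint8)
    return _with_ops(sample, img_r, msk_r,
                     [f"crop=({y0},{x0},{crop})", f"resize={target_size}"])


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------

_CLASS_STYLES = ("leaf_stripes", "soil_texture", "clutter")


def class_scene_params(base: SceneParams, class_id: int) -> SceneParams:
    """Deterministic per-class conditions: background style cycles through
    the three textures and every fourth class is low-contrast."""
    return base.replace(
        background_style=_CLASS_STYLES[class_id % len(_CLASS_STYLES)],
        contrast_level="low" if class_id % 4 == 3 else base.contrast_level,
    )


def build_dataset(n_per_class, seed: int, base_params: "SceneParams | None" = None,
                  balance_to: "int | None" = None) -> list:
    """Generate a multi-class dataset of :class:`SyntheticSample`.

    ``n_per_class[c]`` scenes are rendered for class ``c``; when
    ``balance_to`` is set, under-represented classes are topped up with
    augmented variants of their own scenes (mirroring augmentation-based
    class balancing).
    """
    if len(n_per_class) == 0:
        raise ConfigurationError("n_per_class must be nonempty")
    base = base_params or SceneParams()
    ss = np.random.SeedSequence(seed)
    class_seeds = ss.spawn(len(n_per_class))
    samples = []
    for cls, (count, cseed) in enumerate(zip(n_per_class, class_seeds)):
        rng = np.random.default_rng(cseed)
        params = class_scene_params(base, cls)
        originals = [generate_pest_scene(params, rng=rng, class_id=cls)
                     for _ in range(count)]
        samples.extend(originals)
        if balance_to is not None and count < balance_to:
            need = balance_to - count
            arng = np.random.default_rng(cseed.spawn(1)[0])
            for i in range(need):
                samples.append(augment_sample(originals[i % len(originals)], arng))
    return samples
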