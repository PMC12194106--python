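"""Scene generator: determinism, geometry bounds, augmentation, pipeline."""

import numpy as np
import pytest

from catransunet import (SceneParams, augment_sample, augment_variants,
                         build_dataset, generate_pest_scene, preprocess)
from catransunet.config import ConfigurationError


def test_fixed_seed_is_bitwise_deterministic():
    p = SceneParams(canvas_size=96, seed=42)
    a, b = generate_pest_scene(p), generate_pest_scene(p)
    assert np.array_equal(a.image, b.image) and np.array_equal(a.mask, b.mask)


def test_no_pests_means_empty_mask():
    p = SceneParams(canvas_size=96, n_pests=(0, 0), seed=1)
    s = generate_pest_scene(p)
    assert s.mask.sum() == 0
    assert s.image.shape == (96, 96, 3)


def test_single_capsule_area_within_geometric_bounds():
    """A 0.2-scale capsule body is an ellipse with semi-axes a=0.1*S and
    a/aspect, aspect in [1.5,4]; with thin appendages the foreground
    fraction must stay inside a loose analytic band around pi*a*b/S^2."""
    p = SceneParams(canvas_size=320, n_pests=(1, 1),
                    pest_scale_range=(0.2, 0.2), occlusion_prob=0.0, seed=0)
    fracs = []
    for seed in range(8):
        s = generate_pest_scene(p.replace(seed=seed), class_id=0)
        fracs.append(s.mask.mean())
    a = 0.1 * 320
    lo = np.pi * a * (a / 4.0) / 320 ** 2 * 0.8          # slimmest body
    hi = np.pi * a * (a / 1.5) / 320 ** 2 * 1.8          # fattest + appendages
    assert all(lo < f < hi for f in fracs), fracs


def test_masks_only_where_pest_pixels_were_drawn():
    """Image differs from the pest-free render exactly on mask pixels."""
    p = SceneParams(canvas_size=96, seed=5, occlusion_prob=0.0)
    s = generate_pest_scene(p)
    bare = generate_pest_scene(p.replace(n_pests=(0, 0)))
    changed = np.any(s.image != bare.image, axis=-1)
    mask = s.mask.astype(bool)
    assert not np.any(changed & ~mask)          # nothing changes off-mask
    # nearly every mask pixel visibly differs (a few may quantize equal)
    assert (changed & mask).sum() > 0.9 * mask.sum()


def test_double_flip_is_identity():
    s = generate_pest_scene(SceneParams(canvas_size=64, seed=3))
    r = np.random.default_rng(0)

    class FixedRng:  # force a pure horizontal flip
        def integers(self, lo, hi):
            return {4: 0, 2: 1}[hi]

        def random(self):
            return 1.0

    f1 = augment_sample(s, FixedRng())
    f2 = augment_sample(f1, FixedRng())
    assert np.array_equal(f2.image, s.image) and np.array_equal(f2.mask, s.mask)
    assert f2.provenance["ops"] != s.provenance.get("ops")


def test_rotations_conserve_mask_area():
    s = generate_pest_scene(SceneParams(canvas_size=64, seed=7))
    for v in augment_variants(s, n=7):
        assert v.mask.sum() == s.mask.sum()


def test_fourteen_variants_are_distinct_with_lineage():
    s = generate_pest_scene(SceneParams(canvas_size=64, seed=9))
    variants = augment_variants(s, n=14)
    assert len(variants) == 14
    provs = [tuple(v.provenance["ops"]) for v in variants]
    assert len(set(provs)) == 14
    payloads = {v.image.tobytes() for v in variants}
    assert len(payloads) >= 7   # rigid transforms are all distinct


def test_preprocess_crops_and_resizes_with_binary_mask():
    big = generate_pest_scene(SceneParams(canvas_size=800, seed=4))
    out = preprocess(big, target_size=256, crop_size=640,
                     rng=np.random.default_rng(1))
    assert out.image.shape == (256, 256, 3)
    assert out.mask.shape == (256, 256)
    assert set(np.unique(out.mask)) <= {0, 1}
    again = preprocess(big, target_size=256, crop_size=640,
                       rng=np.random.default_rng(1))
    assert np.array_equal(out.image, again.image)


def test_preprocess_rejects_too_small_inputs():
    tiny = generate_pest_scene(SceneParams(canvas_size=64, seed=0))
    with pytest.raises(ValueError, match="smaller"):
        preprocess(tiny, target_size=256, crop_size=640)


def test_dataset_counts_classes_and_balancing():
    ds = build_dataset([10, 2], seed=0,
                       base_params=SceneParams(canvas_size=48), balance_to=10)
    by_class = {c: sum(1 for s in ds if s.class_id == c) for c in (0, 1)}
    assert by_class == {0: 10, 1: 10}
    augmented = [s for s in ds if s.class_id == 1 and s.provenance["ops"]]
    assert len(augmented) == 8


def test_dataset_manifest_is_seed_deterministic():
    kw = dict(base_params=SceneParams(canvas_size=48))
    d1 = build_dataset([3, 3], seed=5, **kw)
    d2 = build_dataset([3, 3], seed=5, **kw)
    assert all(np.array_equal(a.image, b.image) for a, b in zip(d1, d2))
    d3 = build_dataset([3, 3], seed=6, **kw)
    assert any(not np.array_equal(a.image, b.image) for a, b in zip(d1, d3))


def test_foreground_fraction_distribution_is_plausible():
    """Across 100 seeded scenes the mean foreground fraction stays within
    the band implied by the configured pest count and scale range."""
    p = SceneParams(canvas_size=96, n_pests=(1, 3),
                    pest_scale_range=(0.05, 0.25), occlusion_prob=0.0)
    fracs = [generate_pest_scene(p.replace(seed=s)).mask.mean()
             for s in range(100)]
    mean = np.mean(fracs)
    assert 0.001 < mean < 0.2
    assert max(fracs) < 0.5


def test_degenerate_params_rejected():
    with pytest.raises(ConfigurationError):
        SceneParams(pest_scale_range=(0.0, 0.2))
    with pytest.raises(ConfigurationError):
        SceneParams(n_pests=(5, 1))
    with pytest.raises(ConfigurationError):
        SceneParams(background_style="checkerboard")
    with pytest.raises(ConfigurationError):
        build_dataset([], seed=0)


def test_low_contrast_pests_stay_near_background_luminance():
    p = SceneParams(canvas_size=128, n_pests=(2, 2), contrast_level="low",
                    pest_scale_range=(0.15, 0.2), occlusion_prob=0.0, seed=2)
    s = generate_pest_scene(p)
    lum = s.image.astype(float) @ np.array([0.299, 0.587, 0.114]) / 255
    fg, bg = lum[s.mask == 1].mean(), lum[s.mask == 0].mean()
    assert abs(fg - bg) < 0.25  # far tighter than the normal-contrast gap
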