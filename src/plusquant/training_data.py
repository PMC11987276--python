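"""Assembling segmenter training patches from cohorts or phantoms."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .preprocess import RawImage, preprocess_image
from .morphometry import skeletonize_mask
from .segmentation import detect_bifurcations, sample_patches


def patches_from_image(img: np.ndarray, mask: np.ndarray, n: int, size: int = 128,
                       seed: int = 0) -> list:
    """Bifurcation-centered patches from one working image + reference mask.

    Falls back to random vessel-pixel centers when too few bifurcations
    survive the border exclusion.
    """
    skel = skeletonize_mask(mask)
    centers = detect_bifurcations(skel)
    half = size // 2
    h, w = mask.shape
    valid = [(r, c) for r, c in centers if half <= r <= h - half and half <= c <= w - half]
    if len(valid) < n:
        rng = np.random.default_rng(seed + 17)
        rows, cols = np.nonzero(skel)
        inside = (rows >= half) & (rows <= h - half) & (cols >= half) & (cols <= w - half)
        rows, cols = rows[inside], cols[inside]
        extra_idx = rng.choice(len(rows), size=min(len(rows), 4 * n), replace=False)
        valid = sorted(set(valid) | {(int(rows[i]), int(cols[i])) for i in extra_idx})
    n = min(n, len(valid))
    return sample_patches(img, mask, valid, n=n, size=size, seed=seed)


def patches_from_phantoms(n_patches: int = 200, n_images: int = 4, size: int = 128,
                          seed: int = 0, base_spec=None) -> list:
    """Generate phantoms, preprocess them and cut training patches."""
    from .phantom import PhantomSpec, generate_phantom, severity_to_spec
    from dataclasses import replace

    base = base_spec or PhantomSpec()
    patches = []
    per_img = int(np.ceil(n_patches / n_images))
    for i in range(n_images):
        theta = 1.0 + 4.0 * i / max(1, n_images - 1)
        spec = replace(severity_to_spec(theta, base), seed=seed * 1009 + i)
        raw, truth = generate_phantom(spec)
        work = preprocess_image(raw)
        patches += patches_from_image(work.pixels, truth.mask, per_img, size=size,
                                      seed=seed * 31 + i)
    return patches[:n_patches]


def patches_from_cohort(cohort_dir: Path, n_patches: int = 200, size: int = 128,
                        seed: int = 0) -> list:
    """Cut patches from every image/mask pair in a cohort directory."""
    from PIL import Image

    cohort = Path(cohort_dir)
    image_paths = sorted((cohort / "images").glob("*.png"))
    if not image_paths:
        raise FileNotFoundError(f"no images under {cohort / 'images'}")
    per_img = int(np.ceil(n_patches / len(image_paths)))
    patches = []
    for i, path in enumerate(image_paths):
        mask_path = cohort / "masks" / path.name
        if not mask_path.exists():
            continue
        raw = RawImage(np.asarray(Image.open(path).convert("RGB")), image_id=path.stem)
        mask = np.asarray(Image.open(mask_path).convert("L")) > 127
        work = preprocess_image(raw)
        patches += patches_from_image(work.pixels, mask, per_img, size=size, seed=seed + i)
    return patches[:n_patches]
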