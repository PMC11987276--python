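"""Bifurcation-centered training-patch extraction.

Patches are cut around vessel bifurcation points of the skeletonized
reference mask — these carry the most informative local geometry — and
split into train/validation sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass
class TrainingPatch:
    image_patch: np.ndarray  # size x size float
    mask_patch: np.ndarray  # size x size {0,1}
    center: tuple  # (row, col)
    source_id: str = ""


_NEIGH = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


def detect_bifurcations(skeleton: np.ndarray) -> list:
    """Skeleton pixels with >= 3 neighbours in 8-connectivity, row-major sorted.

    Requires a 1-px-wide skeleton; a thick mask makes neighbour counts
    meaningless and is rejected.
    """
    skel = np.asarray(skeleton).astype(bool)
    counts = ndimage.convolve(skel.astype(int), _NEIGH, mode="constant")
    if (counts[skel] == 8).any():  # interior pixel => thick region, not a skeleton
        raise ValueError("input is not a 1-px skeleton; skeletonize the mask first")
    rows, cols = np.nonzero(skel & (counts >= 3))
    return sorted(zip(rows.tolist(), cols.tolist()))


def sample_patches(
    img: np.ndarray,
    mask: np.ndarray,
    centers: list,
    n: int,
    size: int = 128,
    seed: int = 0,
) -> list:
    """Sample ``n`` patches of ``size`` centred on ``centers`` without replacement.

    Centers closer than size/2 to the border are excluded first; the patch
    window is half-open, rows ``[r - size//2, r + size//2)``.
    """
    if size % 2 != 0:
        raise ValueError("patch size must be even")
    img = np.asarray(img, dtype=float)
    mask = np.asarray(mask).astype(np.uint8)
    h, w = img.shape
    half = size // 2
    valid = [(r, c) for r, c in centers if half <= r <= h - half and half <= c <= w - half]
    if not valid:
        raise ValueError(
            "no valid patch centers after border exclusion; "
            "fall back to random vessel-pixel centers"
        )
    if n > len(valid):
        raise ValueError(f"requested {n} patches but only {len(valid)} valid centers")
    rng = np.random.default_rng(seed)
    chosen = [valid[i] for i in rng.choice(len(valid), size=n, replace=False)]
    patches = []
    for r, c in chosen:
        sl = (slice(r - half, r + half), slice(c - half, c + half))
        patches.append(TrainingPatch(img[sl].copy(), mask[sl].copy(), (r, c)))
    return patches


def split_patches(patches: list, train_fraction: float = 0.8, seed: int = 0) -> tuple:
    """Disjoint, exhaustive train/validation split (floor rule for train size)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    if len(patches) < 2:
        raise ValueError("need at least 2 patches to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patches))
    n_train = int(np.floor(train_fraction * len(patches)))
    n_train = max(1, min(n_train, len(patches) - 1))
    train = [patches[i] for i in order[:n_train]]
    val = [patches[i] for i in order[n_train:]]
    return train, val
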