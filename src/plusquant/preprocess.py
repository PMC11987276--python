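"""Fundus image preprocessing.

Raw RGB fundus photographs are converted into a single-channel working
image, contrast-enhanced with CLAHE and corrected for the uneven
illumination typical of contact wide-field pediatric imaging.  Every step
records itself in the working image's provenance list so that downstream
outputs can state exactly how their input was produced.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import exposure

log = logging.getLogger(__name__)

_BG_EPS = 1e-3


@dataclass
class RawImage:
    """An 8-bit-per-channel RGB fundus photograph."""

    pixels: np.ndarray  # H x W x 3, uint8-range integers
    image_id: str = ""
    pixel_pitch: float = 1.0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"RawImage expects H x W x 3 pixels, got shape {px.shape}")
        if px.shape[0] < 128 or px.shape[1] < 128:
            raise ValueError("image must be at least 128 x 128 px")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        self.pixels = px


@dataclass
class WorkingImage:
    """Single-channel float image in [0, 1] with a processing provenance."""

    pixels: np.ndarray
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise ValueError("WorkingImage is single-channel (2-D)")
        if not np.all(np.isfinite(px)) or px.min() < 0 or px.max() > 1:
            raise ValueError("pixels must be finite and in [0, 1]")
        self.pixels = px

    @property
    def shape(self) -> tuple:
        return self.pixels.shape


def to_working_channel(raw: RawImage, mode: str = "green") -> WorkingImage:
    """Extract a single working channel from an RGB image, scaled to [0, 1].

    The green channel carries the highest vessel/background contrast in
    fundus photography and is the default.  ``mode`` may be ``"green"``,
    ``"red"``, ``"blue"`` or ``"luma"`` (Rec. 601 luminance).
    """
    channels = {"red": 0, "green": 1, "blue": 2}
    px = np.asarray(raw.pixels, dtype=float)
    if mode in channels:
        chan = px[:, :, channels[mode]]
    elif mode == "luma":
        chan = px @ np.array([0.299, 0.587, 0.114])
    else:
        raise ValueError(f"unknown channel mode {mode!r}")
    return WorkingImage(chan / 255.0, provenance=[{"step": "to_working_channel", "mode": mode}])


def clahe_enhance(
    img: WorkingImage, clip_limit: float = 0.01, tile_grid: tuple = (8, 8)
) -> WorkingImage:
    """Contrast-limited adaptive histogram equalization.

    ``clip_limit`` is the normalized clipping limit and ``tile_grid`` the
    number of contextual tiles per axis.  A constant image has no contrast
    to redistribute and is returned unchanged (with a warning).
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    if min(tile_grid) < 1:
        raise ValueError("tile dimensions must be >= 1")
    px = img.pixels
    entry = {"step": "clahe_enhance", "clip_limit": clip_limit, "tile_grid": tuple(tile_grid)}
    if np.ptp(px) == 0:
        warnings.warn("CLAHE on a constant image is degenerate; returning input unchanged")
        return WorkingImage(px.copy(), provenance=img.provenance + [entry])
    kernel = (
        max(1, px.shape[0] // tile_grid[0]),
        max(1, px.shape[1] // tile_grid[1]),
    )
    out = exposure.equalize_adapthist(px, kernel_size=kernel, clip_limit=clip_limit)
    out = np.clip(out, 0.0, 1.0)
    return WorkingImage(out, provenance=img.provenance + [entry])


def correct_illumination(img: WorkingImage, background_scale: float = 0.25,
                         poly_order: int = 4) -> WorkingImage:
    """Divide out a smooth background field to flatten uneven illumination.

    The multiplicative background is modelled as the exponential of a
    low-order 2-D polynomial fitted to the log of a lightly smoothed copy
    of the image (smoothing scale ``background_scale/8 * min(H, W)``
    suppresses the vessels so they do not drag the fit).  Dividing by the
    fitted surface makes a vignetted constant image approximately flat
    while leaving fine vessel contrast untouched.
    """
    if not 0 < background_scale <= 1:
        raise ValueError("background_scale must be in (0, 1]")
    px = img.pixels
    h, w = px.shape
    sigma = background_scale / 8.0 * min(h, w)
    smooth = ndimage.gaussian_filter(px, sigma=sigma, mode="nearest")
    if smooth.min() < _BG_EPS:
        warnings.warn("near-zero background values clamped during illumination correction")
        smooth = np.maximum(smooth, _BG_EPS)
    # normalized coordinates in [-1, 1] keep the Vandermonde well conditioned
    rr = np.linspace(-1.0, 1.0, h)[:, None] * np.ones((1, w))
    cc = np.ones((h, 1)) * np.linspace(-1.0, 1.0, w)[None, :]
    terms = [
        rr**i * cc**j
        for i in range(poly_order + 1)
        for j in range(poly_order + 1 - i)
    ]
    A = np.stack([t.ravel() for t in terms], axis=1)
    coef, *_ = np.linalg.lstsq(A, np.log(smooth).ravel(), rcond=None)
    background = np.exp((A @ coef).reshape(h, w))
    flat = px / np.maximum(background, _BG_EPS)
    hi = np.percentile(flat, 99.9)
    flat = np.clip(flat / hi if hi > 0 else flat, 0.0, 1.0)
    entry = {"step": "correct_illumination", "background_scale": background_scale,
             "poly_order": poly_order}
    return WorkingImage(flat, provenance=img.provenance + [entry])


def preprocess_image(
    raw: RawImage,
    mode: str = "green",
    clip_limit: float = 0.01,
    tile_grid: tuple = (8, 8),
    background_scale: float = 0.25,
) -> WorkingImage:
    """Full preprocessing chain: channel -> CLAHE -> illumination correction."""
    work = to_working_channel(raw, mode=mode)
    work = clahe_enhance(work, clip_limit=clip_limit, tile_grid=tile_grid)
    return correct_illumination(work, background_scale=background_scale)
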