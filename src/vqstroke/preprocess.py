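"""Classical image preprocessing: resize, grayscale, normalization,
histogram equalization, augmentation, and class-imbalance handling.

Images are plain numpy arrays.  Two value domains are used and tracked by
dtype: integer arrays carry 8-bit-style intensities in [0, 255] (or
[0, levels-1] for equalization), floating arrays carry either unit-range
[0, 1] values (after :func:`normalize`) or real-valued grayscale intensities
(after :func:`to_grayscale`, which is deliberately not quantized).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import DataError, DomainError

__all__ = [
    "resize_bilinear",
    "to_grayscale",
    "normalize",
    "hist_equalize",
    "quantize_uint8",
    "augment",
    "balance_classes",
]

logger = logging.getLogger(__name__)

GRAY_WEIGHTS = (0.2989, 0.5870, 0.1140)  # ITU-R 601 luma coefficients


def resize_bilinear(
    img: np.ndarray,
    target_w: int,
    target_h: int,
    mapping: str = "scale",
) -> np.ndarray:
    """Resize a 2-D image with bilinear interpolation.

    ``mapping`` selects the coordinate map from destination to source pixels:

    - ``"scale"`` (default): ``src = dst * (src_size / dst_size)``, fractional
      coordinates clamped to the source grid.  The identity when sizes match.
    - ``"align_corners"``: ``src = dst * (src_size - 1) / (dst_size - 1)``,
      pinning the four corners exactly (degenerates to coordinate 0 when the
      target has a single row/column).

    Output intensities are convex combinations of the four neighbours, so they
    never leave the source min/max range.
    """
    if target_w < 1 or target_h < 1:
        raise ValueError(f"target size must be positive, got {target_w}x{target_h}")
    if mapping not in ("scale", "align_corners"):
        raise ValueError(f"unknown mapping {mapping!r}")
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    src_h, src_w = img.shape

    def coords(dst_n: int, src_n: int) -> np.ndarray:
        d = np.arange(dst_n, dtype=float)
        if mapping == "scale":
            c = d * (src_n / dst_n)
        else:
            c = d * ((src_n - 1) / (dst_n - 1)) if dst_n > 1 else np.zeros(1)
        return np.clip(c, 0.0, src_n - 1)

    ys = coords(target_h, src_h)
    xs = coords(target_w, src_w)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, src_h - 1)
    x1 = np.minimum(x0 + 1, src_w - 1)
    wy = (ys - y0)[:, None]
    wx = (xs - x0)[None, :]
    top = img[np.ix_(y0, x0)] * (1 - wx) + img[np.ix_(y0, x1)] * wx
    bot = img[np.ix_(y1, x0)] * (1 - wx) + img[np.ix_(y1, x1)] * wx
    return top * (1 - wy) + bot * wy


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Weighted RGB-to-gray conversion, 0.2989 R + 0.5870 G + 0.1140 B.

    Accepts an (H, W, 3) array with channels in [0, 255]; returns a
    real-valued (H, W) array (not quantized — use :func:`quantize_uint8` for
    an 8-bit result).
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    r, g, b = GRAY_WEIGHTS
    return r * img[..., 0] + g * img[..., 1] + b * img[..., 2]


def quantize_uint8(img: np.ndarray) -> np.ndarray:
    """Quantize a real-valued [0, 255] image to uint8, rounding half up."""
    img = np.asarray(img, dtype=float)
    return np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)


def normalize(img: np.ndarray) -> np.ndarray:
    """Scale an 8-bit image to the unit range by dividing by 255.

    Requires an integer-dtype input; a floating input is rejected to prevent
    accidental double scaling.
    """
    img = np.asarray(img)
    if not np.issubdtype(img.dtype, np.integer):
        raise DomainError(
            "normalize expects an integer [0, 255] image; "
            f"got dtype {img.dtype} (already normalized?)"
        )
    if img.min() < 0 or img.max() > 255:
        raise DomainError("integer image has values outside [0, 255]")
    return img.astype(float) / 255.0


def hist_equalize(img: np.ndarray, levels: int = 256) -> np.ndarray:
    """Histogram equalization through the empirical CDF.

    Each intensity ``v`` maps to ``floor(CDF(v) * (levels - 1))`` where CDF is
    the empirical cumulative distribution of intensities over the whole image.
    The map is monotone non-decreasing in input intensity, so pixel ranking is
    preserved; a constant image maps to the top level (CDF = 1 everywhere).
    """
    if levels < 2:
        raise ValueError(f"levels must be >= 2, got {levels}")
    img = np.asarray(img)
    if not np.issubdtype(img.dtype, np.integer):
        raise DomainError("hist_equalize expects integer intensities")
    if img.min() < 0 or img.max() > levels - 1:
        raise DomainError(f"intensities must lie in [0, {levels - 1}]")
    hist = np.bincount(img.ravel(), minlength=levels)
    cdf = np.cumsum(hist) / img.size
    lut = np.floor(cdf * (levels - 1)).astype(img.dtype)
    return lut[img]


def augment(
    img: np.ndarray,
    rotation_degrees: int = 0,
    flip_h: bool = False,
    flip_v: bool = False,
    noise_sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    domain_max: float | None = None,
) -> np.ndarray:
    """Rotate/flip/noise augmentation, applied in that order.

    Rotations are restricted to multiples of 90 degrees so no interpolation is
    involved (pixel multiset preserved); image dimensions swap for 90/270.
    Additive Gaussian noise (std ``noise_sigma``) is clipped to the image
    domain — [0, 255] for integer inputs, [0, 1] for floating inputs unless
    ``domain_max`` overrides it.
    """
    if rotation_degrees not in (0, 90, 180, 270):
        raise ValueError(
            f"rotation_degrees must be one of 0/90/180/270, got {rotation_degrees}"
        )
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    img = np.asarray(img)
    is_int = np.issubdtype(img.dtype, np.integer)
    out = np.rot90(img, k=rotation_degrees // 90)
    if flip_h:
        out = out[:, ::-1]
    if flip_v:
        out = out[::-1, :]
    out = out.copy()
    if noise_sigma > 0:
        if rng is None:
            raise ValueError("noise_sigma > 0 requires an rng")
        hi = domain_max if domain_max is not None else (255.0 if is_int else 1.0)
        noisy = out.astype(float) + rng.normal(0.0, noise_sigma, out.shape)
        noisy = np.clip(noisy, 0.0, hi)
        out = np.rint(noisy).astype(img.dtype) if is_int else noisy
    return out


def balance_classes(
    manifest: pd.DataFrame,
    mode: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Equalize train-split class counts; test rows pass through untouched.

    Modes: ``oversample`` duplicates minority rows uniformly at random with
    replacement until counts match; ``undersample`` drops majority rows
    uniformly without replacement; ``over_then_under`` runs both in sequence —
    after oversampling the classes are already equal, so the undersampling
    stage is a no-op and a warning is logged.
    """
    if mode not in ("oversample", "undersample", "over_then_under"):
        raise ValueError(f"unknown balancing mode {mode!r}")
    train = manifest[manifest["split"] == "train"]
    test = manifest[manifest["split"] != "train"]
    counts = train["label"].value_counts()
    if len(counts) < 2 or counts.min() == 0:
        raise DataError(
            f"train split needs >= 1 sample of each class, got {counts.to_dict()}"
        )

    def _oversample(df: pd.DataFrame) -> pd.DataFrame:
        c = df["label"].value_counts()
        minority = c.idxmin()
        deficit = int(c.max() - c.min())
        if deficit == 0:
            return df
        pool = df[df["label"] == minority]
        extra = pool.iloc[rng.integers(0, len(pool), size=deficit)]
        return pd.concat([df, extra], ignore_index=True)

    def _undersample(df: pd.DataFrame) -> pd.DataFrame:
        c = df["label"].value_counts()
        majority, minority = c.idxmax(), c.idxmin()
        target = int(c.min())
        if c.max() == target:
            return df
        maj = df[df["label"] == majority]
        keep_idx = rng.choice(len(maj), size=target, replace=False)
        keep = maj.iloc[np.sort(keep_idx)]
        rest = df[df["label"] == minority]
        return pd.concat([rest, keep], ignore_index=True)

    if mode == "oversample":
        balanced = _oversample(train)
    elif mode == "undersample":
        balanced = _undersample(train)
    else:
        balanced = _oversample(train)
        before = len(balanced)
        balanced = _undersample(balanced)
        if len(balanced) == before:
            logger.warning(
                "over_then_under: undersampling stage is a no-op after "
                "oversampling already balanced the classes"
            )
    out = pd.concat([balanced, test], ignore_index=True)
    c = out[out["split"] == "train"]["label"].value_counts()
    assert c.nunique() == 1, "balancing postcondition violated"
    return out
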