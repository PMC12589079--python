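"""Classical feature extraction: Canny edges and GLCM texture statistics.

The classifier consumes a 4-dimensional feature vector per image — edge
density plus the three Haralick statistics contrast, energy and correlation of
a symmetric normalized gray-level co-occurrence matrix.  Four features are
used because the quantum register is four qubits wide; the set is configurable
through :class:`FeatureConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import DataError, DomainError

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "canny",
    "glcm",
    "glcm_stats",
    "quantize_levels",
    "extract_feature_vector",
    "extract_features_table",
]

FEATURE_NAMES = ["edge_density", "glcm_contrast", "glcm_energy", "glcm_correlation"]


@dataclass(frozen=True)
class FeatureConfig:
    """Feature-extraction parameters.

    GLCM: ``levels`` gray levels via min-max linear quantization, pair offset
    ``(drow, dcol)``, symmetric and normalized.  Canny: Gaussian ``sigma`` in
    pixels; ``low``/``high`` hysteresis thresholds as fractions of the maximum
    gradient magnitude.
    """

    levels: int = 16
    offset: tuple[int, int] = (0, 1)
    canny_sigma: float = 1.0
    canny_low: float = 0.1
    canny_high: float = 0.3

    def __post_init__(self) -> None:
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.offset == (0, 0):
            raise ValueError("GLCM offset must be nonzero")
        if not 0 <= self.canny_low <= self.canny_high <= 1:
            raise ValueError("require 0 <= low <= high <= 1 for Canny thresholds")


@dataclass(frozen=True)
class FeatureVector:
    edge_density: float
    glcm_contrast: float
    glcm_energy: float
    glcm_correlation: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.edge_density,
                self.glcm_contrast,
                self.glcm_energy,
                self.glcm_correlation,
            ]
        )


def canny(
    img: np.ndarray, sigma: float = 1.0, low: float = 0.1, high: float = 0.3
) -> np.ndarray:
    """Canny edge detector; returns a binary (0/1) edge map.

    Stages: Gaussian smoothing (std ``sigma``), Sobel gradients, non-maximum
    suppression along the gradient direction quantized to 4 bins (0, 45, 90,
    135 degrees), then double-threshold hysteresis: pixels with magnitude
    >= ``high * maxgrad`` are strong seeds, pixels >= ``low * maxgrad`` are
    kept only if 8-connected to a strong seed.  Thresholds are fractions of
    the maximum smoothed gradient magnitude.
    """
    if not 0 <= low <= high <= 1:
        raise ValueError(f"require 0 <= low <= high <= 1, got low={low}, high={high}")
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    smoothed = ndimage.gaussian_filter(img, sigma) if sigma > 0 else img
    gy = ndimage.sobel(smoothed, axis=0, mode="nearest")
    gx = ndimage.sobel(smoothed, axis=1, mode="nearest")
    mag = np.hypot(gx, gy)
    maxgrad = mag.max()
    if maxgrad == 0:
        return np.zeros(img.shape, dtype=np.uint8)

    # non-maximum suppression with 4 quantized directions
    angle = np.mod(np.degrees(np.arctan2(gy, gx)), 180.0)
    padded = np.pad(mag, 1, mode="constant")
    m = padded[1:-1, 1:-1]
    neighbours = {
        0: (padded[1:-1, 2:], padded[1:-1, :-2]),  # horizontal gradient: E/W
        45: (padded[:-2, 2:], padded[2:, :-2]),  # NE/SW
        90: (padded[:-2, 1:-1], padded[2:, 1:-1]),  # N/S
        135: (padded[:-2, :-2], padded[2:, 2:]),  # NW/SE
    }
    bins = (np.round(angle / 45.0).astype(int) % 4) * 45
    nms = np.zeros_like(mag)
    for direction, (n1, n2) in neighbours.items():
        sel = bins == direction
        keep = sel & (m >= n1) & (m >= n2)
        nms[keep] = mag[keep]

    strong = nms >= high * maxgrad
    weak = nms >= low * maxgrad
    labels, _ = ndimage.label(weak, structure=np.ones((3, 3), dtype=int))
    keep_labels = np.unique(labels[strong])
    keep_labels = keep_labels[keep_labels != 0]
    edges = np.isin(labels, keep_labels)
    return edges.astype(np.uint8)


def glcm(
    img: np.ndarray,
    offset: tuple[int, int],
    levels: int,
    symmetric: bool = True,
    normalize: bool = True,
) -> np.ndarray:
    """Gray-level co-occurrence matrix for one pixel offset.

    ``M[i, j]`` counts in-bounds pixel pairs ``(p, p + offset)`` whose values
    are ``(i, j)``; with ``symmetric`` the transpose is added (each pair
    counted in both orders); with ``normalize`` entries are divided by the
    total count so they sum to 1.
    """
    img = np.asarray(img)
    if not np.issubdtype(img.dtype, np.integer):
        raise DomainError("glcm expects an integer image pre-quantized to [0, levels-1]")
    if img.min() < 0 or img.max() > levels - 1:
        raise DomainError(f"intensities must lie in [0, {levels - 1}]")
    dr, dc = offset
    if (dr, dc) == (0, 0):
        raise ValueError("offset must be nonzero")
    h, w = img.shape
    if abs(dr) >= h or abs(dc) >= w:
        raise DataError(f"offset {offset} leaves no valid pairs in a {h}x{w} image")

    def sl(d: int, n: int) -> tuple[slice, slice]:
        # slices of the reference pixels and of the offset pixels
        if d >= 0:
            return slice(0, n - d), slice(d, n)
        return slice(-d, n), slice(0, n + d)

    r_ref, r_off = sl(dr, h)
    c_ref, c_off = sl(dc, w)
    a = img[r_ref, c_ref].ravel().astype(np.int64)
    b = img[r_off, c_off].ravel().astype(np.int64)
    mat = np.bincount(a * levels + b, minlength=levels * levels).reshape(levels, levels)
    mat = mat.astype(float)
    if symmetric:
        mat = mat + mat.T
    if normalize:
        mat /= mat.sum()
    return mat


def glcm_stats(G: np.ndarray) -> tuple[float, float, float]:
    """Haralick contrast, energy and correlation of a normalized GLCM.

    contrast = sum (i-j)^2 p(i,j); energy = sum p(i,j)^2; correlation =
    sum (i - mu_i)(j - mu_j) p(i,j) / (sigma_i sigma_j), defined as 0 when
    either marginal standard deviation vanishes (single-level image).
    """
    G = np.asarray(G, dtype=float)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise ValueError("GLCM must be square")
    if abs(G.sum() - 1.0) > 1e-9:
        raise DomainError("glcm_stats requires a normalized GLCM (entries sum to 1)")
    k = G.shape[0]
    i = np.arange(k)[:, None]
    j = np.arange(k)[None, :]
    contrast = float(np.sum((i - j) ** 2 * G))
    energy = float(np.sum(G**2))
    p_i = G.sum(axis=1)
    p_j = G.sum(axis=0)
    mu_i = float(np.sum(np.arange(k) * p_i))
    mu_j = float(np.sum(np.arange(k) * p_j))
    var_i = float(np.sum((np.arange(k) - mu_i) ** 2 * p_i))
    var_j = float(np.sum((np.arange(k) - mu_j) ** 2 * p_j))
    if var_i <= 0 or var_j <= 0:
        correlation = 0.0
    else:
        correlation = float(
            np.sum((i - mu_i) * (j - mu_j) * G) / np.sqrt(var_i * var_j)
        )
    return contrast, energy, correlation


def quantize_levels(img: np.ndarray, levels: int) -> np.ndarray:
    """Min-max linear quantization of an image to integer levels [0, levels-1].

    Bins are relative to the image's own min/max, so the result (and therefore
    every GLCM feature) is invariant to adding a constant to all pixels.  A
    constant image maps to level 0.
    """
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    if hi == lo:
        return np.zeros(img.shape, dtype=np.int64)
    q = np.floor((img - lo) / (hi - lo) * levels).astype(np.int64)
    return np.clip(q, 0, levels - 1)


def extract_feature_vector(img: np.ndarray, cfg: FeatureConfig | None = None) -> FeatureVector:
    """Edge density plus GLCM contrast/energy/correlation of one image."""
    cfg = cfg or FeatureConfig()
    img = np.asarray(img, dtype=float)
    edges = canny(img, cfg.canny_sigma, cfg.canny_low, cfg.canny_high)
    density = float(edges.sum()) / edges.size
    q = quantize_levels(img, cfg.levels)
    G = glcm(q, cfg.offset, cfg.levels, symmetric=True, normalize=True)
    contrast, energy, correlation = glcm_stats(G)
    return FeatureVector(density, contrast, energy, correlation)


def extract_features_table(
    manifest: pd.DataFrame,
    images_root,
    cfg: FeatureConfig | None = None,
) -> pd.DataFrame:
    """Feature vectors for every manifest row.

    Returns a DataFrame with columns ``sample_id, edge_density, glcm_contrast,
    glcm_energy, glcm_correlation, label, split`` (label as 0/1 codes).
    """
    from pathlib import Path

    from PIL import Image

    from .synthetic import LABEL_CODES

    cfg = cfg or FeatureConfig()
    root = Path(images_root)
    records = []
    for _, row in manifest.iterrows():
        path = root / row["path"]
        with Image.open(path) as im:
            img = np.asarray(im.convert("L"), dtype=float)
        fv = extract_feature_vector(img, cfg)
        records.append(
            {
                "sample_id": row["path"],
                **dict(zip(FEATURE_NAMES, fv.as_array())),
                "label": LABEL_CODES[row["label"]],
                "split": row["split"],
            }
        )
    return pd.DataFrame.from_records(records)
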