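"""Synthetic brain-phantom generator.

Produces labeled grayscale images that emulate the structure of a CT/MRI
stroke dataset: an elliptical "brain" foreground on a dark background, additive
Gaussian pixel noise, and — for the stroke class — one circular lesion whose
signed contrast against the surrounding tissue controls class separability
(positive offsets mimic hyper-intense hemorrhagic lesions, negative offsets
hypo-intense ischemic ones).

The generator makes no claim of anatomical or modality fidelity; it exists so
the full pipeline (preprocessing, feature extraction, circuit training,
evaluation) is exercisable and testable without any external download.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

from .errors import ConfigurationError, DataError

__all__ = ["SyntheticConfig", "generate_image", "generate_dataset", "read_manifest"]

MANIFEST_COLUMNS = ["path", "label", "split"]
LABEL_NAMES = {0: "normal", 1: "stroke"}
LABEL_CODES = {"normal": 0, "stroke": 1}


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the phantom dataset.

    Default per-class/per-split counts reproduce the emulated dataset layout
    (1,500/500 normal and 1,400/400 stroke train/test images, 3,800 total).
    Intensity defaults (background 20, brain 120, lesion +80, noise sigma 10)
    give a dataset that is learnable but not trivially separable.
    """

    image_size: int = 128
    n_normal_train: int = 1500
    n_normal_test: int = 500
    n_stroke_train: int = 1400
    n_stroke_test: int = 400
    brain_axes: tuple[float, float] = (48.0, 40.0)
    background_level: float = 20.0
    brain_level: float = 120.0
    lesion_radius: float = 10.0
    lesion_delta: float = 80.0
    noise_sigma: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        for f in ("n_normal_train", "n_normal_test", "n_stroke_train", "n_stroke_test"):
            if getattr(self, f) < 0:
                raise ConfigurationError(f"{f} must be >= 0, got {getattr(self, f)}")
        if self.image_size < 16:
            raise ConfigurationError(f"image_size must be >= 16, got {self.image_size}")
        if abs(self.lesion_delta) > 255:
            raise ConfigurationError(
                f"lesion_delta must lie in [-255, 255], got {self.lesion_delta}"
            )
        if self.noise_sigma < 0:
            raise ConfigurationError(
                f"noise_sigma must be >= 0, got {self.noise_sigma}"
            )
        if self.lesion_radius <= 0:
            raise ConfigurationError(
                f"lesion_radius must be > 0, got {self.lesion_radius}"
            )
        ax = self.brain_axes
        if len(ax) != 2 or min(ax) <= 0:
            raise ConfigurationError(f"brain_axes must be two positive lengths, got {ax}")
        if min(ax) <= self.lesion_radius:
            raise ConfigurationError(
                "brain_axes semi-axes must exceed lesion_radius "
                f"(got axes {ax}, radius {self.lesion_radius})"
            )
        for f in ("background_level", "brain_level"):
            v = getattr(self, f)
            if not 0 <= v <= 255:
                raise ConfigurationError(f"{f} must lie in [0, 255], got {v}")

    def counts(self) -> dict[tuple[str, str], int]:
        return {
            ("normal", "train"): self.n_normal_train,
            ("normal", "test"): self.n_normal_test,
            ("stroke", "train"): self.n_stroke_train,
            ("stroke", "test"): self.n_stroke_test,
        }


def _disc_footprint(radius: float) -> np.ndarray:
    r = int(np.floor(radius))
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy**2 + xx**2) <= radius**2


def _brain_mask(cfg: SyntheticConfig) -> np.ndarray:
    n = cfg.image_size
    c = (n - 1) / 2.0
    yy, xx = np.mgrid[0:n, 0:n]
    a, b = cfg.brain_axes  # (row semi-axis, column semi-axis)
    return ((yy - c) / a) ** 2 + ((xx - c) / b) ** 2 <= 1.0


def _lesion_centers(cfg: SyntheticConfig) -> np.ndarray:
    """Pixel coordinates where a lesion disc fits entirely inside the brain.

    Exact pixel-grid erosion of the ellipse mask by the same disc footprint
    used to draw the lesion, so the inside-the-brain contract holds exactly.
    """
    eroded = ndimage.binary_erosion(
        _brain_mask(cfg), structure=_disc_footprint(cfg.lesion_radius)
    )
    centers = np.argwhere(eroded)
    if centers.size == 0:
        raise ConfigurationError(
            "lesion_radius too large: no placement keeps the lesion inside the brain"
        )
    return centers


def generate_image(
    label: int, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    """One phantom image as a uint8 array of shape (image_size, image_size).

    Background at ``background_level``, ellipse interior at ``brain_level``;
    for the stroke class one disc of radius ``lesion_radius``, placed uniformly
    over the eroded ellipse interior, is shifted by ``lesion_delta``; Gaussian
    noise of std ``noise_sigma`` is added everywhere; the result is clipped to
    [0, 255] and rounded.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 (normal) or 1 (stroke), got {label}")
    img = np.full((cfg.image_size, cfg.image_size), cfg.background_level, dtype=float)
    img[_brain_mask(cfg)] = cfg.brain_level
    # Draw the lesion placement even for normal images so that a stroke image
    # and the same-substream normal image differ only inside the disc.
    centers = _lesion_centers(cfg)
    cy, cx = centers[rng.integers(len(centers))]
    if label == 1:
        yy, xx = np.mgrid[0 : cfg.image_size, 0 : cfg.image_size]
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= cfg.lesion_radius**2
        img[disc] += cfg.lesion_delta
    if cfg.noise_sigma > 0:
        img += rng.normal(0.0, cfg.noise_sigma, img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


def generate_dataset(cfg: SyntheticConfig, out_dir: str | Path) -> pd.DataFrame:
    """Write one 8-bit grayscale PNG per sample plus a CSV manifest.

    A single global seed spawns an independent, index-keyed random substream
    per image, so the dataset is bitwise reproducible and insensitive to
    generation order.  Returns the manifest as a DataFrame with columns
    ``path,label,split`` (paths relative to ``out_dir``); the same table is
    written to ``out_dir/manifest.csv``.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create output directory {out_dir}: {exc}") from exc

    rows = []
    index = 0
    for (label_name, split), count in cfg.counts().items():
        label = LABEL_CODES[label_name]
        for i in range(count):
            rng = np.random.default_rng(
                np.random.SeedSequence(entropy=cfg.seed, spawn_key=(index,))
            )
            img = generate_image(label, cfg, rng)
            fname = f"{label_name}_{split}_{i:05d}.png"
            Image.fromarray(img, mode="L").save(out_dir / fname)
            rows.append({"path": fname, "label": label_name, "split": split})
            index += 1
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Load and validate a ``path,label,split`` manifest CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"manifest {path} missing columns: {missing}")
    bad_label = set(df["label"]) - set(LABEL_CODES)
    if bad_label:
        raise DataError(f"manifest {path} has unknown labels: {sorted(bad_label)}")
    bad_split = set(df["split"]) - {"train", "test"}
    if bad_split:
        raise DataError(f"manifest {path} has unknown splits: {sorted(bad_split)}")
    return df[MANIFEST_COLUMNS].copy()


def config_from_mapping(mapping: dict) -> SyntheticConfig:
    """Build a :class:`SyntheticConfig` from a plain dict (YAML/JSON block)."""
    valid = {f.name for f in dataclasses.fields(SyntheticConfig)}
    unknown = set(mapping) - valid
    if unknown:
        raise ConfigurationError(f"unknown synthetic-config keys: {sorted(unknown)}")
    kwargs = dict(mapping)
    if "brain_axes" in kwargs:
        kwargs["brain_axes"] = tuple(kwargs["brain_axes"])
    return SyntheticConfig(**kwargs)
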