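"""Retinal front-end: log light adaptation, DoG center-surround filtering,
edge cropping, and random patch extraction with per-patch standardization.

The output patches stand for the responses of a square array of retinal
ganglion cells (RGCs) to a small piece of image; they are the stimulus
vectors ``d`` that drive cortical learning.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import imageio.v3 as iio
import numpy as np
from scipy import signal

logger = logging.getLogger(__name__)

__all__ = [
    "ImageEnsemble",
    "DoGParams",
    "PatchSet",
    "log_transform",
    "build_dog_kernel",
    "filter_and_crop",
    "extract_patches",
    "load_images",
]


@dataclass
class ImageEnsemble:
    """A collection of same-sized 2-D grayscale luminance images.

    Pixel values must be strictly positive before :func:`log_transform`
    is applied (after the transform they may be any real number).
    """

    images: list[np.ndarray]

    def __post_init__(self) -> None:
        if not self.images:
            raise ValueError("ImageEnsemble requires at least one image")
        self.images = [np.asarray(im, dtype=float) for im in self.images]
        shape = self.images[0].shape
        for k, im in enumerate(self.images):
            if im.ndim != 2:
                raise ValueError(f"image {k} is not 2-D (shape {im.shape})")
            if im.shape != shape:
                raise ValueError(
                    f"image {k} has shape {im.shape}, expected {shape}"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.images[0].shape

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(self.images)


@dataclass(frozen=True)
class DoGParams:
    """Difference-of-Gaussians filter parameters (in pixels).

    The surround Gaussian is rescaled so the discrete kernel sums to zero
    (zero-DC filter): constant inputs are annihilated exactly.
    """

    sigma_center: float = 0.75
    sigma_surround: float = 2.25
    kernel_halfwidth: int | None = None  # default ceil(4 * sigma_surround)

    def __post_init__(self) -> None:
        if not (0 < self.sigma_center < self.sigma_surround):
            raise ValueError(
                "require sigma_surround > sigma_center > 0, got "
                f"({self.sigma_center}, {self.sigma_surround})"
            )

    @property
    def halfwidth(self) -> int:
        if self.kernel_halfwidth is not None:
            if self.kernel_halfwidth < 1:
                raise ValueError("kernel_halfwidth must be >= 1")
            return int(self.kernel_halfwidth)
        return int(math.ceil(4.0 * self.sigma_surround))


@dataclass
class PatchSet:
    """Standardized RGC-response patches.

    ``data`` is ``(n_patches, g*g)`` with each row zero-mean, unit-sd.
    ``sources`` records ``(image_index, row, col)`` of each patch's
    top-left corner so a run can be audited.
    """

    data: np.ndarray
    grid_size: int
    sources: np.ndarray = field(default_factory=lambda: np.empty((0, 3), int))
    seed: int | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("PatchSet data must be 2-D")
        if self.data.shape[1] != self.grid_size**2:
            raise ValueError(
                f"row length {self.data.shape[1]} != grid_size^2 "
                f"({self.grid_size**2})"
            )

    @property
    def n_patches(self) -> int:
        return self.data.shape[0]

    def patch_image(self, k: int) -> np.ndarray:
        """Return patch ``k`` reshaped to its 2-D grid."""
        return self.data[k].reshape(self.grid_size, self.grid_size)

    def save(self, path: str | Path) -> None:
        """Write data to ``<path>.npy`` with a JSON sidecar of metadata."""
        path = Path(path)
        np.save(path.with_suffix(".npy"), self.data)
        meta = {
            "grid_size": self.grid_size,
            "seed": self.seed,
            "n_patches": self.n_patches,
            "sources": self.sources.tolist(),
        }
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "PatchSet":
        path = Path(path)
        data = np.load(path.with_suffix(".npy"))
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            data=data,
            grid_size=meta["grid_size"],
            sources=np.asarray(meta["sources"], dtype=int).reshape(-1, 3),
            seed=meta["seed"],
        )


def log_transform(images: ImageEnsemble) -> ImageEnsemble:
    """Natural log of every pixel; models photoreceptor light adaptation.

    Raises ``ValueError`` identifying the first image with a non-positive
    pixel (the log of such values is undefined / non-finite).
    """
    out = []
    for k, im in enumerate(images):
        if np.any(im <= 0):
            bad = int(np.sum(im <= 0))
            raise ValueError(
                f"image {k} has {bad} non-positive pixel(s); "
                "log transform requires strictly positive luminance"
            )
        out.append(np.log(im))
    return ImageEnsemble(out)


def build_dog_kernel(params: DoGParams = DoGParams()) -> np.ndarray:
    """Discrete difference-of-Gaussians kernel with exact zero DC gain.

    Center (excitatory) Gaussian minus surround (inhibitory) Gaussian,
    both unit-volume analytically, with the surround rescaled so the
    *sampled* kernel sums to zero — sampling a truncated Gaussian does
    not preserve its volume, so the balance is enforced on the discrete
    kernel itself.
    """
    h = params.halfwidth
    x = np.arange(-h, h + 1, dtype=float)
    xx, yy = np.meshgrid(x, x, indexing="ij")
    r2 = xx**2 + yy**2

    def gauss(sigma: float) -> np.ndarray:
        g = np.exp(-r2 / (2.0 * sigma**2)) / (2.0 * np.pi * sigma**2)
        return g

    center = gauss(params.sigma_center)
    surround = gauss(params.sigma_surround)
    surround *= center.sum() / surround.sum()
    kernel = center - surround
    assert abs(kernel.sum()) < 1e-10, "DC balance failed"
    return kernel


def filter_and_crop(
    image: np.ndarray, kernel: np.ndarray, crop: int = 10
) -> np.ndarray:
    """'Same'-size zero-padded convolution followed by discarding a border.

    The crop (default 10 px) removes the region contaminated by the zero
    padding at the image edges.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a 2-D image")
    if min(image.shape) <= 2 * crop:
        raise ValueError(
            f"image of shape {image.shape} too small for crop of {crop} px"
        )
    out = signal.fftconvolve(image, kernel, mode="same")
    if crop > 0:
        out = out[crop:-crop, crop:-crop]
    return out


def extract_patches(
    filtered: Sequence[np.ndarray] | ImageEnsemble,
    g: int = 16,
    n_patches: int = 1000,
    seed: int | None = None,
    max_resamples: int = 1000,
) -> PatchSet:
    """Cut randomly positioned g-by-g patches and standardize each.

    Patch positions are uniform over (image, top-left corner), sampled
    with replacement. Each patch has its mean subtracted and is divided
    by its standard deviation. Zero-variance patches are resampled (the
    standardization would be undefined); more than ``max_resamples``
    consecutive failures raises.
    """
    images = list(filtered)
    h, w = images[0].shape
    if g > min(h, w):
        raise ValueError(f"patch size {g} exceeds image size {(h, w)}")
    rng = np.random.default_rng(seed)
    data = np.empty((n_patches, g * g), dtype=float)
    sources = np.empty((n_patches, 3), dtype=int)
    k = 0
    failures = 0
    while k < n_patches:
        i = int(rng.integers(len(images)))
        r = int(rng.integers(h - g + 1))
        c = int(rng.integers(w - g + 1))
        patch = images[i][r : r + g, c : c + g]
        sd = patch.std()
        if sd == 0 or not np.isfinite(sd):
            failures += 1
            logger.debug("zero-variance patch at (%d, %d, %d); resampling", i, r, c)
            if failures > max_resamples:
                raise RuntimeError(
                    f"{failures} consecutive zero-variance patches; "
                    "input images appear degenerate"
                )
            continue
        failures = 0
        data[k] = ((patch - patch.mean()) / sd).ravel()
        sources[k] = (i, r, c)
        k += 1
    return PatchSet(data=data, grid_size=g, sources=sources, seed=seed)


def load_images(
    paths: Sequence[str | Path], epsilon: float = 0.0
) -> ImageEnsemble:
    """Read grayscale images (PNG/TIFF/... via imageio, or .npy arrays).

    ``epsilon`` > 0 adds a constant offset, for integer formats whose
    black level is exactly 0 (the log transform requires positive pixels).
    """
    images = []
    for p in paths:
        p = Path(p)
        if p.suffix == ".npy":
            im = np.load(p)
        else:
            im = np.asarray(iio.imread(p), dtype=float)
            if im.ndim == 3:  # collapse RGB(A) to luminance
                im = im[..., :3].mean(axis=-1)
        im = np.asarray(im, dtype=float) + epsilon
        if np.any(im <= 0):
            raise ValueError(
                f"{p}: non-positive pixels; pass epsilon > 0 to offset"
            )
        images.append(im)
    return ImageEnsemble(images)
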