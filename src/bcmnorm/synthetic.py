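"""Synthetic stimulus generation.

Natural-image stand-ins with approximately 1/f amplitude spectra and an
adjustable excess of vertical/horizontal orientation energy, plus small
deterministic environments (orthogonal pattern streams, Gabor fields) used
as analytic fixtures by the learning and tuning analyses.

Images are generated in log-luminance and exponentiated, so the retinal
log transform recovers an approximately Gaussian 1/f field.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

from bcmnorm.retina import ImageEnsemble
from bcmnorm.rf_analysis import ReceptiveFieldSet

__all__ = [
    "SyntheticImageSpec",
    "GaborParams",
    "PatternEnvironment",
    "pink_noise_ensemble",
    "rotate_ensemble",
    "two_pattern_environment",
    "gabor_field_set",
    "band_energy_ratio",
    "radial_amplitude_slope",
]


@dataclass(frozen=True)
class SyntheticImageSpec:
    """Recipe for a random ensemble of positive-luminance images.

    ``spectral_slope`` is the exponent of the radial amplitude profile
    (-1 gives 1/f). ``orientation_bias`` is the target ratio of
    vertical+horizontal band energy to oblique band energy. ``rotation``
    rotates the finished images (orientation-control experiments).
    """

    n_images: int = 16
    size: int = 128
    spectral_slope: float = -1.0
    orientation_bias: float = 2.0
    axis_ratio: float = 1.0  # vertical-feature vs horizontal-feature energy
    rotation: float = 0.0
    luminance_floor: float = 1e-3
    log_contrast: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")
        if self.luminance_floor <= 0:
            raise ValueError("luminance_floor must be positive")
        if self.orientation_bias <= 0 or self.axis_ratio <= 0:
            raise ValueError("orientation_bias and axis_ratio must be positive")


def _orientation_gain(
    theta: np.ndarray, bias: float, axis_ratio: float = 1.0
) -> np.ndarray:
    """Smooth energy gain with lobes on the vertical/horizontal axes.

    gain(theta) = 1 + a*cos(4*theta) + b*cos(2*theta). ``a`` sets the
    (vertical+horizontal)/oblique band-energy ratio to ``bias`` exactly in
    the continuum limit, a = (pi/2)*(bias-1)/(bias+1); ``b`` splits the
    two axis lobes so the theta=0 lobe (vertical image features) carries
    ``axis_ratio`` times the energy of the theta=90 lobe, leaving the
    oblique band untouched (cos(2*theta) integrates to zero there).
    """
    a = (np.pi / 2.0) * (bias - 1.0) / (bias + 1.0)
    if abs(a) >= 1.0:
        raise ValueError(
            f"orientation_bias {bias} out of the representable range"
        )
    lobe = 1.0 + a * 2.0 / np.pi  # mean axis-band gain
    sinc = np.sin(np.pi / 4.0) / (np.pi / 4.0)  # mean cos(2t) near an axis
    b = (axis_ratio - 1.0) / (axis_ratio + 1.0) * lobe / sinc
    gain = 1.0 + a * np.cos(4.0 * theta) + b * np.cos(2.0 * theta)
    if np.any(gain < 0):
        raise ValueError(
            f"axis_ratio {axis_ratio} too extreme for bias {bias}"
        )
    return gain


def pink_noise_ensemble(spec: SyntheticImageSpec) -> ImageEnsemble:
    """Random-phase images with radial amplitude ~ f^slope and axis bias.

    White Gaussian noise is shaped in the frequency domain by the radial
    profile and the orientation-bias gain, inverse-transformed to a
    log-luminance field (standardized, scaled by ``log_contrast``), then
    exponentiated with a positive floor.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.size
    f = np.fft.fftfreq(n)
    fy, fx = np.meshgrid(f, f, indexing="ij")
    radius = np.hypot(fx, fy)
    theta = np.arctan2(fy, fx)
    with np.errstate(divide="ignore"):
        amp = np.where(radius > 0, radius**spec.spectral_slope, 0.0)
    amp *= np.sqrt(
        _orientation_gain(theta, spec.orientation_bias, spec.axis_ratio)
    )

    images = []
    for _ in range(spec.n_images):
        white = rng.standard_normal((n, n))
        shaped = np.fft.ifft2(np.fft.fft2(white) * amp).real
        shaped = (shaped - shaped.mean()) / shaped.std()
        images.append(spec.luminance_floor + np.exp(spec.log_contrast * shaped))
    ens = ImageEnsemble(images)
    if spec.rotation != 0.0:
        ens = rotate_ensemble(ens, spec.rotation)
    return ens


def rotate_ensemble(images: ImageEnsemble, angle: float) -> ImageEnsemble:
    """Rotate every image about its centre and crop the valid region.

    Bilinear interpolation (keeps pixel values inside the original range,
    so positivity survives); the crop is the largest centred square fully
    inside the rotated frame.
    """
    h, w = images.shape
    n = min(h, w)
    rad = np.radians(angle % 90.0)
    side = int(np.floor(n / (abs(np.cos(rad)) + abs(np.sin(rad)))))
    if side < 2:
        raise ValueError(f"valid region after {angle} deg rotation is empty")
    out = []
    for im in images:
        rot = ndimage.rotate(im, angle, reshape=False, order=1, mode="nearest")
        r0 = (h - side) // 2
        c0 = (w - side) // 2
        out.append(rot[r0 : r0 + side, c0 : c0 + side])
    return ImageEnsemble(out)


@dataclass
class PatternEnvironment:
    """An i.i.d. stream over a fixed set of mutually orthogonal patterns."""

    patterns: np.ndarray  # (k, d), orthonormal rows
    probabilities: np.ndarray  # (k,), sums to 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if abs(self.probabilities.sum() - 1.0) > 1e-9 or np.any(
            self.probabilities < 0
        ):
            raise ValueError("probabilities must be nonnegative and sum to 1")
        gram = self.patterns @ self.patterns.T
        if not np.allclose(gram, np.eye(len(self.patterns)), atol=1e-9):
            raise ValueError("patterns must be mutually orthogonal unit vectors")

    def __iter__(self) -> Iterator[np.ndarray]:
        rng = np.random.default_rng(self.seed)
        k = len(self.probabilities)
        while True:
            yield self.patterns[rng.choice(k, p=self.probabilities)]

    def sample(self, n: int) -> np.ndarray:
        """(n, d) matrix of i.i.d. draws."""
        rng = np.random.default_rng(self.seed)
        idx = rng.choice(len(self.probabilities), size=n, p=self.probabilities)
        return self.patterns[idx]


def two_pattern_environment(
    probabilities: Sequence[float],
    dimension: int,
    seed: int = 0,
    patterns: np.ndarray | None = None,
) -> PatternEnvironment:
    """Environment of k orthonormal patterns drawn i.i.d. with given probs.

    Default patterns are a random orthonormal set (QR of seeded Gaussian);
    pass ``patterns`` explicitly for canonical fixtures.
    """
    probs = np.asarray(probabilities, dtype=float)
    k = len(probs)
    if k > dimension:
        raise ValueError("more patterns than dimensions")
    if patterns is None:
        rng = np.random.default_rng(seed)
        q, _ = np.linalg.qr(rng.standard_normal((dimension, k)))
        patterns = q.T[:k]
    return PatternEnvironment(
        patterns=patterns, probabilities=probs, seed=seed + 1
    )


@dataclass(frozen=True)
class GaborParams:
    """Gabor with carrier frequency vector at angle ``ori`` (degrees)."""

    sf: float  # carrier, cycles/pixel
    ori: float  # degrees; frequency-vector angle (0 = modulation along x)
    sigma_major: float  # envelope sd along the modulation axis, pixels
    sigma_minor: float  # envelope sd along the bar axis, pixels
    phase: float = 0.0  # degrees
    x0: float | None = None  # centre; default grid centre
    y0: float | None = None

    def __post_init__(self) -> None:
        if not (0 < self.sf <= 0.5):
            raise ValueError(f"carrier {self.sf} outside (0, 0.5] cycles/pixel")
        if self.sigma_major <= 0 or self.sigma_minor <= 0:
            raise ValueError("envelope sigmas must be positive")


def gabor_field_set(
    params: Sequence[GaborParams], g: int = 16
) -> ReceptiveFieldSet:
    """Standardized Gabor receptive fields with known ground-truth tuning."""
    y, x = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    fields = np.empty((len(params), g, g))
    for n, p in enumerate(params):
        cx = (g - 1) / 2.0 if p.x0 is None else p.x0
        cy = (g - 1) / 2.0 if p.y0 is None else p.y0
        th = np.radians(p.ori)
        xr = (x - cx) * np.cos(th) + (y - cy) * np.sin(th)
        yr = -(x - cx) * np.sin(th) + (y - cy) * np.cos(th)
        env = np.exp(
            -0.5 * ((xr / p.sigma_major) ** 2 + (yr / p.sigma_minor) ** 2)
        )
        carrier = np.cos(2.0 * np.pi * p.sf * xr + np.radians(p.phase))
        field = env * carrier
        sd = field.std()
        if sd == 0:
            raise ValueError(f"degenerate Gabor at index {n}")
        fields[n] = (field - field.mean()) / sd
    return ReceptiveFieldSet(fields=fields, standardized=True)


# -- spectral measurement helpers (used by tests and reports) ---------------

def _mean_log_power(images: ImageEnsemble) -> np.ndarray:
    """Mean power spectrum of the mean-removed log images (unshifted)."""
    acc = None
    for im in images:
        lg = np.log(im)
        lg = lg - lg.mean()
        p = np.abs(np.fft.fft2(lg)) ** 2
        acc = p if acc is None else acc + p
    return acc / len(images)


def band_energy_ratio(
    images: ImageEnsemble, half_band: float = 22.5,
    r_min: float = 0.03, r_max: float = 0.5,
) -> float:
    """Vertical+horizontal vs oblique band energy of the log ensemble.

    Axis band: frequency angle within ``half_band`` degrees of 0 or 90;
    oblique band: the rest. Radius restricted to [r_min, r_max] to avoid
    the DC neighbourhood and the grid corners.
    """
    power = _mean_log_power(images)
    n = power.shape[0]
    f = np.fft.fftfreq(n)
    fy, fx = np.meshgrid(f, f, indexing="ij")
    radius = np.hypot(fx, fy)
    theta = np.degrees(np.arctan2(fy, fx)) % 90.0
    dist = np.minimum(theta, 90.0 - theta)  # distance to the nearest axis
    annulus = (radius >= r_min) & (radius <= r_max)
    axis_band = annulus & (dist <= half_band)
    oblique = annulus & (dist > half_band)
    return float(power[axis_band].mean() / power[oblique].mean())


def radial_amplitude_slope(
    images: ImageEnsemble, r_min: float = 0.02, r_max: float = 0.4,
    n_bins: int = 24,
) -> float:
    """Log-log slope of the radially averaged amplitude of the log ensemble."""
    power = _mean_log_power(images)
    amp = np.sqrt(power)
    n = amp.shape[0]
    f = np.fft.fftfreq(n)
    fy, fx = np.meshgrid(f, f, indexing="ij")
    radius = np.hypot(fx, fy)
    edges = np.geomspace(r_min, r_max, n_bins + 1)
    centers, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (radius >= lo) & (radius < hi)
        if np.any(sel):
            centers.append(np.sqrt(lo * hi))
            means.append(amp[sel].mean())
    slope = np.polyfit(np.log(centers), np.log(means), 1)[0]
    return float(slope)
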