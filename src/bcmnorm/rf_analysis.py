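"""Receptive-field reconstruction and spectral tuning measurement.

Learned weights act on DoG-filtered stimuli; the equivalent stimulus-domain
receptive field is the convolution of the weight array with the DoG kernel.
The convolution is done in the Fourier domain on a zero-padded grid (the
g x g weights embedded in a (pad_factor*g)^2 array), after which the field
is cropped back to g x g and standardized.

Tuning is read off the zero-padded Fourier amplitude spectrum: preferred
spatial frequency and orientation come from the single strongest non-DC
coefficient; bandwidths are half-maximum extents along the radial line
(octaves) and the iso-frequency ring (degrees) through that peak.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from bcmnorm.retina import DoGParams, build_dog_kernel

__all__ = [
    "ReceptiveFieldSet",
    "TuningParams",
    "reconstruct_fields",
    "amplitude_spectrum",
    "preferred_tuning",
    "sf_bandwidth",
    "ori_bandwidth",
    "measure_tuning",
]


@dataclass
class ReceptiveFieldSet:
    """Stack of stimulus-domain receptive fields, one g x g array per neuron."""

    fields: np.ndarray  # (J, g, g)
    standardized: bool = False

    def __post_init__(self) -> None:
        self.fields = np.asarray(self.fields, dtype=float)
        if self.fields.ndim != 3 or self.fields.shape[1] != self.fields.shape[2]:
            raise ValueError("fields must be a (J, g, g) stack")

    @property
    def n_fields(self) -> int:
        return self.fields.shape[0]

    @property
    def grid_size(self) -> int:
        return self.fields.shape[1]

    @property
    def matrix(self) -> np.ndarray:
        """Fields flattened to a (J, g*g) matrix."""
        return self.fields.reshape(self.n_fields, -1)


@dataclass(frozen=True)
class TuningParams:
    """Spectral tuning of one receptive field.

    preferred_sf is in cycles/pixel (0, 0.5]; preferred_ori is the angle of
    the peak's frequency vector, degrees in (-90, 90], 0 deg meaning
    modulation along the horizontal (x) axis, i.e. a vertical grating.
    Bandwidths are full half-maximum extents; *_upper_bound flags mark
    values clipped by the edge of the resolvable spectrum.
    """

    preferred_sf: float
    preferred_ori: float
    sf_bandwidth: float
    ori_bandwidth: float
    sf_upper_bound: bool = False
    ori_upper_bound: bool = False


def _embed_center(arr: np.ndarray, size: int) -> np.ndarray:
    """Place a square array at the centre of a size x size zero array."""
    g = arr.shape[0]
    if g > size:
        raise ValueError(f"cannot embed {g} into {size}")
    out = np.zeros((size, size), dtype=float)
    lo = (size - g) // 2
    out[lo : lo + g, lo : lo + g] = arr
    return out


def _dog_transfer(dog_params: DoGParams, size: int) -> np.ndarray:
    """Transfer function of the discrete DoG kernel on a size x size grid.

    The kernel is embedded with its centre at the (0, 0) origin (circular
    layout), so the transfer function carries no phase ramp.
    """
    kernel = build_dog_kernel(dog_params)
    h = kernel.shape[0] // 2
    if kernel.shape[0] > size:
        raise ValueError("padded grid smaller than DoG kernel support")
    padded = np.zeros((size, size), dtype=float)
    padded[: 2 * h + 1, : 2 * h + 1] = kernel
    padded = np.roll(padded, (-h, -h), axis=(0, 1))
    return np.fft.fft2(padded)


def reconstruct_fields(
    weights: np.ndarray,
    dog_params: DoGParams = DoGParams(),
    pad_factor: int = 4,
    standardize: bool = True,
) -> ReceptiveFieldSet:
    """Convolve each weight array with the DoG kernel via the padded FFT.

    ``weights`` is (J, g*g). Zero-variance results (degenerate neurons)
    raise, reporting the offending indices.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.ndim != 2:
        raise ValueError("weights must be (J, g*g)")
    j, d = weights.shape
    g = int(round(np.sqrt(d)))
    if g * g != d:
        raise ValueError(f"weight length {d} is not a square grid")
    size = pad_factor * g
    transfer = _dog_transfer(dog_params, size)

    lo = (size - g) // 2
    fields = np.empty((j, g, g), dtype=float)
    degenerate = []
    for n in range(j):
        padded = _embed_center(weights[n].reshape(g, g), size)
        conv = np.fft.ifft2(np.fft.fft2(padded) * transfer).real
        fields[n] = conv[lo : lo + g, lo : lo + g]
        sd = fields[n].std()
        if sd < 1e-300 or not np.isfinite(sd):
            degenerate.append(n)
        elif standardize:
            fields[n] = (fields[n] - fields[n].mean()) / sd
    if degenerate:
        raise ValueError(f"degenerate (zero-variance) fields at indices {degenerate}")
    return ReceptiveFieldSet(fields=fields, standardized=standardize)


def amplitude_spectrum(field: np.ndarray, pad_factor: int = 4) -> np.ndarray:
    """Zero-padded 2-D Fourier amplitude spectrum, DC at the array centre.

    For a g x g field the spectrum is (pad_factor*g) square; frequency
    step is 1/(pad_factor*g) cycles/pixel on each axis.
    """
    field = np.asarray(field, dtype=float)
    g = field.shape[0]
    padded = _embed_center(field, pad_factor * g)
    return np.abs(np.fft.fftshift(np.fft.fft2(padded)))


def _freq_axes(size: int) -> np.ndarray:
    """fftshift-ed frequency coordinates, cycles/pixel."""
    return np.fft.fftshift(np.fft.fftfreq(size))


def preferred_tuning(spectrum: np.ndarray) -> tuple[float, float]:
    """Location of the strongest non-DC coefficient: (sf, orientation).

    Orientation is the frequency-vector angle, degrees in (-90, 90]
    (0 deg = modulation along x). A real field's spectrum is symmetric
    through DC, so only the fx >= 0 half-plane is searched. Exact ties
    resolve to the lowest spatial frequency, then the lowest angle.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    if not np.any(spectrum > 0):
        raise ValueError("all-zero spectrum")
    size = spectrum.shape[0]
    f = _freq_axes(size)
    fy, fx = np.meshgrid(f, f, indexing="ij")  # row index ~ y, col ~ x
    radius = np.hypot(fx, fy)
    half = (fx > 0) | ((fx == 0) & (fy > 0))  # non-DC half-plane

    vals = np.where(half, spectrum, -np.inf)
    peak = vals.max()
    cands = np.argwhere(vals >= peak * (1 - 1e-12))
    # tie-break: lowest radius, then lowest angle
    ang = np.degrees(np.arctan2(fy, fx))
    order = sorted(
        (round(radius[r, c], 12), round(ang[r, c], 9), r, c) for r, c in cands
    )
    _, _, r, c = order[0]
    ori = ang[r, c]
    if ori <= -90.0:
        ori += 180.0
    elif ori > 90.0:
        ori -= 180.0
    return float(radius[r, c]), float(ori)


def _sample_spectrum(
    spectrum: np.ndarray, radii: np.ndarray, angles_deg: np.ndarray
) -> np.ndarray:
    """Bilinear interpolation of the spectrum at polar frequency points."""
    size = spectrum.shape[0]
    dc = size // 2  # index of zero frequency after fftshift
    th = np.radians(angles_deg)
    cols = dc + radii * np.cos(th) * size  # fx axis -> columns
    rows = dc + radii * np.sin(th) * size  # fy axis -> rows
    return ndimage.map_coordinates(
        spectrum, np.vstack([rows, cols]), order=1, mode="nearest"
    )


def _half_max_crossing(
    x: np.ndarray, y: np.ndarray, half: float
) -> tuple[float, bool]:
    """First x where y (starting at/above half at x[0]) drops below half.

    Returns (x_cross, hit_edge). Linear interpolation between samples;
    hit_edge=True when y never drops below half in the sampled range.
    """
    below = np.nonzero(y < half)[0]
    if len(below) == 0:
        return float(x[-1]), True
    i = below[0]
    if i == 0:
        return float(x[0]), False
    x0, x1 = x[i - 1], x[i]
    y0, y1 = y[i - 1], y[i]
    t = (y0 - half) / (y0 - y1) if y0 != y1 else 0.0
    return float(x0 + t * (x1 - x0)), False


def sf_bandwidth(
    spectrum: np.ndarray,
    peak: tuple[float, float] | None = None,
    n_samples: int = 512,
) -> tuple[float, bool]:
    """Octave bandwidth along the radial line through the spectral peak.

    Walk outward and inward from the peak radius at the peak orientation;
    the bandwidth is log2(r_high/r_low) between the half-maximum crossings.
    Returns (octaves, upper_bound_flag); the flag is set when a crossing
    lies outside the resolvable range (bandwidth is then a lower-bound
    estimate clipped at the grid edge / lowest resolvable frequency).
    """
    if peak is None:
        peak = preferred_tuning(spectrum)
    r_peak, ori = peak
    size = spectrum.shape[0]
    peak_val = float(
        _sample_spectrum(spectrum, np.array([r_peak]), np.array([ori]))[0]
    )
    half = peak_val / 2.0
    r_min = 1.0 / size  # lowest resolvable non-DC frequency
    r_max = 0.5 * np.sqrt(2.0)

    r_out = np.linspace(r_peak, r_max, n_samples)
    y_out = _sample_spectrum(spectrum, r_out, np.full(n_samples, ori))
    r_hi, edge_hi = _half_max_crossing(r_out, y_out, half)

    r_in = np.linspace(r_peak, r_min, n_samples)
    y_in = _sample_spectrum(spectrum, r_in, np.full(n_samples, ori))
    r_lo, edge_lo = _half_max_crossing(r_in, y_in, half)

    r_lo = max(r_lo, r_min)
    octaves = float(np.log2(r_hi / r_lo))
    return octaves, bool(edge_hi or edge_lo)


def ori_bandwidth(
    spectrum: np.ndarray,
    peak: tuple[float, float] | None = None,
    n_samples: int = 721,
) -> tuple[float, bool]:
    """Half-maximum angular extent along the iso-frequency ring at the peak.

    Walk clockwise and counter-clockwise (up to 90 deg each way) from the
    peak orientation at constant radius; report the angle between the two
    half-maximum crossings, in degrees. The upper-bound flag is set when
    the amplitude stays above half-maximum all the way around (bandwidth
    reported as 180 deg).
    """
    if peak is None:
        peak = preferred_tuning(spectrum)
    r_peak, ori = peak
    peak_val = float(
        _sample_spectrum(spectrum, np.array([r_peak]), np.array([ori]))[0]
    )
    half = peak_val / 2.0
    dtheta = np.linspace(0.0, 90.0, n_samples)

    y_pos = _sample_spectrum(
        spectrum, np.full(n_samples, r_peak), ori + dtheta
    )
    a_hi, edge_hi = _half_max_crossing(dtheta, y_pos, half)
    y_neg = _sample_spectrum(
        spectrum, np.full(n_samples, r_peak), ori - dtheta
    )
    a_lo, edge_lo = _half_max_crossing(dtheta, y_neg, half)

    return float(a_hi + a_lo), bool(edge_hi or edge_lo)


def measure_tuning(
    fields: ReceptiveFieldSet, pad_factor: int = 4
) -> list[TuningParams]:
    """Tuning parameters for every field in the set."""
    out = []
    for n in range(fields.n_fields):
        spec = amplitude_spectrum(fields.fields[n], pad_factor)
        peak = preferred_tuning(spec)
        bw_sf, sf_flag = sf_bandwidth(spec, peak)
        bw_ori, ori_flag = ori_bandwidth(spec, peak)
        out.append(
            TuningParams(
                preferred_sf=peak[0],
                preferred_ori=peak[1],
                sf_bandwidth=bw_sf,
                ori_bandwidth=bw_ori,
                sf_upper_bound=sf_flag,
                ori_upper_bound=ori_flag,
            )
        )
    return out
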