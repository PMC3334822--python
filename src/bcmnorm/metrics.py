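"""Population coding-quality metrics for a set of receptive fields.

The suite: lifetime and population sparseness (Vinje–Gallant statistic),
dispersal of response variance across neurons, pairwise orthogonality,
matrix rank at a singular-value tolerance, and spectral coverage — the
ability of the code to encode and decode every sinusoid on the grid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from bcmnorm.retina import PatchSet
from bcmnorm.rf_analysis import ReceptiveFieldSet

__all__ = [
    "ResponseMatrix",
    "CodingReport",
    "field_responses",
    "lifetime_sparseness",
    "population_sparseness",
    "dispersal",
    "orthogonality",
    "rank",
    "sinusoid_basis",
    "coverage",
    "coverage_error_map",
    "coding_report",
]

SV_TOLERANCE = 2.5  # singular-value cutoff for rank and pseudo-inverse


def _as_matrix(fields: ReceptiveFieldSet | np.ndarray) -> np.ndarray:
    if isinstance(fields, ReceptiveFieldSet):
        return fields.matrix
    m = np.asarray(fields, dtype=float)
    if m.ndim == 3:
        m = m.reshape(m.shape[0], -1)
    return m


@dataclass
class ResponseMatrix:
    """Responses of J neurons (rows) to N stimuli (columns)."""

    responses: np.ndarray
    stimulus_tag: str = ""

    def __post_init__(self) -> None:
        self.responses = np.asarray(self.responses, dtype=float)
        if self.responses.ndim != 2:
            raise ValueError("responses must be 2-D (neurons x stimuli)")
        if not np.all(np.isfinite(self.responses)):
            raise ValueError("responses contain non-finite entries")


@dataclass
class CodingReport:
    """The coding-quality summary for one receptive-field set."""

    reconstruction_error: float  # mean per-sinusoid decoding error E[m_i]
    coverage: float  # R = 1 - E[m_i]
    orthogonality: float
    rank: int
    lifetime_sparseness: float
    population_sparseness: float
    dispersal: float  # normalized, sum(sigma/max sigma)/J
    dispersal_raw: float  # sum(sigma/max sigma), in [1, J]
    n_fields: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    def table(self, label: str = "model") -> str:
        rows = [
            ("Reconstruction error", f"{self.reconstruction_error:.3f}"),
            ("Orthogonality", f"{self.orthogonality:.3f}"),
            ("Rank", f"{self.rank} (/{self.n_fields})"),
            ("Lifetime sparseness", f"{self.lifetime_sparseness:.3f}"),
            ("Population sparseness", f"{self.population_sparseness:.3f}"),
            ("Dispersal", f"{self.dispersal:.3f}"),
        ]
        width = max(len(r[0]) for r in rows)
        lines = [f"{'':{width}}  {label}"]
        lines += [f"{name:{width}}  {val}" for name, val in rows]
        return "\n".join(lines)


def field_responses(
    fields: ReceptiveFieldSet | np.ndarray, eval_patches: PatchSet | np.ndarray
) -> ResponseMatrix:
    """Linear responses of every field to every evaluation patch.

    Evaluation patches are log-transformed image fragments that have NOT
    been DoG-filtered: the reconstructed fields already absorb the DoG.
    """
    f = _as_matrix(fields)
    p = eval_patches.data if isinstance(eval_patches, PatchSet) else np.asarray(eval_patches, float)
    if f.shape[1] != p.shape[1]:
        raise ValueError(
            f"field dimension {f.shape[1]} != patch dimension {p.shape[1]}"
        )
    return ResponseMatrix(responses=f @ p.T)


def _vinje_gallant(rect: np.ndarray) -> np.ndarray:
    """S = 1 - E[r]^2 / E[r^2] along axis 1; NaN where a row is all zero."""
    mean = rect.mean(axis=1)
    meansq = np.square(rect).mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = 1.0 - np.square(mean) / meansq
    s[meansq == 0] = np.nan
    return s


def lifetime_sparseness(
    responses: ResponseMatrix | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Per-neuron sparseness over stimuli, and the mean over neurons.

    Responses are rectified to magnitudes first; the signed responses are
    near zero-mean, which would push the statistic to 1 regardless of
    selectivity. All-zero neurons yield NaN and are excluded from the mean.
    """
    r = responses.responses if isinstance(responses, ResponseMatrix) else np.asarray(responses, float)
    s = _vinje_gallant(np.abs(r))
    return s, float(np.nanmean(s))


def population_sparseness(
    responses: ResponseMatrix | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Per-stimulus sparseness across neurons, and the mean over stimuli."""
    r = responses.responses if isinstance(responses, ResponseMatrix) else np.asarray(responses, float)
    s = _vinje_gallant(np.abs(r).T)
    return s, float(np.nanmean(s))


def dispersal(responses: ResponseMatrix | np.ndarray) -> float:
    """D = sum_j sigma_j / max_j sigma_j, in [1, J].

    sigma_j is the standard deviation of neuron j's responses. D counts
    how many neurons carry an appreciable share of the response variance.
    """
    r = responses.responses if isinstance(responses, ResponseMatrix) else np.asarray(responses, float)
    sigma = r.std(axis=1)
    top = sigma.max()
    if top == 0:
        raise ValueError("all neurons have zero response variance")
    return float(np.sum(sigma / top))


def orthogonality(fields: ReceptiveFieldSet | np.ndarray) -> float:
    """1 minus the mean |cosine similarity| over distinct field pairs.

    Fields are normalized so each field's self-product is 1; a mutually
    orthogonal set scores 1.0, identical fields score 0.0.
    """
    f = _as_matrix(fields)
    if f.shape[0] < 2:
        raise ValueError("need at least two fields")
    norms = np.linalg.norm(f, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero field in set")
    unit = f / norms[:, None]
    gram = np.abs(unit @ unit.T)
    iu = np.triu_indices(f.shape[0], k=1)
    return float(1.0 - gram[iu].mean())


def rank(fields: ReceptiveFieldSet | np.ndarray, tol: float = SV_TOLERANCE) -> int:
    """Number of singular values of the flattened field matrix above tol.

    The absolute cutoff is meaningful because standardized fields all have
    row norm g (grid size).
    """
    f = _as_matrix(fields)
    sv = np.linalg.svd(f, compute_uv=False)
    return int(np.sum(sv > tol))


def sinusoid_basis(g: int = 16) -> tuple[np.ndarray, list[tuple[int, int, str]]]:
    """Complete orthonormal set of g*g real sinusoids on the g x g grid.

    For each distinct integer frequency (u, v) of the discrete Fourier
    grid (one member of each conjugate pair) there is a cosine-phase and a
    sine-phase stimulus; self-conjugate frequencies (DC and the Nyquist
    combinations) contribute a single cosine member. Every stimulus has
    unit Euclidean norm; the set is a complete orthonormal basis.

    Returns (basis, freqs): basis is (g*g, g*g) with stimuli as rows,
    freqs lists (u, v, phase) with phase in {"cos", "sin"}.
    """
    if g % 2:
        raise ValueError("grid size must be even")
    y, x = np.meshgrid(np.arange(g), np.arange(g), indexing="ij")
    seen: set[tuple[int, int]] = set()
    rows: list[np.ndarray] = []
    freqs: list[tuple[int, int, str]] = []
    for u in range(g):
        for v in range(g):
            conj = ((-u) % g, (-v) % g)
            if (u, v) in seen or conj in seen:
                continue
            seen.add((u, v))
            arg = 2.0 * np.pi * (u * x + v * y) / g
            cos = np.cos(arg).ravel()
            rows.append(cos / np.linalg.norm(cos))
            freqs.append((u, v, "cos"))
            if (u, v) != conj:
                sin = np.sin(arg).ravel()
                rows.append(sin / np.linalg.norm(sin))
                freqs.append((u, v, "sin"))
    basis = np.vstack(rows)
    assert basis.shape == (g * g, g * g)
    return basis, freqs


def _truncated_pinv_project(f: np.ndarray, tol: float) -> np.ndarray:
    """Projector P = F+ F with the pseudo-inverse truncated at tol.

    Decoding x_hat = F+ (F x) is the orthogonal projection of x onto the
    span of the right singular vectors whose singular value exceeds tol.
    """
    _, sv, vt = np.linalg.svd(f, full_matrices=False)
    keep = sv > tol
    vk = vt[keep]
    return vk.T @ vk


def coverage(
    fields: ReceptiveFieldSet | np.ndarray, tol: float = SV_TOLERANCE
) -> tuple[float, np.ndarray]:
    """Encode/decode every basis sinusoid; R = 1 - mean squared residual.

    Each unit-norm sinusoid x is encoded as r = F x and decoded with the
    tolerance-truncated pseudo-inverse, x_hat = F+ r. The per-sinusoid
    error m_i = ||x - x_hat||^2 lies in [0, 1]; returns (R, m) with m in
    the order produced by :func:`sinusoid_basis`.
    """
    f = _as_matrix(fields)
    g = int(round(np.sqrt(f.shape[1])))
    if g * g != f.shape[1]:
        raise ValueError("fields are not on a square grid")
    basis, _ = sinusoid_basis(g)
    proj = _truncated_pinv_project(f, tol)
    resid = basis - basis @ proj.T
    m = np.sum(np.square(resid), axis=1)
    return float(1.0 - m.mean()), m


def coverage_error_map(m: np.ndarray, g: int) -> np.ndarray:
    """Arrange per-sinusoid errors on the centred (u, v) frequency grid.

    Cosine/sine phases at one frequency are averaged; conjugate positions
    are mirrored so the map displays the full plane, DC at the centre.
    """
    _, freqs = sinusoid_basis(g)
    acc = np.zeros((g, g))
    cnt = np.zeros((g, g))
    for err, (u, v, _) in zip(m, freqs):
        for uu, vv in ((u, v), ((-u) % g, (-v) % g)):
            acc[vv, uu] += err
            cnt[vv, uu] += 1
    out = np.where(cnt > 0, acc / np.maximum(cnt, 1), np.nan)
    return np.fft.fftshift(out)


def coding_report(
    fields: ReceptiveFieldSet | np.ndarray,
    eval_patches: PatchSet | np.ndarray,
    tol: float = SV_TOLERANCE,
) -> CodingReport:
    """Compute the full coding-quality suite for one field set."""
    f = _as_matrix(fields)
    resp = field_responses(f, eval_patches)
    r_cov, m = coverage(f, tol)
    d_raw = dispersal(resp)
    return CodingReport(
        reconstruction_error=float(m.mean()),
        coverage=r_cov,
        orthogonality=orthogonality(f),
        rank=rank(f, tol),
        lifetime_sparseness=lifetime_sparseness(resp)[1],
        population_sparseness=population_sparseness(resp)[1],
        dispersal=d_raw / f.shape[0],
        dispersal_raw=d_raw,
        n_fields=f.shape[0],
    )
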