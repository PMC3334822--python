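"""BCM and normalized-BCM (NBCM) synaptic learning.

Per stimulus presentation:

1. linear activation      r_j = sum_i m_ij d_i
2. sigmoid output         c_j = k1*tanh(r_j) if r_j > 0 else k2*tanh(r_j)
3. (NBCM only)            c'_j = beta * c_j / (alpha + sum_i c_i^2)
4. weight update          dm_ij = eta * c_j (c_j - theta_j) d_i
5. sliding threshold      dtheta_j = (c_j^2 - theta_j) / tau
6. annealing              eta = eta0 * anneal_factor^(iteration // 1000)

In NBCM mode the normalized output c' replaces c in the weight update,
while the sliding threshold keeps tracking the raw sigmoid output by
default (configurable): theta then stays on the scale of the
un-normalized responses, so the anti-Hebbian pressure that pulls the
network out of its saturated initial state is preserved. Divisive
normalization is the only coupling between neurons: the pool sum uses
the raw sigmoid outputs of the whole population.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from bcmnorm.retina import PatchSet

logger = logging.getLogger(__name__)

__all__ = [
    "LearningConfig",
    "NormalizationParams",
    "NetworkState",
    "ActivationVector",
    "TrainingDiverged",
    "activate",
    "normalize",
    "update_weights",
    "update_threshold",
    "anneal",
    "train",
]


class TrainingDiverged(RuntimeError):
    """Raised when weights become non-finite; carries the failing state."""

    def __init__(self, message: str, state: "NetworkState"):
        super().__init__(message)
        self.state = state


@dataclass(frozen=True)
class NormalizationParams:
    """Divisive-normalization constants: c' = beta*c / (alpha + sum c^2).

    alpha acts like a semi-saturation constant; beta scales the gain.
    Reference pairings: (alpha=1, beta=2) and (alpha=2, beta=4).
    """

    alpha: float = 1.0
    beta: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")


@dataclass(frozen=True)
class LearningConfig:
    k1: float = 25.0
    k2: float = 1.0
    tau: float = 1000.0
    eta0: float = 1e-5
    anneal_factor: float = 0.999
    anneal_every: int = 1000
    n_iterations: int = 1_000_000
    n_neurons: int = 256
    mode: str = "bcm"  # "bcm" | "nbcm"
    linear_output: bool = False  # bypass the sigmoid (test mode)
    # NBCM: feed c' (True) or the raw sigmoid output c (False) to the
    # threshold update. Raw c is the default: it keeps theta on the scale
    # of the un-normalized responses, which is the only reading consistent
    # with stable learning at eta ~ 1e-5 from saturated initial weights.
    threshold_uses_normalized: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.k1, self.k2, self.tau, self.eta0) <= 0:
            raise ValueError("k1, k2, tau, eta0 must be positive")
        if not (0 < self.anneal_factor <= 1):
            raise ValueError("anneal_factor must be in (0, 1]")
        if self.mode not in ("bcm", "nbcm"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class NetworkState:
    """Weights, per-neuron thresholds, learning-rate clock, and (when
    produced by :func:`train`) the stimulus-sampler RNG state needed to
    resume bit-for-bit."""

    weights: np.ndarray  # (J, n_inputs)
    thresholds: np.ndarray  # (J,)
    eta: float
    iteration: int = 0
    rng_state: dict | None = None

    @classmethod
    def initialize(cls, n_neurons: int, n_inputs: int, config: LearningConfig,
                   rng: np.random.Generator) -> "NetworkState":
        # weights uniform on [-1, 1]; thresholds start at zero
        w = rng.uniform(-1.0, 1.0, size=(n_neurons, n_inputs))
        return cls(
            weights=w,
            thresholds=np.zeros(n_neurons),
            eta=config.eta0,
            iteration=0,
        )

    def copy(self) -> "NetworkState":
        return NetworkState(
            weights=self.weights.copy(),
            thresholds=self.thresholds.copy(),
            eta=self.eta,
            iteration=self.iteration,
            rng_state=json.loads(json.dumps(self.rng_state))
            if self.rng_state is not None
            else None,
        )

    def save(self, path: str | Path, config: LearningConfig | None = None) -> None:
        path = Path(path)
        np.save(path.with_suffix(".weights.npy"), self.weights)
        np.save(path.with_suffix(".thresholds.npy"), self.thresholds)
        meta = {
            "eta": self.eta,
            "iteration": self.iteration,
            "rng_state": self.rng_state,
        }
        if config is not None:
            meta["config"] = asdict(config)
        path.with_suffix(".json").write_text(json.dumps(meta))

    @classmethod
    def load(cls, path: str | Path) -> "NetworkState":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            weights=np.load(path.with_suffix(".weights.npy")),
            thresholds=np.load(path.with_suffix(".thresholds.npy")),
            eta=meta["eta"],
            iteration=meta["iteration"],
            rng_state=meta.get("rng_state"),
        )


@dataclass
class ActivationVector:
    linear: np.ndarray  # r
    output: np.ndarray  # c (post-sigmoid)
    normalized: np.ndarray | None = None  # c' (NBCM only)

    @property
    def effective(self) -> np.ndarray:
        """The response that drives learning: c' when normalized, else c."""
        return self.output if self.normalized is None else self.normalized


def sigmoid(r: np.ndarray, k1: float, k2: float) -> np.ndarray:
    """Asymmetric tanh: k1*tanh(r) for r > 0, k2*tanh(r) for r < 0."""
    return np.where(r > 0, k1, k2) * np.tanh(r)


def activate(
    state: NetworkState, patch: np.ndarray, config: LearningConfig
) -> ActivationVector:
    """Linear summation followed by the asymmetric-tanh output nonlinearity."""
    if not np.all(np.isfinite(state.weights)):
        raise TrainingDiverged("non-finite weights", state)
    r = state.weights @ patch
    c = r if config.linear_output else sigmoid(r, config.k1, config.k2)
    return ActivationVector(linear=r, output=c)


def normalize(c: np.ndarray, params: NormalizationParams) -> np.ndarray:
    """Divisive contrast normalization over the whole population.

    Every output is divided by the same pooled signal alpha + sum_i c_i^2
    (the un-normalized outputs, including the neuron itself), then scaled
    by beta. The denominator is >= alpha > 0, so this never blows up.
    """
    pool = params.alpha + float(np.sum(np.square(c)))
    return params.beta * c / pool


def update_weights(
    state: NetworkState, c_eff: np.ndarray, patch: np.ndarray, eta: float
) -> None:
    """Apply dm_ij = eta * c_j (c_j - theta_j) d_i in place.

    Hebbian when c_j exceeds theta_j, anti-Hebbian when 0 < c_j < theta_j.
    """
    gain = eta * c_eff * (c_eff - state.thresholds)
    state.weights += np.outer(gain, patch)


def update_threshold(
    state: NetworkState, c_eff: np.ndarray, tau: float
) -> None:
    """Slide each threshold toward c^2: dtheta = (c^2 - theta)/tau.

    This is an exponential tracker of E[c^2] with time constant tau.
    """
    state.thresholds += (np.square(c_eff) - state.thresholds) / tau


def anneal(eta0: float, iteration: int, factor: float = 0.999,
           every: int = 1000) -> float:
    """Stepwise learning-rate schedule: eta0 * factor^(iteration // every)."""
    return eta0 * factor ** (iteration // every)


def train(
    patches: PatchSet | np.ndarray | Iterable[np.ndarray],
    config: LearningConfig,
    norm_params: NormalizationParams | None = None,
    initial_state: NetworkState | None = None,
    checkpoint_every: int | None = None,
    log_every: int = 10_000,
) -> tuple[NetworkState, list[NetworkState]]:
    """Run the learning loop and return (final state, checkpoints).

    ``patches`` is a PatchSet / (n, d) matrix sampled uniformly with
    replacement per iteration, or any iterable yielding stimulus vectors
    (in which case the caller owns the randomness). Fully deterministic
    given ``config.seed``; a run resumed from a saved checkpoint replays
    the uninterrupted run bit-for-bit because the sampler RNG state is
    part of the checkpoint.
    """
    if config.mode == "nbcm" and norm_params is None:
        norm_params = NormalizationParams()

    rng = np.random.default_rng(config.seed)
    rng_init, rng_draw = rng.spawn(2)

    if isinstance(patches, PatchSet):
        bank: np.ndarray | None = patches.data
    elif isinstance(patches, np.ndarray):
        bank = patches
    else:
        bank = None
        stream: Iterator[np.ndarray] = iter(patches)

    if bank is not None:
        if bank.ndim != 2 or bank.shape[0] == 0:
            raise ValueError("patch bank must be a nonempty (n, d) matrix")
        n_inputs = bank.shape[1]
    else:
        first = next(stream)
        n_inputs = first.shape[0]

    state = initial_state or NetworkState.initialize(
        config.n_neurons, n_inputs, config, rng_init
    )
    if state.weights.shape[1] != n_inputs:
        raise ValueError(
            f"state expects {state.weights.shape[1]} inputs, "
            f"patches have {n_inputs}"
        )
    if state.rng_state is not None:
        rng_draw.bit_generator.state = state.rng_state

    checkpoints: list[NetworkState] = []
    start = state.iteration
    pending_first = None if bank is not None else first
    for k in range(start, start + config.n_iterations):
        if bank is not None:
            patch = bank[rng_draw.integers(bank.shape[0])]
        elif pending_first is not None:
            patch, pending_first = pending_first, None
        else:
            patch = next(stream)

        state.eta = anneal(config.eta0, k, config.anneal_factor,
                           config.anneal_every)
        act = activate(state, patch, config)
        if config.mode == "nbcm":
            act.normalized = normalize(act.output, norm_params)
        c_w = act.effective
        c_t = (
            c_w
            if config.mode == "bcm" or config.threshold_uses_normalized
            else act.output
        )
        gain = state.eta * c_w * (c_w - state.thresholds)
        state.weights += np.outer(gain, patch)
        update_threshold(state, c_t, config.tau)
        state.iteration = k + 1

        if log_every and (k + 1) % log_every == 0:
            if not np.all(np.isfinite(state.weights)):
                raise TrainingDiverged(
                    f"weights diverged at iteration {k + 1}", state
                )
            logger.info(
                "iter=%d eta=%.3g mean(theta)=%.3g mean|dm_gain|=%.3g",
                k + 1, state.eta, float(state.thresholds.mean()),
                float(np.abs(gain).mean()),
            )
        if checkpoint_every and (k + 1) % checkpoint_every == 0:
            state.rng_state = rng_draw.bit_generator.state
            checkpoints.append(state.copy())

    if not np.all(np.isfinite(state.weights)):
        raise TrainingDiverged("weights diverged", state)
    state.rng_state = rng_draw.bit_generator.state
    return state, checkpoints
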