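"""Ground-truth population codes for position and heading.

Place-cell targets are posterior probabilities under a mixture of isotropic
2-D Gaussians: cell i with centre c_i and shared scale sigma responds to
position p with

    pcact_i = exp(-||p - c_i||^2 / (2 sigma^2)) / sum_j exp(-||p - c_j||^2 / (2 sigma^2))

i.e. a softmax over negative scaled squared distances.  Head-direction
targets are the analogous posterior under a mixture of Von Mises
distributions with shared concentration kappa:

    hdcact_i = exp(kappa cos(phi - mu_i)) / sum_j exp(kappa cos(phi - mu_j))

Both codes are probability vectors (non-negative, summing to 1) and serve as
soft supervision targets; decoding helpers invert them approximately for
evaluation (activation-weighted mean of centres, circular mean for headings).
Both softmaxes are evaluated with the log-sum-exp trick so small scales or
large concentrations cannot underflow.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import log_softmax

from .arena import ArenaConfig, wrap_angle

__all__ = [
    "PlaceCellEnsemble",
    "HeadDirectionEnsemble",
    "UndefinedHeadingError",
    "init_place_centers",
    "init_hd_centers",
    "place_activations",
    "hd_activations",
    "decode_position",
    "decode_heading",
]


class UndefinedHeadingError(ValueError):
    """Raised when an activation vector has no resolvable mean direction."""


@dataclass(frozen=True)
class PlaceCellEnsemble:
    """Fixed set of place-cell centres (N x 2, metres) with shared scale (m)."""

    centers: np.ndarray
    scale: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.atleast_2d(np.asarray(self.centers, float)))
        if self.scale <= 0:
            raise ValueError("place-cell scale must be positive")

    @property
    def n_cells(self) -> int:
        return self.centers.shape[0]

    def to_dict(self) -> dict:
        return {"centers": self.centers.tolist(), "scale": self.scale}

    @classmethod
    def from_dict(cls, d: dict) -> "PlaceCellEnsemble":
        return cls(np.asarray(d["centers"]), float(d["scale"]))


@dataclass(frozen=True)
class HeadDirectionEnsemble:
    """Fixed set of preferred angles (rad) with shared Von Mises concentration."""

    centers: np.ndarray
    concentration: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "centers", np.atleast_1d(np.asarray(self.centers, float)))
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")

    @property
    def n_cells(self) -> int:
        return self.centers.shape[0]

    def to_dict(self) -> dict:
        return {"centers": self.centers.tolist(), "concentration": self.concentration}

    @classmethod
    def from_dict(cls, d: dict) -> "HeadDirectionEnsemble":
        return cls(np.asarray(d["centers"]), float(d["concentration"]))


def init_place_centers(
    n: int,
    arena: ArenaConfig,
    rng: np.random.Generator,
    scale: float = 0.35,
) -> PlaceCellEnsemble:
    """Scatter ``n`` place-cell centres uniformly over the arena square.

    ``scale`` (the Gaussian spread, metres) is fixed for the lifetime of the
    ensemble; 0.35 m gives place fields roughly a tenth of the arena wide.
    """
    if n < 1:
        raise ValueError("need at least one place cell")
    centers = rng.uniform(-arena.half_width, arena.half_width, size=(n, 2))
    return PlaceCellEnsemble(centers, scale)


def init_hd_centers(
    m: int,
    rng: np.random.Generator,
    concentration: float = 20.0,
) -> HeadDirectionEnsemble:
    """Assign ``m`` preferred facing angles uniformly on (-pi, pi]."""
    if m < 1:
        raise ValueError("need at least one head-direction cell")
    centers = np.pi - rng.uniform(0.0, 2.0 * np.pi, size=m)
    return HeadDirectionEnsemble(centers, concentration)


def place_activations(pos, ens: PlaceCellEnsemble) -> np.ndarray:
    """Place-code probability vector(s) for position(s) ``pos``.

    ``pos`` is a length-2 vector or an (..., 2) array; the result appends an
    axis of length N (one probability per cell), each slice summing to 1.
    """
    pos = np.asarray(pos, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("position must be finite")
    diff = pos[..., None, :] - ens.centers  # (..., N, 2)
    logits = -np.sum(diff * diff, axis=-1) / (2.0 * ens.scale**2)
    return np.exp(log_softmax(logits, axis=-1))


def hd_activations(heading, ens: HeadDirectionEnsemble) -> np.ndarray:
    """Head-direction probability vector(s) for heading(s) in radians."""
    heading = np.asarray(heading, dtype=float)
    if not np.all(np.isfinite(heading)):
        raise ValueError("heading must be finite")
    logits = ens.concentration * np.cos(heading[..., None] - ens.centers)
    return np.exp(log_softmax(logits, axis=-1))


def decode_position(act: np.ndarray, ens: PlaceCellEnsemble) -> np.ndarray:
    """Activation-weighted mean of the place-cell centres."""
    act = np.asarray(act, dtype=float)
    return act @ ens.centers


def decode_heading(act: np.ndarray, ens: HeadDirectionEnsemble) -> float | np.ndarray:
    """Circular mean of the preferred angles weighted by the activations.

    Raises :class:`UndefinedHeadingError` when the resultant vector vanishes
    (e.g. equal weight on two opposite directions plus nothing else).
    """
    act = np.asarray(act, dtype=float)
    s = act @ np.sin(ens.centers)
    c = act @ np.cos(ens.centers)
    if np.any(np.hypot(s, c) < 1e-12):
        raise UndefinedHeadingError("zero resultant vector: heading undefined")
    angle = wrap_angle(np.arctan2(s, c))
    return float(angle) if act.ndim == 1 else angle
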