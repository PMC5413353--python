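"""Synthetic generators for coupled orientations and co-localized intensities.

Two models produce fixture data with a known mix of global bias and local
interaction.

Co-orientation: marginals X, Y are truncated normals on (-90, 90) with mean
mu and pre-truncation standard deviation sigma. The narrower the marginals,
the stronger the global bias. A local interaction then shifts one member of
each pair toward the other, along the shortest axial arc, by zeta_i degrees;
which member moves is a fair Bernoulli coin per pair. zeta_i is either
proportional, zeta_i = alpha * theta_i with theta_i the pre-interaction
alignment angle and |alpha| <= 1 (alpha = 1 collapses every pair, alpha < 0
pushes pairs apart), or a constant zeta capped at theta_i so the shifted
angle never overshoots its partner.

Co-localization: x_i ~ truncated Normal(mu_x, sigma_x) on [0, 1]; an
interacting pair satisfies y_i = x_i * zeta_i with zeta_i ~ Normal(mu_zeta,
sigma_zeta) — mean 1 models a one-to-one interaction, larger sigma_zeta a
weaker one. A non-interacting pair draws y_i independently from its own
truncated normal. ``interacting_fraction`` selects how many pairs interact.

All randomness flows through one seeded generator per call, consumed in a
fixed order (x draws, y draws, coin flips / zeta draws, subgroup choice), so
a single seed reproduces the whole dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy import stats

from .core import PairedSample, alignment_angle, wrap_orientation

__all__ = [
    "OrientationSimConfig",
    "ColocSimConfig",
    "sample_truncated_normal",
    "simulate_coorientation",
    "simulate_colocalization",
]


def sample_truncated_normal(
    mu: float,
    sigma: float,
    low: float,
    high: float,
    n: int,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw n values from Normal(mu, sigma) conditioned on (low, high).

    ``sigma`` is the standard deviation *before* truncation; the realized
    spread is smaller whenever the interval clips appreciable mass.
    """
    if not low < high:
        raise ValueError(f"empty interval ({low}, {high})")
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    a, b = (low - mu) / sigma, (high - mu) / sigma
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sigma, size=n, random_state=rng)


@dataclass(frozen=True)
class OrientationSimConfig:
    """Parameters of the co-orientation generator.

    interaction: ("proportional", alpha) with |alpha| <= 1, or
    ("constant", zeta) with zeta >= 0 degrees.
    """

    sigma_x: float
    sigma_y: float
    n: int
    seed: int
    mu: float = 0.0
    interaction: tuple[Literal["proportional", "constant"], float] = ("proportional", 0.0)

    def __post_init__(self) -> None:
        if self.sigma_x <= 0 or self.sigma_y <= 0:
            raise ValueError("sigma_x and sigma_y must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        kind, value = self.interaction
        if kind == "proportional":
            if abs(value) > 1:
                raise ValueError(f"|alpha| must be <= 1, got {value}")
        elif kind == "constant":
            if value < 0:
                raise ValueError(f"constant zeta must be >= 0, got {value}")
        else:
            raise ValueError(f"unknown interaction kind {kind!r}")

    def to_dict(self) -> dict:
        kind, value = self.interaction
        return {
            "model": "orientation",
            "mu": self.mu,
            "sigma_x": self.sigma_x,
            "sigma_y": self.sigma_y,
            "interaction": {"kind": kind, "value": value},
            "n": self.n,
            "seed": self.seed,
        }


@dataclass(frozen=True)
class ColocSimConfig:
    """Parameters of the multiplicative co-localization generator."""

    sigma_x: float
    n: int
    seed: int
    mu_x: float = 0.5
    mu_zeta: float = 1.0
    sigma_zeta: float = 0.0
    interacting_fraction: float = 1.0
    sigma_y_noninteracting: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.mu_x < 1:
            raise ValueError("mu_x must lie in (0, 1)")
        if self.sigma_x <= 0:
            raise ValueError("sigma_x must be positive")
        if self.sigma_zeta < 0:
            raise ValueError("sigma_zeta must be >= 0")
        if not 0 <= self.interacting_fraction <= 1:
            raise ValueError("interacting_fraction must lie in [0, 1]")
        if self.sigma_y_noninteracting is not None and self.sigma_y_noninteracting <= 0:
            raise ValueError("sigma_y_noninteracting must be positive")
        if self.n < 1:
            raise ValueError("n must be >= 1")

    @property
    def sigma_y(self) -> float:
        return self.sigma_y_noninteracting if self.sigma_y_noninteracting is not None else self.sigma_x

    def to_dict(self) -> dict:
        return {
            "model": "colocalization",
            "mu_x": self.mu_x,
            "sigma_x": self.sigma_x,
            "mu_zeta": self.mu_zeta,
            "sigma_zeta": self.sigma_zeta,
            "interacting_fraction": self.interacting_fraction,
            "sigma_y_noninteracting": self.sigma_y,
            "n": self.n,
            "seed": self.seed,
        }


def _axial_step(start: np.ndarray, target: np.ndarray, step: np.ndarray) -> np.ndarray:
    """Move orientations toward (step > 0) or away from (step < 0) a partner.

    The move follows the shortest axial arc between the two orientations
    (mod 180), and the result is wrapped back into [-90, 90]. For pairs with
    |start - target| <= 90 a positive step reproduces the linear
    max(start - z, target) / min(start + z, target) update; for wrap-around
    pairs the arc crosses the +/-90 boundary. |step| never exceeds the
    axial alignment angle, so attraction cannot overshoot the partner.
    """
    d = (target - start + 90.0) % 180.0 - 90.0  # signed axial offset in (-90, 90]
    direction = np.where(d >= 0, 1.0, -1.0)
    moved = wrap_orientation(start + direction * step)
    # zero step returns start bitwise (wrapping is not an identity in floats)
    return np.where(step == 0, start, moved)


def simulate_coorientation(config: OrientationSimConfig) -> PairedSample:
    """Generate matched orientation pairs with a controlled local interaction.

    The interaction co-aligns each pair: one member (a fair coin decides
    which) moves toward the other along the shortest axial arc by zeta_i
    degrees, where zeta_i = alpha * theta_i (proportional; theta_i the
    pre-interaction alignment angle) or zeta_i = min(zeta, theta_i)
    (constant). The post-interaction alignment is therefore theta_i - zeta_i
    exactly. Negative alpha moves the selected member away instead
    (anti-alignment). Returns the post-interaction pairs (x', y'); their
    marginals may differ slightly from the generating truncated normals
    whenever the interaction is active.
    """
    rng = np.random.default_rng(config.seed)
    x = sample_truncated_normal(config.mu, config.sigma_x, -90.0, 90.0, config.n, rng)
    y = sample_truncated_normal(config.mu, config.sigma_y, -90.0, 90.0, config.n, rng)
    move_y = rng.random(config.n) < 0.5

    kind, value = config.interaction
    theta = alignment_angle(x, y)
    if kind == "proportional":
        step = value * theta  # negative value = repulsion
    else:
        step = np.minimum(value, theta)

    x2 = np.where(move_y, x, _axial_step(x, y, step))
    y2 = np.where(move_y, _axial_step(y, x, step), y)
    label = f"sim-orientation({kind}={value}, sigma=({config.sigma_x},{config.sigma_y}))"
    return PairedSample("orientation", x2, y2, label=label)


def simulate_colocalization(config: ColocSimConfig) -> PairedSample:
    """Generate matched intensity pairs via the multiplicative model."""
    rng = np.random.default_rng(config.seed)
    x = sample_truncated_normal(config.mu_x, config.sigma_x, 0.0, 1.0, config.n, rng)
    y = np.empty(config.n)

    n_interacting = int(round(config.interacting_fraction * config.n))
    interacting = np.zeros(config.n, dtype=bool)
    if 0 < n_interacting:
        idx = rng.choice(config.n, size=n_interacting, replace=False)
        interacting[idx] = True

    if n_interacting:
        xi = x[interacting]
        yi = xi * rng.normal(config.mu_zeta, config.sigma_zeta, size=n_interacting)
        if config.sigma_zeta == 0:
            # degenerate zeta: redrawing cannot help, clamp instead
            yi = np.clip(yi, 0.0, 1.0)
        else:
            # redraw zeta where x*zeta escapes [0, 1] (true truncation: no
            # point mass at the boundaries)
            bad = (yi < 0) | (yi > 1)
            while bad.any():
                yi[bad] = xi[bad] * rng.normal(
                    config.mu_zeta, config.sigma_zeta, size=int(bad.sum())
                )
                bad = (yi < 0) | (yi > 1)
        y[interacting] = yi
    n_free = config.n - n_interacting
    if n_free:
        y[~interacting] = sample_truncated_normal(
            config.mu_x, config.sigma_y, 0.0, 1.0, n_free, rng
        )
    label = (
        f"sim-coloc(mu_zeta={config.mu_zeta}, sigma_zeta={config.sigma_zeta}, "
        f"fraction={config.interacting_fraction})"
    )
    return PairedSample("colocalization", x, y, label=label)
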