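"""Random-walk model of gene lifespan.

A gene's fitness performs a +/-1 random walk on the lattice of fixed
substitutions: each fixation moves fitness up by s (beneficial, probability
``alpha``) or down by s (deleterious).  The gene is lost when k more
deleterious than beneficial substitutions have accumulated, i.e. when the walk
first reaches -k.  For alpha < 1/2 absorption is certain and the expected
number of substitutions before loss is k/(1-2*alpha); dividing by the total
fixation rate r_B + r_D converts substitutions to time.

The probability generating function of the total substitution count is the
classic gambler's-ruin first-passage PGF raised to the k-th power.  The PGF
dummy variable is named ``z`` here (the conventional symbol collides with the
selection coefficient).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import ConfigError, DivergentMeanError

__all__ = [
    "WalkModel",
    "WalkResult",
    "ExtinctionTime",
    "extinction_pgf",
    "expected_substitutions",
    "expected_extinction_time",
    "simulate_walk",
]


@dataclass(frozen=True)
class WalkModel:
    """Parameters of the gene-lifespan walk.

    alpha : fraction of fixed substitutions that are beneficial.
    k : loss threshold in net deleterious substitutions (positive integer).
    r_B, r_D : fixation rates of beneficial and deleterious mutations per unit
        time; optional, required only for time (rather than step) results.
        When both are given they must satisfy alpha = r_B/(r_B + r_D).
    """

    alpha: float
    k: int
    r_B: float | None = None
    r_D: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha < 1.0:
            raise ConfigError(f"alpha must lie in [0, 1), got {self.alpha}")
        if int(self.k) != self.k or self.k < 1:
            raise ConfigError(f"k must be a positive integer, got {self.k}")
        if (self.r_B is None) != (self.r_D is None):
            raise ConfigError("r_B and r_D must be supplied together")
        if self.r_B is not None:
            if self.r_B < 0 or self.r_D < 0 or self.r_B + self.r_D <= 0:
                raise ConfigError("rates must be >= 0 with r_B + r_D > 0")
            implied = self.r_B / (self.r_B + self.r_D)
            if abs(implied - self.alpha) > 1e-9:
                raise ConfigError(
                    f"alpha={self.alpha} inconsistent with "
                    f"r_B/(r_B+r_D)={implied:.12g}"
                )

    @classmethod
    def from_rates(cls, k: int, r_B: float, r_D: float) -> "WalkModel":
        if r_B < 0 or r_D < 0 or r_B + r_D <= 0:
            raise ConfigError("rates must be >= 0 with r_B + r_D > 0")
        return cls(alpha=r_B / (r_B + r_D), k=k, r_B=r_B, r_D=r_D)


def extinction_pgf(model: WalkModel, z: float) -> float:
    """PGF V(z) of the total substitution count at loss.

    V(z) = [(1 - sqrt(1 - 4*alpha*(1-alpha)*z^2)) / (2*alpha*z)]^k, evaluated
    in the cancellation-free form [2*(1-alpha)*z / (1 + sqrt(...))]^k (the two
    are algebraically identical).  V(1) is the absorption probability:
    1 for alpha <= 1/2, ((1-alpha)/alpha)^k above.  At alpha = 0 the walk is
    deterministic and V(z) = z^k.
    """
    if not 0.0 < z <= 1.0:
        raise ConfigError(f"z must lie in (0, 1], got {z}")
    a = model.alpha
    if a == 0.0:
        return z**model.k
    disc = 1.0 - 4.0 * a * (1.0 - a) * z * z
    root = 2.0 * (1.0 - a) * z / (1.0 + math.sqrt(max(disc, 0.0)))
    return root**model.k


def expected_substitutions(model: WalkModel) -> float:
    """Expected total substitutions before loss, V'(1) = k/(1 - 2*alpha).

    The printed closed form k/(2^k sqrt(1-4a(1-a))) * [(1-sqrt(1-4a(1-a)))/a]^k
    reduces algebraically to k/(1-2*alpha) for alpha < 1/2 because
    sqrt(1-4a(1-a)) = 1-2a there; the reduction is asserted in the tests.
    Diverges for alpha >= 1/2.
    """
    a = model.alpha
    if a >= 0.5:
        raise DivergentMeanError(
            f"expected substitution count diverges for alpha={a} >= 0.5"
        )
    if a == 0.0:
        return float(model.k)
    d = 1.0 - 2.0 * a  # = sqrt(1 - 4a(1-a)) on this branch
    bracket = 2.0 * (1.0 - a) / (1.0 + d)  # == [(1 - sqrt(disc))/a] / 2
    return model.k / d * bracket**model.k


class ExtinctionTime(NamedTuple):
    """Expected time to gene loss: the small-alpha approximation
    (k/(r_B+r_D)) * (1 + 2*r_B/(r_B+r_D)) and the exact composition
    n_T / (r_B + r_D) = k / ((r_B+r_D)(1-2*alpha))."""

    approx: float
    exact: float


def expected_extinction_time(model: WalkModel) -> ExtinctionTime:
    """Expected time to loss; requires fixation rates.

    The approximate form is the first-order (alpha << 1) expansion and stays
    finite for all alpha < 1; the exact form requires alpha < 1/2.
    """
    if model.r_B is None or model.r_D is None:
        raise ConfigError("fixation rates r_B, r_D are required for time results")
    total = model.r_B + model.r_D
    if total <= 0:
        raise ConfigError("r_B + r_D must be > 0")
    approx = (model.k / total) * (1.0 + 2.0 * model.r_B / total)
    if model.alpha < 0.5:
        exact = expected_substitutions(model) / total
    else:
        exact = math.inf
    return ExtinctionTime(approx=approx, exact=exact)


@dataclass(frozen=True)
class WalkResult:
    n_draws: int
    mean_steps: float
    se_steps: float
    absorbed_fraction: float
    n_censored: int


def simulate_walk(
    model: WalkModel,
    n_draws: int,
    max_steps: int = 10**7,
    seed: int | None = None,
) -> WalkResult:
    """Monte-Carlo oracle: simulate ``n_draws`` walks until absorption at -k.

    Walks still alive after ``max_steps`` are censored and excluded from the
    mean (their count is reported).  Steps are generated in blocks so memory
    stays bounded near alpha = 1/2 where absorption times are heavy-tailed.
    """
    if n_draws < 1:
        raise ConfigError(f"n_draws must be >= 1, got {n_draws}")
    rng = np.random.default_rng(seed)
    a, k = model.alpha, model.k

    if a == 0.0:
        steps = np.full(n_draws, k, dtype=np.int64)
        return WalkResult(n_draws, float(k), 0.0, 1.0, 0)

    pos = np.zeros(n_draws, dtype=np.int64)
    absorbed_at = np.full(n_draws, -1, dtype=np.int64)
    active = np.arange(n_draws)
    t = 0
    block = 256
    while active.size and t < max_steps:
        nb = min(block, max_steps - t)
        inc = np.where(rng.random((active.size, nb)) < a, 1, -1).cumsum(axis=1)
        path = pos[active][:, None] + inc
        hit = path <= -k
        first = hit.argmax(axis=1)
        did = hit[np.arange(active.size), first]
        absorbed_at[active[did]] = t + first[did] + 1
        pos[active] = path[:, -1]
        active = active[~did]
        t += nb

    done = absorbed_at >= 0
    n_abs = int(done.sum())
    if n_abs == 0:
        return WalkResult(n_draws, math.nan, math.nan, 0.0, n_draws)
    steps = absorbed_at[done].astype(float)
    se = float(steps.std(ddof=1) / math.sqrt(n_abs)) if n_abs > 1 else 0.0
    return WalkResult(
        n_draws=n_draws,
        mean_steps=float(steps.mean()),
        se_steps=se,
        absorbed_fraction=n_abs / n_draws,
        n_censored=n_draws - n_abs,
    )
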