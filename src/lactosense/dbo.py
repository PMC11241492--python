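"""Dung Beetle Optimizer (DBO).

Population-based metaheuristic with four behavioural roles inspired by dung
beetles (Xue & Shen 2022):

* **ball-rolling** beetles explore, steering away from the worst known
  position and occasionally "dancing" (tangent-based reorientation) when an
  obstacle is met;
* **brood balls** (reproduction) are resampled inside a region around the
  current-iteration best that shrinks linearly with iteration,
  ``R = 1 - t/T``;
* **foragers** move within the shrinking region around the global best;
* **thieves** contract toward the global best.

The population here is continuous; mixed integer/categorical search spaces
are handled by decoding positions at evaluation time (:func:`decode_position`)
while the dynamics stay continuous.  All positions are clamped into bounds,
and failed or non-finite objective evaluations score ``-inf`` so the search
continues near constraint boundaries (the convention used when tuning
feature-selection pipelines whose stages can fail for some parameter
combinations).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DBOConfig",
    "Incumbents",
    "OptimizationTrace",
    "categorical",
    "decode_position",
    "optimize",
    "update_population",
]

CONTINUOUS = "continuous"
INTEGER = "integer"


def categorical(cardinality: int) -> tuple[str, int]:
    """Dimension-kind token for a categorical variable with the given cardinality."""
    if cardinality < 1:
        raise ValueError("categorical cardinality must be >= 1")
    return ("categorical", int(cardinality))


@dataclass(frozen=True)
class DBOConfig:
    """Search-space and algorithm configuration.

    ``role_fractions`` are (rolling, foraging, stealing, reproducing) and must
    sum to 1; with the default population of 50 they resolve to 10/20/10/10
    beetles.  ``k`` (defection coefficient), ``b`` (light-intensity
    coefficient), ``S`` (thief scale) and ``obstacle_prob`` follow the
    original algorithm's defaults.
    """

    bounds: tuple[tuple[float, float], ...]
    pop_size: int = 50
    role_fractions: tuple[float, float, float, float] = (0.20, 0.40, 0.20, 0.20)
    max_iter: int = 100
    dim_kinds: tuple | None = None
    seed: int = 0
    k: float = 0.1
    b: float = 0.3
    S: float = 0.5
    obstacle_prob: float = 0.1

    def __post_init__(self) -> None:
        if self.pop_size < 4:
            raise ValueError("pop_size must be >= 4 (one beetle per role)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not math.isclose(sum(self.role_fractions), 1.0, abs_tol=1e-9):
            raise ValueError(f"role_fractions must sum to 1, got {self.role_fractions}")
        for d, (lo, hi) in enumerate(self.bounds):
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds[{d}] must be finite with low < high, got {(lo, hi)}")
        if self.dim_kinds is not None and len(self.dim_kinds) != len(self.bounds):
            raise ValueError("dim_kinds must match bounds length")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")

    @property
    def dim(self) -> int:
        return len(self.bounds)

    @property
    def low(self) -> np.ndarray:
        return np.asarray([b[0] for b in self.bounds], dtype=float)

    @property
    def high(self) -> np.ndarray:
        return np.asarray([b[1] for b in self.bounds], dtype=float)

    def role_counts(self) -> tuple[int, int, int, int]:
        """Integer role block sizes by largest-remainder rounding."""
        raw = [f * self.pop_size for f in self.role_fractions]
        base = [int(math.floor(r)) for r in raw]
        rem = self.pop_size - sum(base)
        order = sorted(range(4), key=lambda i: raw[i] - base[i], reverse=True)
        for i in order[:rem]:
            base[i] += 1
        return tuple(base)  # type: ignore[return-value]


class Incumbents(NamedTuple):
    """Reference positions for one update round."""

    global_best: np.ndarray  # best-so-far across all iterations
    local_best: np.ndarray  # best of the current population
    worst: np.ndarray  # worst of the current population


@dataclass
class OptimizationTrace:
    best_position_per_iter: np.ndarray  # (max_iter, dim)
    best_fitness_per_iter: np.ndarray  # (max_iter,)
    evaluations: int

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.best_position_per_iter,
            columns=[f"x{d}" for d in range(self.best_position_per_iter.shape[1])],
        )
        df.insert(0, "best_fitness", self.best_fitness_per_iter)
        df.insert(0, "iteration", np.arange(1, len(df) + 1))
        return df

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _shrinking_region(
    center: np.ndarray, R: float, low: np.ndarray, high: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    a = center * (1.0 - R)
    b = center * (1.0 + R)
    lo = np.clip(np.minimum(a, b), low, high)
    hi = np.clip(np.maximum(a, b), low, high)
    return lo, hi


def update_population(
    positions: np.ndarray,
    fitnesses: np.ndarray,
    incumbents: Incumbents,
    iter_index: int,
    config: DBOConfig,
    prev_positions: np.ndarray | None = None,
) -> np.ndarray:
    """One synchronous update of all four role blocks.

    Roles are static index blocks in the order (rolling, foraging, stealing,
    reproducing).  Deterministic given ``config.seed`` and ``iter_index``:
    the per-iteration RNG is derived from both.
    """
    if not 1 <= iter_index <= config.max_iter:
        raise ValueError(f"iter_index must be in [1, {config.max_iter}], got {iter_index}")
    pos = np.asarray(positions, dtype=float)
    prev = pos if prev_positions is None else np.asarray(prev_positions, dtype=float)
    low, high = config.low, config.high
    n_roll, n_forage, n_steal, n_rep = config.role_counts()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, iter_index]))
    R = 1.0 - iter_index / config.max_iter
    Xb, Xs, Xw = incumbents.global_best, incumbents.local_best, incumbents.worst

    new = pos.copy()
    i0 = 0
    # rolling: ball-rolling with random defection sign, tangent dance on obstacles
    sl = slice(i0, i0 + n_roll)
    r = pos[sl]
    alpha = (rng.integers(0, 2, size=(n_roll, 1)) * 2 - 1).astype(float)
    dance = rng.random(n_roll) < config.obstacle_prob
    theta = rng.uniform(0.0, np.pi, size=n_roll)
    rolled = r + alpha * config.k * prev[sl] + config.b * np.abs(r - Xw)
    with np.errstate(over="ignore"):
        danced = r + np.tan(theta)[:, None] * np.abs(r - prev[sl])
    blocked = np.isclose(theta, np.pi / 2)
    danced[blocked] = r[blocked]  # a vertical dance angle leaves the beetle in place
    new[sl] = np.where(dance[:, None], danced, rolled)
    i0 += n_roll

    # foraging: move within the shrinking region around the global best
    sl = slice(i0, i0 + n_forage)
    lo_f, hi_f = _shrinking_region(Xb, R, low, high)
    f = pos[sl]
    C1 = rng.standard_normal((n_forage, config.dim))
    C2 = rng.random((n_forage, config.dim))
    new[sl] = f + C1 * (f - lo_f) + C2 * (f - hi_f)
    i0 += n_forage

    # stealing: contract toward the global best
    sl = slice(i0, i0 + n_steal)
    s = pos[sl]
    g = rng.standard_normal((n_steal, config.dim))
    new[sl] = Xb + config.S * g * (np.abs(s - Xs) + np.abs(s - Xb))
    i0 += n_steal

    # reproduction: brood balls constrained to the region around the local best
    sl = slice(i0, i0 + n_rep)
    lo_r, hi_r = _shrinking_region(Xs, R, low, high)
    b1 = rng.random((n_rep, config.dim))
    b2 = rng.random((n_rep, config.dim))
    off = Xs + b1 * (pos[sl] - lo_r) + b2 * (pos[sl] - hi_r)
    new[sl] = np.clip(off, lo_r, hi_r)

    return np.clip(new, low, high)


def _safe_eval(objective: Callable[[np.ndarray], float], x: np.ndarray) -> float:
    try:
        v = float(objective(x))
    except Exception:
        return -np.inf
    return v if np.isfinite(v) else -np.inf


def optimize(
    objective: Callable[[np.ndarray], float],
    config: DBOConfig,
) -> tuple[np.ndarray, float, OptimizationTrace]:
    """Maximize ``objective`` over the bounded space.

    Returns ``(best_position, best_fitness, trace)``.  The trace records the
    incumbent (best-so-far) after each of the ``max_iter`` update rounds, so
    ``best_fitness_per_iter`` is monotone non-decreasing by construction; the
    incumbent is never replaced by a worse position.
    """
    low, high = config.low, config.high
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    pos = low + rng.random((config.pop_size, config.dim)) * (high - low)
    fits = np.asarray([_safe_eval(objective, x) for x in pos])
    evaluations = config.pop_size
    ib = int(np.argmax(fits))
    gbest_pos, gbest_fit = pos[ib].copy(), float(fits[ib])

    best_positions = np.empty((config.max_iter, config.dim))
    best_fits = np.empty(config.max_iter)
    prev = pos.copy()
    for t in range(1, config.max_iter + 1):
        inc = Incumbents(
            global_best=gbest_pos,
            local_best=pos[int(np.argmax(fits))],
            worst=pos[int(np.argmin(fits))],
        )
        new_pos = update_population(pos, fits, inc, t, config, prev_positions=prev)
        new_fits = np.asarray([_safe_eval(objective, x) for x in new_pos])
        evaluations += config.pop_size
        prev, pos, fits = pos, new_pos, new_fits
        ib = int(np.argmax(fits))
        if fits[ib] > gbest_fit:
            gbest_fit = float(fits[ib])
            gbest_pos = pos[ib].copy()
        best_positions[t - 1] = gbest_pos
        best_fits[t - 1] = gbest_fit

    trace = OptimizationTrace(best_positions, best_fits, evaluations)
    return gbest_pos, gbest_fit, trace


def decode_position(position: Sequence[float], config: DBOConfig) -> tuple:
    """Decode a continuous position into mixed-type parameter values.

    Continuous dimensions pass through; integer dimensions are rounded
    half-up then clamped into the integer part of their bounds; categorical
    dimensions map by floor to an index in ``[0, cardinality)``.
    """
    kinds = config.dim_kinds or (CONTINUOUS,) * config.dim
    out = []
    for x, (lo, hi), kind in zip(position, config.bounds, kinds):
        if kind == CONTINUOUS or kind is None:
            out.append(float(np.clip(x, lo, hi)))
        elif kind == INTEGER:
            v = int(math.floor(x + 0.5))
            out.append(int(np.clip(v, math.ceil(lo), math.floor(hi))))
        elif isinstance(kind, tuple) and kind[0] == "categorical":
            card = int(kind[1])
            out.append(min(max(int(math.floor(x)), 0), card - 1))
        else:
            raise ValueError(f"unknown dimension kind {kind!r}")
    return tuple(out)
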