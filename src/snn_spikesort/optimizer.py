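"""Genetic-algorithm tuning of output-layer and plasticity parameters.

The search mirrors the procedure used to tune the reference system: every
generation each surviving parameter set spawns offspring by multiplying
each parameter by ``1 + u`` with ``u`` uniform in ``[-v, +v]`` (v at most
20%), the four best candidates survive (elitism, so the best fitness never
decreases), and the variation level ``v`` is halved whenever a generation
fails to improve the best fitness by at least 1%.  Only the output-layer
LIF parameters and the STDP constants are searched; the filter bank and
input layer are tuned separately and stay fixed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["GAConfig", "GAResult", "ga_optimize"]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 16
    n_winners: int = 4
    variation_frac: float = 0.20
    generations: int = 20
    improvement_frac: float = 0.01  # relative gain below which v is halved
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_winners < 1 or self.n_winners > self.population_size:
            raise ConfigurationError("need 1 <= n_winners <= population_size")
        if not 0.0 <= self.variation_frac <= 0.20:
            raise ConfigurationError("variation_frac must be in [0, 0.2]")
        if self.generations < 1:
            raise ConfigurationError("generations must be >= 1")


@dataclass
class GAResult:
    best_params: dict[str, float]
    best_fitness: float
    history: list[float]  # best fitness after each generation, non-decreasing


def _mutate(
    params: dict[str, float],
    v: float,
    rng: np.random.Generator,
    bounds: dict[str, tuple[float, float]] | None,
) -> dict[str, float]:
    out = {}
    for name, value in params.items():
        x = value * (1.0 + rng.uniform(-v, v))
        lo, hi = (bounds or {}).get(name, (0.0, math.inf))
        lo = max(lo, 0.0)
        clipped = min(max(x, lo), hi)
        if clipped != x:
            warnings.warn(f"parameter {name} clipped to {clipped}", stacklevel=3)
        # multiplicative mutation keeps strictly positive params positive
        out[name] = clipped if clipped > 0 else value
    return out


def ga_optimize(
    base_params: dict[str, float],
    fitness,
    config: GAConfig | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
) -> GAResult:
    """Maximize ``fitness(params)`` by mutation-and-selection.

    ``fitness`` must be deterministic for a given parameter set (fix its
    own seed internally); non-finite fitness values discard the candidate
    with a warning.  Returns the best-ever parameters together with the
    per-generation best-fitness trace.
    """
    config = config or GAConfig()
    rng = np.random.default_rng(config.seed)

    def safe_eval(p: dict[str, float]) -> float | None:
        f = float(fitness(p))
        if not math.isfinite(f):
            warnings.warn("non-finite fitness; candidate discarded", stacklevel=2)
            return None
        return f

    base_fit = safe_eval(dict(base_params))
    if base_fit is None:
        raise ValueError("fitness of the base parameters is not finite")
    winners: list[tuple[dict[str, float], float]] = [(dict(base_params), base_fit)]
    best_params, best_fit = dict(base_params), base_fit
    v = config.variation_frac
    history: list[float] = []

    for _gen in range(config.generations):
        per_winner = max(1, config.population_size // config.n_winners)
        candidates = list(winners)
        for parent, _f in winners:
            for _ in range(per_winner):
                child = _mutate(parent, v, rng, bounds)
                f = safe_eval(child)
                if f is not None:
                    candidates.append((child, f))
        candidates.sort(key=lambda c: -c[1])
        winners = candidates[: config.n_winners]
        gen_best = winners[0][1]
        improvement = gen_best - best_fit
        threshold = config.improvement_frac * max(abs(best_fit), 1e-12)
        if improvement < threshold:
            v /= 2.0
        if gen_best > best_fit:
            best_params, best_fit = dict(winners[0][0]), gen_best
        history.append(best_fit)
    return GAResult(best_params, best_fit, history)
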