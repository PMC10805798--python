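"""Random, grid and manual hyperparameter search at matched budgets.

All strategies consume the same objective callable and
:class:`~myotune.bayesopt.SearchSpace`, and emit the same
:class:`~myotune.bayesopt.OptimTrace`, so they are directly comparable with
the Bayesian optimiser.
"""

from __future__ import annotations

import math
import time
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .bayesopt import (
    Evaluation,
    HyperParams,
    OptimTrace,
    SearchSpace,
    _timed_eval,
    default_search_space,
)
from .exceptions import ConfigError


def random_search(
    objective: Callable[[dict], float],
    space: SearchSpace,
    budget: int,
    seed: int = 0,
) -> OptimTrace:
    """Independent uniform draws on each dimension's scale.

    Log dimensions are sampled log-uniformly; integer dimensions uniformly
    over the feasible integers.  Deterministic given ``seed``.
    """
    if budget < 1:
        raise ConfigError("budget must be >= 1")
    rng = np.random.default_rng(seed)
    trace = OptimTrace()
    for i in range(budget):
        x = {}
        for d in space.dimensions:
            if d.kind == "integer":
                x[d.name] = int(rng.integers(int(d.low), int(d.high) + 1))
            elif d.scale == "log":
                x[d.name] = float(
                    math.exp(rng.uniform(math.log(d.low), math.log(d.high)))
                )
            else:
                x[d.name] = float(rng.uniform(d.low, d.high))
        trace.evaluations.append(_timed_eval(objective, x, i, trace.evaluations))
    return trace


def default_grid(space: Optional[SearchSpace] = None) -> dict[str, list]:
    """5 learning rates x 3 momenta x 7 L2 strengths x 2 depths = 210 points."""
    if space is None:
        space = default_search_space()
    dims = {d.name: d for d in space.dimensions}
    lr = dims["learning_rate"]
    mo = dims["momentum"]
    l2 = dims["l2_strength"]
    return {
        "learning_rate": list(np.geomspace(lr.low, lr.high, 5)),
        "momentum": list(np.linspace(mo.low, mo.high, 3)),
        "l2_strength": list(np.geomspace(l2.low, l2.high, 7)),
        "section_depth": [2, 3],
    }


def grid_search(
    objective: Callable[[dict], float],
    grid: Mapping[str, Sequence],
    space: Optional[SearchSpace] = None,
) -> OptimTrace:
    """Exhaustive evaluation of the grid in deterministic (row-major) order."""
    names = list(grid.keys())
    if not names or any(len(v) == 0 for v in grid.values()):
        raise ConfigError("grid must be nonempty in every dimension")
    if space is not None:
        dims = {d.name: d for d in space.dimensions}
        for name, values in grid.items():
            if name not in dims:
                raise ConfigError(f"grid dimension {name!r} not in search space")
            d = dims[name]
            for v in values:
                if not d.low - 1e-12 <= v <= d.high + 1e-12:
                    raise ConfigError(
                        f"grid value {name}={v} outside bounds [{d.low}, {d.high}]"
                    )
    trace = OptimTrace()
    shape = [len(grid[n]) for n in names]
    for i, flat in enumerate(np.ndindex(*shape)):
        x = {n: grid[n][j] for n, j in zip(names, flat)}
        trace.evaluations.append(_timed_eval(objective, x, i, trace.evaluations))
    return trace


def evaluate_manual(
    objective: Callable[[dict], float],
    x: dict | HyperParams,
    space: Optional[SearchSpace] = None,
) -> Evaluation:
    """Single evaluation of an empirically chosen configuration."""
    xd = x.to_dict() if isinstance(x, HyperParams) else dict(x)
    if space is not None and not space.contains(xd):
        raise ConfigError(f"manual point {xd} outside the search space")
    t0 = time.perf_counter()
    y = float(objective(xd))
    return Evaluation(xd, y, max(time.perf_counter() - t0, 1e-9), 0)


def compare_strategies(
    objective_factory: Callable[[int], Callable[[dict], float]],
    strategies: Sequence[str],
    budgets: Mapping[str, int],
    seeds: Sequence[int],
    space: Optional[SearchSpace] = None,
    grid: Optional[Mapping[str, Sequence]] = None,
    manual_point: Optional[dict | HyperParams] = None,
    bayes_cfg=None,
) -> pd.DataFrame:
    """Run each strategy on every objective instance and tabulate best targets.

    ``objective_factory(i)`` yields the objective for subject/instance ``i``
    (one per seed).  Returns one row per strategy with the mean and std of
    the best objective, the evaluation count, and logged wall time.
    """
    from .bayesopt import run_bayesopt  # local import to avoid cycle at module load

    if len(strategies) < 2:
        raise ConfigError("compare_strategies needs at least two strategies")
    if space is None:
        space = default_search_space()
    rows = []
    for strat in strategies:
        bests, n_evals, times = [], [], []
        for i, seed in enumerate(seeds):
            objective = objective_factory(i)
            t0 = time.perf_counter()
            if strat == "bayes":
                trace = run_bayesopt(
                    objective, space, budget=budgets.get(strat, 30),
                    cfg=bayes_cfg, seed=seed,
                )
            elif strat == "random":
                trace = random_search(
                    objective, space, budgets.get(strat, 30), seed=seed
                )
            elif strat == "grid":
                trace = grid_search(objective, grid or default_grid(space), space)
            elif strat == "manual":
                if manual_point is None:
                    raise ConfigError("manual strategy needs manual_point")
                ev = evaluate_manual(objective, manual_point, space)
                trace = OptimTrace(evaluations=[ev])
            else:
                raise ConfigError(f"unknown strategy {strat!r}")
            bests.append(trace.best_y)
            n_evals.append(len(trace.evaluations))
            times.append(time.perf_counter() - t0)
        rows.append(
            {
                "strategy": strat,
                "best_mean": float(np.mean(bests)),
                "best_std": float(np.std(bests, ddof=1)) if len(bests) > 1 else 0.0,
                "best_min": float(np.min(bests)),
                "evaluations_mean": float(np.mean(n_evals)),
                "wall_time_s_mean": float(np.mean(times)),
            }
        )
    return pd.DataFrame(rows)
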