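"""Bayesian optimisation of CNN hyperparameters, written from first principles.

A Gaussian-process surrogate (anisotropic Matern 5/2 kernel, parameters
fitted by maximising the log marginal likelihood) models the validation
classification error over the normalised search space.  Candidates are
proposed by maximising expected improvement (EI) — or EI per second when a
timing model is attached — over scrambled low-discrepancy candidates plus
coordinate-wise local refinement.  An over-exploitation guard rejects
proposals whose latent posterior deviation ``sigma_F(x)`` falls below
``noise_sigma * t_sigma`` and re-proposes from a surrogate whose kernel
roughness has been inflated by the iteration count, which raises the
posterior variance between observations.

Search-space points are plain ``dict``s keyed by dimension name; the
canonical four-dimensional CNN space (learning rate and L2 strength on a
log scale, momentum linear, section depth integer) is available from
:func:`default_search_space`, with :class:`HyperParams` as its typed view.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize as spo
from scipy.stats import norm, qmc

from .exceptions import ConfigError, DataError, GPConditioningError

# ---------------------------------------------------------------------------
# search space


@dataclass(frozen=True)
class Dimension:
    name: str
    low: float
    high: float
    scale: str = "linear"  # {"linear", "log"}
    kind: str = "real"  # {"real", "integer"}

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ConfigError(f"{self.name}: low must be < high")
        if self.scale not in ("linear", "log"):
            raise ConfigError(f"{self.name}: unknown scale {self.scale!r}")
        if self.kind not in ("real", "integer"):
            raise ConfigError(f"{self.name}: unknown kind {self.kind!r}")
        if self.scale == "log" and self.low <= 0:
            raise ConfigError(f"{self.name}: log scale requires low > 0")

    def to_unit(self, v: float) -> float:
        if self.scale == "log":
            u = (math.log(v) - math.log(self.low)) / (
                math.log(self.high) - math.log(self.low)
            )
        else:
            u = (v - self.low) / (self.high - self.low)
        if not -1e-9 <= u <= 1 + 1e-9:
            raise ConfigError(f"{self.name}={v} outside bounds [{self.low}, {self.high}]")
        return min(max(u, 0.0), 1.0)

    def from_unit(self, u: float) -> float:
        u = min(max(float(u), 0.0), 1.0)
        if self.scale == "log":
            v = math.exp(
                math.log(self.low) + u * (math.log(self.high) - math.log(self.low))
            )
        else:
            v = self.low + u * (self.high - self.low)
        if self.kind == "integer":
            return int(round(min(max(v, self.low), self.high)))
        return float(min(max(v, self.low), self.high))


@dataclass(frozen=True)
class SearchSpace:
    dimensions: tuple[Dimension, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "dimensions", tuple(self.dimensions))

    @property
    def names(self) -> list[str]:
        return [d.name for d in self.dimensions]

    def __len__(self) -> int:
        return len(self.dimensions)

    def contains(self, x: dict) -> bool:
        try:
            self.encode(x)
        except ConfigError:
            return False
        return True

    def encode(self, x: dict | "HyperParams") -> np.ndarray:
        if isinstance(x, HyperParams):
            x = x.to_dict()
        return np.array([d.to_unit(x[d.name]) for d in self.dimensions])

    def decode(self, u: Sequence[float]) -> dict:
        return {d.name: d.from_unit(ui) for d, ui in zip(self.dimensions, u)}

    def canonical(self, u: Sequence[float]) -> np.ndarray:
        """Snap a unit point to the representable grid (integer dims)."""
        return self.encode(self.decode(u))

    def canonical_batch(self, U: np.ndarray) -> np.ndarray:
        """Vectorised :meth:`canonical` over rows of ``U``."""
        U = np.clip(np.asarray(U, dtype=float), 0.0, 1.0)
        out = U.copy()
        for j, d in enumerate(self.dimensions):
            if d.kind == "integer" and d.scale == "linear":
                v = np.round(d.low + U[:, j] * (d.high - d.low))
                out[:, j] = (v - d.low) / (d.high - d.low)
            elif d.kind == "integer":
                out[:, j] = [d.to_unit(d.from_unit(x)) for x in U[:, j]]
        return out


def default_search_space() -> SearchSpace:
    """The four-dimensional CNN hyperparameter space."""
    return SearchSpace(
        (
            Dimension("learning_rate", 1e-4, 1e-2, scale="log"),
            Dimension("momentum", 0.8, 0.98, scale="linear"),
            Dimension("l2_strength", 1e-10, 1e-1, scale="log"),
            Dimension("section_depth", 1, 3, scale="linear", kind="integer"),
        )
    )


@dataclass(frozen=True)
class HyperParams:
    """One candidate point in the canonical CNN search space."""

    learning_rate: float
    momentum: float
    l2_strength: float
    section_depth: int

    def to_dict(self) -> dict:
        return {
            "learning_rate": self.learning_rate,
            "momentum": self.momentum,
            "l2_strength": self.l2_strength,
            "section_depth": int(self.section_depth),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "HyperParams":
        return cls(
            learning_rate=float(d["learning_rate"]),
            momentum=float(d["momentum"]),
            l2_strength=float(d["l2_strength"]),
            section_depth=int(d["section_depth"]),
        )


def encode_point(x: dict | HyperParams, space: SearchSpace) -> np.ndarray:
    """Map a feasible point to the unit cube (log dims log-linearly)."""
    return space.encode(x)


def decode_point(u: Sequence[float], space: SearchSpace) -> dict:
    """Inverse of :func:`encode_point`; integer dims round to feasible values."""
    return space.decode(u)


# ---------------------------------------------------------------------------
# Gaussian-process surrogate


def _matern52(
    A: np.ndarray, B: np.ndarray, length_scales: np.ndarray, amplitude: float
) -> np.ndarray:
    d = (A[:, None, :] - B[None, :, :]) / length_scales[None, None, :]
    r = np.sqrt(np.maximum((d * d).sum(axis=2), 0.0))
    sr = math.sqrt(5.0) * r
    return amplitude**2 * (1.0 + sr + sr * sr / 3.0) * np.exp(-sr)


class GPSurrogate:
    """GP posterior over the normalised search space.

    ``theta`` is the kernel parameter vector: the per-dimension inverse
    length scales (roughness) followed by the signal amplitude.  Targets are
    standardised internally; ``noise_sigma`` is reported on the original
    target scale.
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        length_scales: np.ndarray,
        amplitude: float,
        noise: float,
    ):
        self.X = np.atleast_2d(np.asarray(X, dtype=float))
        self.y = np.asarray(y, dtype=float)
        if len(self.y) != len(self.X):
            raise DataError("X/y length mismatch")
        self.length_scales = np.asarray(length_scales, dtype=float)
        self.amplitude = float(amplitude)
        self.noise = float(noise)  # std on the standardised target scale
        self.ym = float(self.y.mean())
        ys = float(self.y.std())
        self.ys = ys if ys > 1e-12 else 1.0
        self._factorise()

    def _factorise(self) -> None:
        z = (self.y - self.ym) / self.ys
        K = _matern52(self.X, self.X, self.length_scales, self.amplitude)
        n = len(self.X)
        jitter = 1e-10
        for _ in range(8):
            try:
                self._L = np.linalg.cholesky(
                    K + (self.noise**2 + jitter) * np.eye(n)
                )
                break
            except np.linalg.LinAlgError:
                jitter *= 100.0
        else:
            raise GPConditioningError("covariance not positive definite")
        self._alpha = np.linalg.solve(
            self._L.T, np.linalg.solve(self._L, z)
        )

    # -- interface --------------------------------------------------------
    @property
    def theta(self) -> np.ndarray:
        """Kernel parameters: inverse length scales per dimension + amplitude."""
        return np.concatenate([1.0 / self.length_scales, [self.amplitude]])

    @property
    def noise_sigma(self) -> float:
        """Posterior std of the additive observation noise (original scale)."""
        return self.noise * self.ys

    def posterior(self, U: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and latent std ``sigma_F`` at unit-cube points."""
        U = np.atleast_2d(np.asarray(U, dtype=float))
        Ks = _matern52(U, self.X, self.length_scales, self.amplitude)
        mu = Ks @ self._alpha
        v = np.linalg.solve(self._L, Ks.T)
        var = self.amplitude**2 - (v * v).sum(axis=0)
        sigma_f = np.sqrt(np.maximum(var, 0.0))
        return self.ym + self.ys * mu, self.ys * sigma_f

    def sigma_q(self, U: np.ndarray) -> np.ndarray:
        """Total predictive deviation: sigma_Q^2 = sigma_F^2 + sigma^2."""
        _, sf = self.posterior(U)
        return np.sqrt(sf**2 + self.noise_sigma**2)

    def with_length_scales(self, length_scales: np.ndarray) -> "GPSurrogate":
        return GPSurrogate(
            self.X, self.y, length_scales, self.amplitude, self.noise
        )


@dataclass
class Evaluation:
    """One objective evaluation: point, target and wall-clock cost."""

    x: dict
    y: float
    cost_s: float = 1.0
    iteration: int = 0
    failed: bool = False


def _neg_log_marginal_likelihood(
    log_params: np.ndarray, X: np.ndarray, z: np.ndarray
) -> float:
    D = X.shape[1]
    ls = np.exp(log_params[:D])
    amp = math.exp(log_params[D])
    noise = math.exp(log_params[D + 1])
    K = _matern52(X, X, ls, amp) + (noise**2 + 1e-10) * np.eye(len(X))
    try:
        L = np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        return 1e10
    alpha = np.linalg.solve(L.T, np.linalg.solve(L, z))
    return float(
        0.5 * z @ alpha + np.log(np.diag(L)).sum() + 0.5 * len(z) * math.log(2 * math.pi)
    )


def fit_gp(
    evals: Sequence[Evaluation],
    space: SearchSpace,
    seed: int = 0,
    n_restarts: int = 2,
) -> GPSurrogate:
    """Fit kernel and noise by maximising the marginal likelihood.

    Requires at least two finite-target evaluations.  Deterministic given
    ``seed`` (which drives the restart starting points).
    """
    ys = [e.y for e in evals]
    if len(evals) < 2 or not all(map(math.isfinite, ys)):
        raise DataError("fit_gp needs >= 2 evaluations with finite targets")
    X = np.stack([space.encode(e.x) for e in evals])
    y = np.array(ys, dtype=float)
    ym, ysd = y.mean(), y.std()
    z = (y - ym) / (ysd if ysd > 1e-12 else 1.0)

    D = X.shape[1]
    rng = np.random.default_rng(seed)
    bounds = [(math.log(0.03), math.log(30.0))] * D + [
        (math.log(1e-3), math.log(10.0)),
        (math.log(1e-4), math.log(2.0)),
    ]
    starts = [np.concatenate([np.full(D, math.log(0.5)), [0.0, math.log(0.1)]])]
    for _ in range(max(0, n_restarts)):
        starts.append(
            np.array([lo + rng.random() * (hi - lo) for lo, hi in bounds])
        )
    best: tuple[float, np.ndarray] | None = None
    for x0 in starts:
        res = spo.minimize(
            _neg_log_marginal_likelihood,
            x0,
            args=(X, z),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 80},
        )
        val = float(res.fun)
        if best is None or val < best[0]:
            best = (val, res.x)
    p = best[1]
    return GPSurrogate(
        X, y, np.exp(p[:D]), math.exp(p[D]), math.exp(p[D + 1])
    )


def incumbent_best(gp: GPSurrogate) -> float:
    """Lowest posterior mean over the evaluated points (not the min observed y)."""
    if gp is None:
        raise DataError("incumbent_best requires a fitted surrogate")
    mu, _ = gp.posterior(gp.X)
    return float(mu.min())


# ---------------------------------------------------------------------------
# acquisition


def expected_improvement(
    mu: np.ndarray | float, sigma_F: np.ndarray | float, best: float
) -> np.ndarray | float:
    """Closed-form EI for minimisation: E[max(0, best - f(x))].

    ``delta * Phi(delta/sigma) + sigma * phi(delta/sigma)`` with
    ``delta = best - mu``; the ``sigma -> 0`` limit is ``max(0, delta)``.
    """
    mu_arr = np.asarray(mu, dtype=float)
    s_arr = np.asarray(sigma_F, dtype=float)
    if np.any(s_arr < 0):
        raise DataError("sigma_F must be >= 0")
    delta = best - mu_arr
    with np.errstate(divide="ignore", invalid="ignore"):
        zscore = np.where(s_arr > 0, delta / np.where(s_arr > 0, s_arr, 1.0), 0.0)
        ei = np.where(
            s_arr > 0,
            delta * norm.cdf(zscore) + s_arr * norm.pdf(zscore),
            np.maximum(delta, 0.0),
        )
    ei = np.maximum(ei, 0.0)
    return float(ei) if np.isscalar(mu) or mu_arr.ndim == 0 else ei


class TimingModel:
    """GP over log evaluation cost; posterior mean exp-transformed as mu_S."""

    #: positivity floor for the predicted cost (seconds)
    COST_FLOOR = 1e-3

    def __init__(self, evals: Sequence[Evaluation], space: SearchSpace, seed: int = 0):
        costs = np.array([max(e.cost_s, 1e-9) for e in evals], dtype=float)
        if np.any(costs <= 0):
            raise DataError("cost_s must be > 0")
        log_evals = [
            Evaluation(e.x, math.log(c), e.cost_s) for e, c in zip(evals, costs)
        ]
        self._gp = fit_gp(log_evals, space, seed=seed)
        self.floored_events = 0

    def mu_s(self, U: np.ndarray) -> np.ndarray:
        mu, _ = self._gp.posterior(U)
        cost = np.exp(mu)
        floored = cost < self.COST_FLOOR
        self.floored_events += int(np.count_nonzero(floored))
        return np.maximum(cost, self.COST_FLOOR)


def expected_improvement_per_second(
    U: np.ndarray, gp: GPSurrogate, timing: TimingModel, best: float
) -> np.ndarray:
    """EI(x) divided by the positive predicted evaluation cost mu_S(x)."""
    mu, sf = gp.posterior(U)
    return np.asarray(expected_improvement(mu, sf, best)) / timing.mu_s(U)


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition settings; ``t_sigma`` is the exploration ratio."""

    kind: str = "EI"  # {"EI", "EIpS"}
    t_sigma: float = 0.5
    n_candidates: int = 2048
    n_local_refinements: int = 3
    max_escape_retries: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("EI", "EIpS"):
            raise ConfigError(f"unknown acquisition {self.kind!r}")
        if self.t_sigma <= 0:
            raise ConfigError("t_sigma must be > 0")
        if self.n_candidates < 1:
            raise ConfigError("n_candidates must be >= 1")


def check_overexploitation(
    u: np.ndarray, gp: GPSurrogate, cfg: AcquisitionConfig
) -> bool:
    """True iff the latent deviation satisfies sigma_F(x) < sigma * t_sigma."""
    _, sf = gp.posterior(np.atleast_2d(u))
    return bool(sf[0] < gp.noise_sigma * cfg.t_sigma)


def escape_overexploitation(gp: GPSurrogate, iteration: int) -> GPSurrogate:
    """Inflate the kernel roughness by the iteration count.

    The inverse-length-scale components of ``theta`` are multiplied by
    ``iteration`` (so the length scales shrink), which raises the posterior
    variance between observations.  The original surrogate is unmodified.
    """
    if iteration < 1:
        raise ConfigError("iteration must be >= 1")
    return gp.with_length_scales(gp.length_scales / float(iteration))


def _acquisition_values(
    U: np.ndarray,
    gp: GPSurrogate,
    cfg: AcquisitionConfig,
    timing: Optional[TimingModel],
    best: float,
) -> np.ndarray:
    if cfg.kind == "EIpS":
        if timing is None:
            raise ConfigError("EIpS acquisition requires a timing model")
        return np.asarray(expected_improvement_per_second(U, gp, timing, best))
    mu, sf = gp.posterior(U)
    return np.asarray(expected_improvement(mu, sf, best))


def propose_next(
    gp: GPSurrogate,
    space: SearchSpace,
    cfg: AcquisitionConfig,
    timing: Optional[TimingModel] = None,
    iteration: int = 1,
    events: Optional[list] = None,
) -> dict:
    """Maximise the acquisition over quasi-random candidates + refinement.

    Applies the over-exploitation check to the winner and, when triggered,
    re-proposes from an escaped surrogate (at most ``max_escape_retries``
    times).  Returns a feasible point; deterministic given ``cfg.seed``.
    """
    best = incumbent_best(gp)
    rng = np.random.default_rng(cfg.seed)

    def search(g: GPSurrogate, sob_seed: int) -> tuple[np.ndarray, float]:
        sobol = qmc.Sobol(d=len(space), scramble=True, seed=sob_seed)
        n = int(2 ** math.ceil(math.log2(max(2, cfg.n_candidates))))
        cand = space.canonical_batch(sobol.random(n))
        vals = _acquisition_values(cand, g, cfg, timing, best)
        if not np.any(vals > 0):
            _, sf = g.posterior(cand)
            if events is not None:
                events.append(("zero_acquisition", iteration))
            i = int(np.argmax(sf))
            return cand[i], 0.0
        order = np.argsort(-vals)[:5]
        top = [(cand[i].copy(), float(vals[i])) for i in order]
        for _ in range(cfg.n_local_refinements):
            for step in (0.1, 0.03, 0.01):
                for t in range(len(top)):
                    u0, v0 = top[t]
                    for d in range(len(space)):
                        for sgn in (1.0, -1.0):
                            u1 = u0.copy()
                            u1[d] = min(max(u1[d] + sgn * step, 0.0), 1.0)
                            u1 = space.canonical(u1)
                            v1 = float(
                                _acquisition_values(u1[None, :], g, cfg, timing, best)[0]
                            )
                            if v1 > v0:
                                u0, v0 = u1, v1
                    top[t] = (u0, v0)
        top.sort(key=lambda t: -t[1])
        return top[0]

    g = gp
    u_star, _ = search(g, int(rng.integers(0, 2**31 - 1)))
    retries = 0
    while (
        check_overexploitation(u_star, gp, cfg) and retries < cfg.max_escape_retries
    ):
        retries += 1
        if events is not None:
            events.append(("over_exploitation", iteration))
        g = escape_overexploitation(g, max(iteration, 2))
        u_star, _ = search(g, int(rng.integers(0, 2**31 - 1)))
    return space.decode(u_star)


# ---------------------------------------------------------------------------
# the optimisation loop


@dataclass
class OptimTrace:
    """Ordered evaluations plus the incumbent and best-so-far curve."""

    evaluations: list[Evaluation] = field(default_factory=list)
    over_exploit_events: list[int] = field(default_factory=list)
    events: list = field(default_factory=list)

    @property
    def best_index(self) -> int:
        ys = [e.y for e in self.evaluations]
        return int(np.argmin(ys))

    @property
    def best_x(self) -> dict:
        return self.evaluations[self.best_index].x

    @property
    def best_y(self) -> float:
        return self.evaluations[self.best_index].y

    @property
    def best_so_far(self) -> np.ndarray:
        return np.minimum.accumulate([e.y for e in self.evaluations])

    def to_records(self) -> list[dict]:
        return [
            {
                "iteration": e.iteration,
                "x": e.x,
                "y": e.y,
                "cost_s": e.cost_s,
                "failed": e.failed,
            }
            for e in self.evaluations
        ]


def _penalty_target(evals: Sequence[Evaluation]) -> float:
    """Target recorded for a failed evaluation: worst + 3 * spread."""
    ys = [e.y for e in evals if not e.failed and math.isfinite(e.y)]
    if not ys:
        return 1.0
    spread = max(ys) - min(ys)
    return max(ys) + 3.0 * (spread if spread > 0 else max(abs(max(ys)), 1e-3))


def _timed_eval(
    objective: Callable[[dict], float], x: dict, iteration: int, evals: list[Evaluation]
) -> Evaluation:
    t0 = time.perf_counter()
    try:
        y = float(objective(x))
        if not math.isfinite(y):
            raise DataError("objective returned non-finite value")
        failed = False
    except Exception:
        y = _penalty_target(evals)
        failed = True
    cost = max(time.perf_counter() - t0, 1e-9)
    return Evaluation(x, y, cost, iteration, failed)


def run_bayesopt(
    objective: Callable[[dict], float],
    space: SearchSpace,
    budget: int = 30,
    cfg: Optional[AcquisitionConfig] = None,
    seed: int = 0,
    init_design: int = 4,
) -> OptimTrace:
    """Full loop: seeded initial design, then fit -> propose -> evaluate.

    Failed objective calls are recorded with a penalty target so the
    surrogate learns to avoid the region.  Deterministic given ``seed``
    (assuming a deterministic objective).
    """
    if cfg is None:
        cfg = AcquisitionConfig()
    if budget < init_design:
        raise ConfigError(f"budget {budget} below initial design size {init_design}")
    rng = np.random.default_rng(seed)
    trace = OptimTrace()

    sobol = qmc.Sobol(d=len(space), scramble=True, seed=int(rng.integers(0, 2**31 - 1)))
    n0 = int(2 ** math.ceil(math.log2(max(2, init_design))))
    init_pts = sobol.random(n0)[:init_design]
    for i, u in enumerate(init_pts):
        x = space.decode(space.canonical(u))
        trace.evaluations.append(_timed_eval(objective, x, i, trace.evaluations))

    timing: Optional[TimingModel] = None
    for it in range(init_design, budget):
        gp = fit_gp(
            trace.evaluations, space, seed=int(rng.integers(0, 2**31 - 1))
        )
        if cfg.kind == "EIpS":
            timing = TimingModel(
                trace.evaluations, space, seed=int(rng.integers(0, 2**31 - 1))
            )
        events: list = []
        step_cfg = AcquisitionConfig(
            kind=cfg.kind,
            t_sigma=cfg.t_sigma,
            n_candidates=cfg.n_candidates,
            n_local_refinements=cfg.n_local_refinements,
            max_escape_retries=cfg.max_escape_retries,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        x = propose_next(gp, space, step_cfg, timing=timing, iteration=it, events=events)
        for kind, iteration in events:
            trace.events.append((kind, iteration))
            if kind == "over_exploitation":
                trace.over_exploit_events.append(iteration)
        trace.evaluations.append(_timed_eval(objective, x, it, trace.evaluations))
    return trace
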