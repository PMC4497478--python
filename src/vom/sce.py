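"""Shuffled complex evolution (SCE-UA) global maximizer.

Standard algorithm: a population partitioned into complexes, each evolved by
the competitive complex evolution step (simplex reflection, contraction, or
random replacement), with periodic shuffling. Deterministic for a fixed
seed. Used here to search the six long-term vegetation constants, but fully
generic.
"""
from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, NamedTuple, Optional, Sequence

import numpy as np

from .errors import ConfigurationError


@dataclasses.dataclass(frozen=True)
class LongTermParams:
    """The six constants optimized at the multi-decadal scale."""

    m_a_p: float          # perennial fractional cover
    y_r_p: float          # perennial max rooting depth (m, multiple of 0.5)
    c_lambda_f_p: float
    c_lambda_e_p: float
    c_lambda_f_s: float
    c_lambda_e_s: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.m_a_p <= 1.0:
            raise ConfigurationError("m_a_p must be in [0, 1]")
        if self.y_r_p < 0.5:
            raise ConfigurationError("y_r_p must be >= 0.5 m")

    def to_array(self) -> np.ndarray:
        return np.array([self.m_a_p, self.y_r_p, self.c_lambda_f_p,
                         self.c_lambda_e_p, self.c_lambda_f_s,
                         self.c_lambda_e_s])

    @classmethod
    def from_array(cls, x: Sequence[float]) -> "LongTermParams":
        return cls(*[float(v) for v in x])

    def snapped(self, z_max: float) -> "LongTermParams":
        """Rooting depth snapped to the 0.5 m layer grid and clipped to the
        column depth."""
        y = min(max(0.5, round(self.y_r_p / 0.5) * 0.5), z_max)
        return dataclasses.replace(self, y_r_p=y)


@dataclasses.dataclass(frozen=True)
class SCEConfig:
    n_complexes: int = 3
    points_per_complex: int = 13   # >= 2*dim + 1
    max_evaluations: int = 3000
    convergence_tolerance: float = 1e-8
    n_convergence_loops: int = 5
    rng_seed: int = 0

    def validate(self, dim: int) -> None:
        if self.n_complexes < 1:
            raise ConfigurationError("n_complexes must be >= 1")
        if self.points_per_complex < 2 * dim + 1:
            raise ConfigurationError(
                f"points_per_complex must be >= 2*dim+1 = {2 * dim + 1}")


class SCEResult(NamedTuple):
    x: np.ndarray
    score: float
    trace: np.ndarray       # (n_eval, dim + 1): params and score per evaluation
    n_evaluations: int


def sce_maximize(objective: Callable[[np.ndarray], float],
                 bounds: Sequence[tuple[float, float]],
                 config: SCEConfig = SCEConfig(),
                 transform: Optional[Callable[[np.ndarray], np.ndarray]] = None,
                 initial_points: Optional[Sequence[Sequence[float]]] = None
                 ) -> SCEResult:
    """Maximize ``objective`` over a box.

    ``transform`` (e.g. a snap-to-grid) is applied to every candidate before
    evaluation, keeping the search itself continuous. ``initial_points``
    are injected into the starting population (used to seed incumbents).
    Non-finite objective values are discarded with a warning (treated as
    -inf). Deterministic under a fixed ``config.rng_seed``.
    """
    lb = np.array([b[0] for b in bounds], dtype=float)
    ub = np.array([b[1] for b in bounds], dtype=float)
    if not np.all(np.isfinite(lb)) or not np.all(np.isfinite(ub)) \
            or np.any(lb >= ub):
        raise ConfigurationError("bounds must be finite with lb < ub")
    dim = lb.size
    config.validate(dim)
    rng = np.random.default_rng(config.rng_seed)

    trace: list[np.ndarray] = []
    n_eval = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal n_eval
        xe = np.clip(x, lb, ub)
        if transform is not None:
            xe = np.clip(np.asarray(transform(xe), dtype=float), lb, ub)
        f = float(objective(xe))
        n_eval += 1
        if not np.isfinite(f):
            warnings.warn("objective returned a non-finite value; discarded")
            f = -np.inf
        trace.append(np.concatenate([xe, [f]]))
        return f

    npts = config.n_complexes * config.points_per_complex
    pop = lb + rng.random((npts, dim)) * (ub - lb)
    if initial_points is not None:
        for i, pt in enumerate(initial_points[:npts]):
            pop[i] = np.clip(np.asarray(pt, dtype=float), lb, ub)
    scores = np.array([evaluate(p) for p in pop])

    n_simplex = dim + 1
    beta = 2 * dim + 1     # evolution steps per complex per shuffle
    best_hist: list[float] = []

    while n_eval < config.max_evaluations:
        order = np.argsort(-scores)
        pop, scores = pop[order], scores[order]
        best_hist.append(scores[0])
        if len(best_hist) > config.n_convergence_loops:
            prev = best_hist[-config.n_convergence_loops - 1]
            cur = best_hist[-1]
            if abs(cur - prev) <= config.convergence_tolerance * (
                    1.0 + abs(cur)):
                break
        for ic in range(config.n_complexes):
            idx = np.arange(ic, npts, config.n_complexes)
            cx, cs = pop[idx].copy(), scores[idx].copy()
            for _ in range(beta):
                if n_eval >= config.max_evaluations:
                    break
                m = cx.shape[0]
                # triangular selection of a simplex
                weights = 2.0 * (m - np.arange(m)) / (m * (m + 1))
                sel = rng.choice(m, size=n_simplex, replace=False, p=weights)
                sel = sel[np.argsort(-cs[sel])]
                simplex = cx[sel]
                worst = simplex[-1]
                centroid = simplex[:-1].mean(axis=0)
                new = 2.0 * centroid - worst          # reflection
                if np.any(new < lb) or np.any(new > ub):
                    new = lb + rng.random(dim) * (ub - lb)
                fnew = evaluate(new)
                if fnew < cs[sel[-1]]:
                    new = 0.5 * (centroid + worst)    # contraction
                    fnew = evaluate(new)
                    if fnew < cs[sel[-1]] and n_eval < config.max_evaluations:
                        new = lb + rng.random(dim) * (ub - lb)  # mutation
                        fnew = evaluate(new)
                cx[sel[-1]] = new
                cs[sel[-1]] = fnew
                srt = np.argsort(-cs)
                cx, cs = cx[srt], cs[srt]
            pop[idx], scores[idx] = cx, cs

    order = np.argsort(-scores)
    pop, scores = pop[order], scores[order]
    tr = np.asarray(trace)
    # report the best *evaluated* point (post-transform)
    ib = int(np.argmax(tr[:, -1]))
    return SCEResult(x=tr[ib, :-1].copy(), score=float(tr[ib, -1]),
                     trace=tr, n_evaluations=n_eval)
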