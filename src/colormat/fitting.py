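"""Maximum-likelihood estimation of the observer model from trial tables.

A trial table is a list of :class:`TrialRecord`; the likelihood of a
candidate solution is the product over trials of the interpolated
probability of the observed choice.  Because trial order is irrelevant,
trials are aggregated to unique stimulus pairs with binomial counts before
optimization, which makes one objective evaluation a single vectorized
table interpolation.

Parameters are searched on a transformed scale:

* the weight on a logit scale (avoids stalls at the 0/1 boundary),
* polynomial coefficients raw, with a smooth quadratic barrier for
  monotonicity / spacing / range violations over the 7 design levels,
* the full variant as log gap increments between adjacent level positions
  (monotone and minimally spaced by construction), with the same barrier
  for the +/-20 range.

Multi-start local search (L-BFGS-B) handles the documented ridge between
the weight and the positional scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

from .core_model import (
    CONVENTIONS,
    FULL_LEVELS,
    PARAMS_PER_DIMENSION,
    ConstraintViolation,
    ModelSolution,
    ModelSpec,
    NominalStimulus,
    PositionalMapping,
    map_positions,
)
from .likelihood_engine import ChoiceLookupTable, clip_for_likelihood

TrialSource = ("questFull", "questRestricted2", "questRestricted1", "random",
               "fixed", "unknown")


@dataclass(frozen=True)
class TrialRecord:
    """One ternary trial: two tests, the observer's binary choice, provenance."""

    test1: NominalStimulus
    test2: NominalStimulus
    choice: int
    block: int = 0
    sub_block: int = 0
    source: str = "unknown"

    def __post_init__(self) -> None:
        if self.choice not in (1, 2):
            raise ValueError(f"choice must be 1 or 2, got {self.choice}")


@dataclass
class FitConfig:
    """Optimization settings for :func:`fit_model`.

    ``n_starts`` coarse starts span weights 0.1..0.9 crossed with linear
    slopes in the adaptive procedure's 0.5–6 range; ``extra_starts`` may
    add warm starts (e.g. a previous solution's parameters).
    """

    n_starts: int = 10
    seed: int = 0
    max_iterations: int = 300
    tol: float = 1e-6
    extra_starts: list[ModelSolution] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_starts < 1 and not self.extra_starts:
            raise ValueError("need at least one start")


class FitFailure(RuntimeError):
    """All optimizer starts failed; carries per-start diagnostics."""

    def __init__(self, diagnostics: list[str]):
        super().__init__("all fit starts failed:\n" + "\n".join(diagnostics))
        self.diagnostics = diagnostics


# ---------------------------------------------------------------------------
# trial aggregation

def aggregate_trials(trials: Sequence[TrialRecord]):
    """Collapse trials to unique nominal pairs with choose-test-1 counts.

    Returns (pairs, n1, n) where ``pairs`` is (m, 4) int levels
    (t1C, t1M, t2C, t2M), ``n1`` the count of choice==1 and ``n`` the
    total presentations of that ordered pair.
    """
    if not trials:
        return np.empty((0, 4), dtype=int), np.empty(0), np.empty(0)
    quads = np.array(
        [(t.test1.color_level, t.test1.material_level,
          t.test2.color_level, t.test2.material_level) for t in trials],
        dtype=int,
    )
    chose1 = np.array([t.choice == 1 for t in trials], dtype=float)
    pairs, inverse = np.unique(quads, axis=0, return_inverse=True)
    n = np.bincount(inverse, minlength=len(pairs)).astype(float)
    n1 = np.bincount(inverse, weights=chose1, minlength=len(pairs))
    return pairs, n1, n


def _pair_positions(mapping: PositionalMapping, pairs: np.ndarray):
    p1 = mapping.stimulus_positions(pairs[:, :2])
    p2 = mapping.stimulus_positions(pairs[:, 2:])
    return p1, p2


def negative_log_likelihood(
    solution: ModelSolution,
    trials: Sequence[TrialRecord],
    table: ChoiceLookupTable,
) -> float:
    """Sum over trials of -log P(observed choice) under ``solution``.

    Raises :class:`ConstraintViolation` if the solution's mapping breaks
    the monotonicity / spacing / range constraints.
    """
    solution.mapping.validate()
    if solution.spec.metric != table.metric:
        raise ValueError(
            f"solution metric {solution.spec.metric!r} does not match "
            f"table metric {table.metric!r}"
        )
    pairs, n1, n = aggregate_trials(trials)
    if len(pairs) == 0:
        return 0.0
    p1, p2 = _pair_positions(solution.mapping, pairs)
    p = clip_for_likelihood(table.interpolate(solution.w, p1, p2))
    return float(-(n1 * np.log(p) + (n - n1) * np.log1p(-p)).sum())


# ---------------------------------------------------------------------------
# parameter transforms

_LOGIT_BOUND = 12.0
_MIN_GAP_LOG = -10.0
_MAX_GAP_LOG = 3.0


def _w_from_theta(t: float) -> float:
    return 1.0 / (1.0 + np.exp(-t))


def _theta_from_w(w: float) -> float:
    w = min(max(w, 1e-5), 1.0 - 1e-5)
    return float(np.log(w / (1.0 - w)))


def _dim_theta_from_params(variant: str, params: np.ndarray) -> np.ndarray:
    if variant != "full":
        return np.asarray(params, dtype=float)
    # full: positions at levels -3..3 -> 6 log gap increments above min spacing
    pos = np.sort(np.concatenate([map_positions("full", params, FULL_LEVELS),
                                  [0.0]]))
    gaps = np.diff(pos)
    return np.log(np.maximum(gaps - CONVENTIONS.min_spacing, 1e-4))


def _dim_params_from_theta(variant: str, theta: np.ndarray) -> np.ndarray:
    if variant != "full":
        return np.asarray(theta, dtype=float)
    gaps = CONVENTIONS.min_spacing + np.exp(theta)
    # gaps span levels (-3..-2, ..., 2..3); positions accumulate from 0
    below = -np.cumsum(gaps[:3][::-1])  # levels -1, -2, -3
    above = np.cumsum(gaps[3:])         # levels +1, +2, +3
    return np.array([below[2], below[1], below[0], above[0], above[1], above[2]])


def _theta_from_solution(solution: ModelSolution) -> np.ndarray:
    v = solution.spec.variant
    return np.concatenate([
        [_theta_from_w(solution.w)],
        _dim_theta_from_params(v, np.asarray(solution.mapping.color_params)),
        _dim_theta_from_params(v, np.asarray(solution.mapping.material_params)),
    ])


def _solution_from_theta(
    theta: np.ndarray, spec: ModelSpec, log_likelihood: float = 0.0,
    identifiable: bool = True,
) -> ModelSolution:
    k = PARAMS_PER_DIMENSION[spec.variant]
    mapping = PositionalMapping(
        spec.variant,
        tuple(_dim_params_from_theta(spec.variant, theta[1:1 + k])),
        tuple(_dim_params_from_theta(spec.variant, theta[1 + k:1 + 2 * k])),
    )
    return ModelSolution(spec, _w_from_theta(theta[0]), mapping,
                         log_likelihood, identifiable)


_POWERS = np.vander(np.arange(-3.0, 4.0), 4, increasing=True).T[1:]  # s,s^2,s^3


def _positions_batch(variant: str, dim_thetas: np.ndarray) -> np.ndarray:
    """Implied positions at the 7 design levels for a batch of parameters."""
    if variant != "full":
        k = dim_thetas.shape[1]
        return dim_thetas @ _POWERS[:k]
    gaps = CONVENTIONS.min_spacing + np.exp(dim_thetas)  # (b, 6)
    below = -np.cumsum(gaps[:, :3][:, ::-1], axis=1)     # levels -1,-2,-3
    above = np.cumsum(gaps[:, 3:], axis=1)               # levels +1,+2,+3
    zero = np.zeros((len(gaps), 1))
    return np.concatenate(
        [below[:, [2, 1, 0]], zero, above], axis=1
    )


def _barrier_batch(positions: np.ndarray) -> np.ndarray:
    """Smooth penalty for spacing/range violations at the design levels."""
    gaps = np.diff(positions, axis=-1)
    spacing = np.maximum(CONVENTIONS.min_spacing - gaps, 0.0)
    rng = np.maximum(np.abs(positions) - CONVENTIONS.position_bound, 0.0)
    return 1e6 * ((spacing**2).sum(axis=-1) + (rng**2).sum(axis=-1))


def _batch_objective(thetas, spec, pairs, n1, n, table) -> np.ndarray:
    """Penalized negative log-likelihood for a batch of parameter vectors.

    Batching lets a finite-difference gradient cost one vectorized table
    interpolation instead of one call per coordinate.
    """
    thetas = np.atleast_2d(np.asarray(thetas, dtype=float))
    k = PARAMS_PER_DIMENSION[spec.variant]
    w = 1.0 / (1.0 + np.exp(-thetas[:, 0]))
    pc = _positions_batch(spec.variant, thetas[:, 1:1 + k])
    pm = _positions_batch(spec.variant, thetas[:, 1 + k:1 + 2 * k])
    penalty = _barrier_batch(pc) + _barrier_batch(pm)
    # clip positions into the table range so the objective stays defined
    bound = CONVENTIONS.position_bound
    pc = np.clip(pc, -bound, bound)
    pm = np.clip(pm, -bound, bound)
    p1 = np.stack([pc[:, pairs[:, 0] + 3], pm[:, pairs[:, 1] + 3]], axis=-1)
    p2 = np.stack([pc[:, pairs[:, 2] + 3], pm[:, pairs[:, 3] + 3]], axis=-1)
    p = clip_for_likelihood(table.interpolate(w[:, None], p1, p2))
    nll = -(n1 * np.log(p) + (n - n1) * np.log1p(-p)).sum(axis=1)
    return nll + penalty


def _objective(theta, spec, pairs, n1, n, table):
    return float(_batch_objective(theta, spec, pairs, n1, n, table)[0])


_FD_STEP = 1e-6


def _value_and_grad(theta, spec, pairs, n1, n, table):
    """Objective and forward-difference gradient in one batched call."""
    d = len(theta)
    thetas = np.tile(theta, (d + 1, 1))
    thetas[1:, :] += np.eye(d) * _FD_STEP
    vals = _batch_objective(thetas, spec, pairs, n1, n, table)
    return vals[0], (vals[1:] - vals[0]) / _FD_STEP


def default_starts(spec: ModelSpec, n_starts: int, seed: int) -> list[np.ndarray]:
    """Coarse starts: weights spread over 0.1..0.9, slopes over 0.5..6.

    Deterministic given ``seed``; quadratic/cubic terms start at 0 and the
    full variant starts from equal spacing at the chosen slope.
    """
    rng = np.random.default_rng(seed)
    ws = np.linspace(0.1, 0.9, n_starts)
    slopes = rng.permutation(np.linspace(0.5, 6.0, n_starts))
    starts = []
    k = PARAMS_PER_DIMENSION[spec.variant]
    for w, slope in zip(ws, slopes):
        if spec.variant == "full":
            dim = np.log(np.maximum(slope - CONVENTIONS.min_spacing, 1e-3))
            dim = np.full(6, dim)
        else:
            dim = np.zeros(k)
            dim[0] = slope
        starts.append(np.concatenate([[_theta_from_w(w)], dim, dim]))
    return starts


def _is_degenerate(pairs: np.ndarray) -> bool:
    """True when every presented pair has test1 == test2 (flat likelihood)."""
    return len(pairs) == 0 or bool(
        np.all((pairs[:, :2] == pairs[:, 2:]).all(axis=1))
    )


def minimal_spacing_solution(spec: ModelSpec, log_likelihood: float = 0.0,
                             identifiable: bool = False) -> ModelSolution:
    """w = 0.5 with minimally spaced positions; the non-identifiable fallback."""
    if spec.variant == "full":
        params = tuple(CONVENTIONS.min_spacing * np.array([-3, -2, -1, 1, 2, 3],
                                                          dtype=float))
    else:
        params = tuple([CONVENTIONS.min_spacing]
                       + [0.0] * (PARAMS_PER_DIMENSION[spec.variant] - 1))
    mapping = PositionalMapping(spec.variant, params, params)
    return ModelSolution(spec, 0.5, mapping, log_likelihood, identifiable)


def fit_model(
    trials: Sequence[TrialRecord],
    spec: ModelSpec,
    table: ChoiceLookupTable,
    config: FitConfig | None = None,
) -> ModelSolution:
    """Best maximum-likelihood solution for one model spec across all starts.

    The returned ``log_likelihood`` is the (negated) exact objective of the
    returned parameters, recomputed without barrier terms.
    """
    if config is None:
        config = FitConfig()
    if spec.metric != table.metric:
        raise ValueError(
            f"spec metric {spec.metric!r} does not match table metric "
            f"{table.metric!r}"
        )
    if not trials:
        raise ValueError("need at least one trial")
    pairs, n1, n = aggregate_trials(trials)
    if _is_degenerate(pairs):
        ll = float(len(trials) * np.log(0.5))
        return minimal_spacing_solution(spec, ll, identifiable=False)

    starts = default_starts(spec, config.n_starts, config.seed)
    starts += [_theta_from_solution(s) for s in config.extra_starts
               if s.spec.variant == spec.variant]

    k = PARAMS_PER_DIMENSION[spec.variant]
    if spec.variant == "full":
        dim_bounds = [(_MIN_GAP_LOG, _MAX_GAP_LOG)] * k
    else:
        dim_bounds = [(-50.0, 50.0)] * k
    bounds = [(-_LOGIT_BOUND, _LOGIT_BOUND)] + dim_bounds * 2

    best = None
    best_val = np.inf
    diagnostics = []
    for i, theta0 in enumerate(starts):
        try:
            res = optimize.minimize(
                _value_and_grad, theta0,
                args=(spec, pairs, n1, n, table), jac=True,
                method="L-BFGS-B", bounds=bounds,
                options={"maxiter": config.max_iterations,
                         "ftol": config.tol},
            )
        except Exception as exc:  # numerical failure in one start
            diagnostics.append(f"start {i}: {exc!r}")
            continue
        if not np.isfinite(res.fun):
            diagnostics.append(f"start {i}: non-finite objective")
            continue
        if res.fun < best_val:
            best_val = res.fun
            best = res.x
    if best is None:
        raise FitFailure(diagnostics)
    solution = _solution_from_theta(best, spec)
    try:
        solution.mapping.validate()
    except ConstraintViolation:
        # barrier left a marginal violation: polish under hard constraints
        best = _constrained_polish(best, spec, pairs, n1, n, table, config)
        solution = _solution_from_theta(best, spec)
        solution.mapping.validate()
    ll = -negative_log_likelihood(solution, trials, table)
    return replace(solution, log_likelihood=ll)


def _constrained_polish(theta, spec, pairs, n1, n, table, config):
    """Re-solve with explicit inequality constraints (SLSQP).

    The spacing and range constraints are linear in the positional
    parameters, so SLSQP converges quickly from the barrier solution.  A
    tiny margin keeps the polished point strictly feasible.
    """
    k = PARAMS_PER_DIMENSION[spec.variant]
    levels = np.arange(-3, 4)
    margin = 1e-9

    def cons(t):
        pc = map_positions(spec.variant,
                           _dim_params_from_theta(spec.variant, t[1:1 + k]),
                           levels)
        pm = map_positions(spec.variant,
                           _dim_params_from_theta(spec.variant,
                                                  t[1 + k:1 + 2 * k]),
                           levels)
        bound = CONVENTIONS.position_bound
        return np.concatenate([
            np.diff(pc) - CONVENTIONS.min_spacing - margin,
            np.diff(pm) - CONVENTIONS.min_spacing - margin,
            bound - np.abs(pc) - margin,
            bound - np.abs(pm) - margin,
        ])

    res = optimize.minimize(
        _objective, theta, args=(spec, pairs, n1, n, table),
        method="SLSQP", constraints=[{"type": "ineq", "fun": cons}],
        options={"maxiter": config.max_iterations, "ftol": config.tol},
    )
    return res.x if np.all(cons(res.x) >= -margin) else _repair(res.x, spec, k)


def _repair(theta, spec, k):
    """Last-resort repair: scale each dimension's positions into bounds."""
    t = theta.copy()
    levels = np.arange(-3, 4)
    for lo in (1, 1 + k):
        params = _dim_params_from_theta(spec.variant, t[lo:lo + k])
        pos = map_positions(spec.variant, params, levels)
        gaps = np.diff(pos)
        if np.any(gaps < CONVENTIONS.min_spacing) and spec.variant != "full":
            # inflate the linear term until the smallest gap clears 0.25
            slope_fix = (CONVENTIONS.min_spacing - gaps.min()) + 1e-6
            params = np.asarray(params, dtype=float)
            params[0] += slope_fix
            pos = map_positions(spec.variant, params, levels)
        scale = min(1.0, CONVENTIONS.position_bound / np.abs(pos).max())
        params = np.asarray(params, dtype=float) * scale
        t[lo:lo + k] = _dim_theta_from_params(spec.variant, params)
    return t
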