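"""Monte-Carlo choice probabilities: 5-D lookup table and interpolation.

There is no closed form for the probability that a noisy observer picks
test 1 over test 2 given their mean perceptual positions and the weight
``w``.  The engine estimates these probabilities by forward simulation and
caches them in a gridded 5-D table over (w, p1C, p1M, p2C, p2M); fitting
then interpolates the table with a tricubic spline instead of re-simulating.

Default grids follow the experimental convention: 10 linearly spaced
weights in [0, 1], 20 linearly spaced positions in [-20, +20] shared by
all four position axes, 3000 simulated trials per cell.  A reduced preset
(11 positions, 1000 trials) keeps test suites fast.

The table is built with common random numbers: one set of noise-draw
triples (target, test 1, test 2) is shared by every cell of a weight
slice, and each cell's probability is symmetrized over the two stimulus
orderings.  This makes the complement law P(p1,p2) + P(p2,p1) = 1 exact,
removes a spurious Monte-Carlo asymmetry, and cuts the build from hours to
seconds relative to independent per-cell streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core_model import Metric, weighted_distance

#: interpolated probabilities are clipped into [EPS, 1-EPS] before logs
EPS = 1e-4

#: default Monte-Carlo trials per table cell
DEFAULT_MC_TRIALS = 3000


def default_weight_grid() -> np.ndarray:
    return np.linspace(0.0, 1.0, 10)


def default_position_grid() -> np.ndarray:
    return np.linspace(-20.0, 20.0, 20)


def reduced_position_grid() -> np.ndarray:
    """Coarse position grid (step 4) for fast test builds."""
    return np.arange(-20.0, 21.0, 4.0)


class InterpolationRangeError(ValueError):
    """A query fell outside the table's bounding box."""


@dataclass
class ChoiceLookupTable:
    """Gridded first-test choice probabilities for one distance metric.

    ``probabilities[i, j, k, l, m]`` is P(choose test 1) at weight
    ``weight_grid[i]`` with test 1 at (position_grid[j], position_grid[k])
    and test 2 at (position_grid[l], position_grid[m]); the target is at
    the origin and all three stimuli receive independent unit Gaussian
    noise on both dimensions.
    """

    metric: Metric
    weight_grid: np.ndarray
    position_grid: np.ndarray
    probabilities: np.ndarray
    mc_trials_per_cell: int
    seed: int
    _spline_coeffs: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        nw, np_ = len(self.weight_grid), len(self.position_grid)
        expected = (nw, np_, np_, np_, np_)
        if self.probabilities.shape != expected:
            raise ValueError(
                f"probabilities shape {self.probabilities.shape} != {expected}"
            )

    @property
    def spline_coeffs(self) -> np.ndarray:
        """Tricubic spline coefficients, computed lazily and cached."""
        if self._spline_coeffs is None:
            self._spline_coeffs = ndimage.spline_filter(
                self.probabilities, order=3, mode="mirror"
            )
        return self._spline_coeffs

    def interpolate(self, w, p1, p2) -> np.ndarray:
        """Vectorized cubic interpolation of P(choose test 1).

        ``p1`` and ``p2`` are (..., 2) arrays of (pC, pM); ``w`` broadcasts
        against their leading shape.  Results are clipped to [0, 1] (cubic
        interpolation can overshoot the data range).
        """
        single = np.asarray(p1).ndim == 1
        p1 = np.atleast_2d(np.asarray(p1, dtype=float))
        p2 = np.atleast_2d(np.asarray(p2, dtype=float))
        w = np.asarray(w, dtype=float)
        if np.any(w < 0.0) or np.any(w > 1.0):
            raise InterpolationRangeError("weight outside [0, 1]")
        lo, hi = self.position_grid[0], self.position_grid[-1]
        pos = np.concatenate([p1, p2], axis=-1)  # (..., 4)
        if np.any(pos < lo) or np.any(pos > hi):
            raise InterpolationRangeError(
                f"position outside table range [{lo}, {hi}]"
            )
        wlo, whi = self.weight_grid[0], self.weight_grid[-1]
        iw = np.broadcast_to(
            (w - wlo) / (whi - wlo) * (len(self.weight_grid) - 1),
            pos.shape[:-1],
        )
        ip = (pos - lo) / (hi - lo) * (len(self.position_grid) - 1)
        coords = np.concatenate(
            [iw[None, ...], np.moveaxis(ip, -1, 0)], axis=0
        )
        vals = ndimage.map_coordinates(
            self.spline_coeffs, coords.reshape(5, -1),
            order=3, prefilter=False, mode="mirror",
        ).reshape(pos.shape[:-1])
        vals = np.clip(vals, 0.0, 1.0)
        return float(vals[0]) if single else vals


def _delta_draws(n_trials: int, rng: np.random.Generator):
    """Noise differences (test draw - target draw) for both tests.

    Returns g1, g2 of shape (n_trials, 2).  Both share the target draw, so
    they are correlated (cov I between them, var 2I each) exactly as in the
    three-draw decision process.
    """
    e_target = rng.standard_normal((n_trials, 2))
    g1 = rng.standard_normal((n_trials, 2)) - e_target
    g2 = rng.standard_normal((n_trials, 2)) - e_target
    return g1, g2


def simulate_choice_probability(
    p1: Sequence[float],
    p2: Sequence[float],
    w: float,
    metric: Metric,
    n_trials: int,
    seed: int | np.random.Generator = 0,
) -> float:
    """Direct Monte-Carlo estimate of P(choose test 1).

    The target sits at the origin; independent unit Gaussian noise perturbs
    the target and both tests on both dimensions.  Exact distance ties
    count 1/2 (the unbiased tie-break in expectation).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    g1, g2 = _delta_draws(n_trials, rng)
    d1 = weighted_distance(w, p1[0] + g1[:, 0], p1[1] + g1[:, 1], metric)
    d2 = weighted_distance(w, p2[0] + g2[:, 0], p2[1] + g2[:, 1], metric)
    return float((d1 < d2).mean() + 0.5 * (d1 == d2).mean())


def build_lookup_table(
    metric: Metric,
    weight_grid: np.ndarray | None = None,
    position_grid: np.ndarray | None = None,
    mc_trials_per_cell: int = DEFAULT_MC_TRIALS,
    seed: int = 0,
) -> ChoiceLookupTable:
    """Build the gridded 5-D choice-probability table for one metric.

    For each weight slice, one shared set of ``mc_trials_per_cell`` noise
    triples is evaluated at every grid position for test 1 and test 2, and
    each cell is symmetrized over the two orderings, so the complement law
    holds exactly and rebuilding with the same seed is bit-for-bit
    reproducible.
    """
    if weight_grid is None:
        weight_grid = default_weight_grid()
    if position_grid is None:
        position_grid = default_position_grid()
    weight_grid = np.asarray(weight_grid, dtype=float)
    position_grid = np.asarray(position_grid, dtype=float)
    if np.any(np.diff(weight_grid) <= 0) or np.any(np.diff(position_grid) <= 0):
        raise ValueError("grids must be strictly increasing")
    rng = np.random.default_rng(seed)
    g1, g2 = _delta_draws(mc_trials_per_cell, rng)

    n_pos = len(position_grid)
    pc, pm = np.meshgrid(position_grid, position_grid, indexing="ij")
    pc = pc.ravel()[:, None]  # (n_pos^2, 1)
    pm = pm.ravel()[:, None]
    n_cells = n_pos * n_pos
    table = np.empty((len(weight_grid), n_cells, n_cells))
    # chunk rows so the boolean comparison block stays ~1e8 elements
    chunk = int(min(n_cells, max(1, 1.2e8 // (n_cells * mc_trials_per_cell))))
    for wi, w in enumerate(weight_grid):
        d1 = weighted_distance(w, pc + g1[:, 0], pm + g1[:, 1], metric)
        d2 = weighted_distance(w, pc + g2[:, 0], pm + g2[:, 1], metric)
        first = np.empty((n_cells, n_cells))
        for s in range(0, n_cells, chunk):
            block1 = d1[s:s + chunk, None, :]
            lt = (block1 < d2[None, :, :]).mean(axis=2)
            eq = (block1 == d2[None, :, :]).mean(axis=2)
            first[s:s + chunk] = lt + 0.5 * eq
        # symmetrize over orderings: exact complement law
        table[wi] = 0.5 * (first + 1.0 - first.T)
    return ChoiceLookupTable(
        metric=metric,
        weight_grid=weight_grid,
        position_grid=position_grid,
        probabilities=table.reshape(
            len(weight_grid), n_pos, n_pos, n_pos, n_pos
        ),
        mc_trials_per_cell=mc_trials_per_cell,
        seed=seed,
    )


def build_reduced_table(metric: Metric, seed: int = 0) -> ChoiceLookupTable:
    """Coarse-grid, 1000-trial table preset for fast test pipelines."""
    return build_lookup_table(
        metric,
        position_grid=reduced_position_grid(),
        mc_trials_per_cell=1000,
        seed=seed,
    )


def interpolate_choice_probability(
    table: ChoiceLookupTable, w, p1, p2
) -> np.ndarray:
    """Interpolated P(choose test 1); see :meth:`ChoiceLookupTable.interpolate`."""
    return table.interpolate(w, p1, p2)


def clip_for_likelihood(p: np.ndarray, eps: float = EPS) -> np.ndarray:
    """Clip probabilities away from 0/1 before taking logs."""
    return np.clip(p, eps, 1.0 - eps)
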