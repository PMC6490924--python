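"""Bayesian adaptive trial placement over the cubic observer-model grid.

The adaptive procedure maintains a posterior over a discrete 7-parameter
grid — per dimension a cubic mapping (linear coefficient 0.5–6 in 5
levels, quadratic and cubic coefficients −0.3–0.3 in 4 levels each) plus
the color-material weight (0.05–0.95 in 5 levels) — restricted to
parameter combinations whose implied perceptual positions are monotone,
within ±20 and spaced by at least 0.25.  Choice likelihoods per
(combination, candidate pair) come from the Euclidean lookup table and
are precomputed into a matrix, after which each trial costs a few
matrix-vector products: the next pair is the one minimizing expected
posterior entropy over the two possible responses, and responses update
the posterior by Bayes' rule.

The prior is uniform over valid combinations.  Ties in expected entropy
break to the lowest pair index (pairs sorted lexicographically by nominal
levels) so sessions replay deterministically.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy.special import xlogy

from .core_model import CONVENTIONS, NominalStimulus
from .likelihood_engine import ChoiceLookupTable

#: likelihood floor per trial in posterior updates
LIKELIHOOD_FLOOR = 1e-6

StimulusPair = tuple[NominalStimulus, NominalStimulus]


@dataclass(frozen=True)
class QuestParameterGrid:
    """Discrete parameter grid for the cubic/Euclidean adaptive model."""

    linear_levels: tuple[float, ...] = tuple(np.linspace(0.5, 6.0, 5))
    quadratic_levels: tuple[float, ...] = tuple(np.linspace(-0.3, 0.3, 4))
    cubic_levels: tuple[float, ...] = tuple(np.linspace(-0.3, 0.3, 4))
    weight_levels: tuple[float, ...] = tuple(np.linspace(0.05, 0.95, 5))

    @classmethod
    def coarse(cls) -> "QuestParameterGrid":
        """Few-level preset for smoke runs: quick to scan, still adaptive."""
        return cls(linear_levels=(0.5, 1.5, 3.0),
                   quadratic_levels=(-0.2, 0.2),
                   cubic_levels=(0.0,),
                   weight_levels=(0.2, 0.5, 0.8))

    @property
    def raw_size(self) -> int:
        """Grid size before validity filtering ((5*4*4)^2 * 5 by default)."""
        per_dim = (len(self.linear_levels) * len(self.quadratic_levels)
                   * len(self.cubic_levels))
        return per_dim**2 * len(self.weight_levels)

    def dimension_combos(self) -> np.ndarray:
        """All (a1, a2, a3) coefficient triples, before filtering."""
        return np.array(list(itertools.product(
            self.linear_levels, self.quadratic_levels, self.cubic_levels
        )))

    def valid_dimension_combos(self) -> tuple[np.ndarray, np.ndarray]:
        """Coefficient triples whose implied positions are admissible.

        Returns (triples, positions): triples (nv, 3) and the implied
        positions at the 7 design levels (nv, 7), keeping only monotone
        mappings within the position bound with minimum spacing.
        """
        triples = self.dimension_combos()
        s = np.arange(-3, 4, dtype=float)
        pos = (triples[:, [0]] * s + triples[:, [1]] * s**2
               + triples[:, [2]] * s**3)
        gaps = np.diff(pos, axis=1)
        ok = ((gaps >= CONVENTIONS.min_spacing).all(axis=1)
              & (np.abs(pos) <= CONVENTIONS.position_bound).all(axis=1))
        return triples[ok], pos[ok]

    def valid_combos(self):
        """Full valid grid: weight, per-dim triples and implied positions.

        Returns (w, c_triples, m_triples, c_pos, m_pos), each indexed by
        combo; combos are ordered weight-major, then color, then material.
        """
        triples, pos = self.valid_dimension_combos()
        nv = len(triples)
        if nv == 0:
            raise ValueError("validity filtering left an empty parameter grid")
        nw = len(self.weight_levels)
        iw, ic, im = np.unravel_index(np.arange(nw * nv * nv), (nw, nv, nv))
        return (np.asarray(self.weight_levels)[iw], triples[ic], triples[im],
                pos[ic], pos[im])

    def fingerprint(self) -> str:
        h = hashlib.sha256()
        for levels in (self.linear_levels, self.quadratic_levels,
                       self.cubic_levels, self.weight_levels):
            h.update(np.asarray(levels, dtype=float).tobytes())
        return h.hexdigest()[:16]


def stimuli_in_range(stimulus_range: int) -> list[NominalStimulus]:
    """The (2r+1)^2 design stimuli within +/-r, lexicographic order."""
    if stimulus_range not in (1, 2, 3):
        raise ValueError("stimulus range must be 1, 2 or 3")
    r = stimulus_range
    return [NominalStimulus(c, m)
            for c in range(-r, r + 1) for m in range(-r, r + 1)]


def candidate_pairs(stimulus_range: int) -> list[StimulusPair]:
    """All unordered test pairs within the range (C(n, 2) of them)."""
    return list(itertools.combinations(stimuli_in_range(stimulus_range), 2))


@dataclass
class LikelihoodMatrix:
    """P(choose test 1) per (grid combo, candidate pair), with entropy caches."""

    pairs: list[StimulusPair]
    L: np.ndarray                      # (n_combo, n_pair), clipped
    M1: np.ndarray = field(init=False)  # L * log L
    M2: np.ndarray = field(init=False)  # (1-L) * log(1-L)

    def __post_init__(self) -> None:
        self.L = np.clip(self.L, LIKELIHOOD_FLOOR, 1.0 - LIKELIHOOD_FLOOR)
        self.M1 = self.L * np.log(self.L)
        self.M2 = (1.0 - self.L) * np.log1p(-self.L)


def table_fingerprint(table: ChoiceLookupTable) -> str:
    h = hashlib.sha256()
    h.update(table.metric.encode())
    h.update(np.asarray([table.seed, table.mc_trials_per_cell]).tobytes())
    h.update(table.weight_grid.tobytes())
    h.update(table.position_grid.tobytes())
    return h.hexdigest()[:16]


_matrix_cache: dict[tuple[str, str, int], LikelihoodMatrix] = {}


def compute_likelihood_matrix(
    grid: QuestParameterGrid,
    table: ChoiceLookupTable,
    stimulus_range: int,
    cache_dir: str | Path | None = None,
) -> LikelihoodMatrix:
    """Precompute choice likelihoods for every (combo, pair).

    Matrices are cached in memory by (grid, table, range) content hash —
    restricted ranges reuse columns of a cached full-range matrix — and
    optionally on disk under ``cache_dir``.
    """
    key = (grid.fingerprint(), table_fingerprint(table), stimulus_range)
    if key in _matrix_cache:
        return _matrix_cache[key]
    pairs = candidate_pairs(stimulus_range)
    full_key = (key[0], key[1], 3)
    if stimulus_range < 3 and full_key in _matrix_cache:
        full = _matrix_cache[full_key]
        index = {p: i for i, p in enumerate(full.pairs)}
        cols = np.array([index[p] for p in pairs])
        mat = LikelihoodMatrix(pairs, full.L[:, cols])
        _matrix_cache[key] = mat
        return mat

    cache_file = None
    if cache_dir is not None:
        cache_file = Path(cache_dir) / (
            f"questL_{key[0]}_{key[1]}_r{stimulus_range}.npy"
        )
        if cache_file.exists():
            mat = LikelihoodMatrix(pairs, np.load(cache_file))
            _matrix_cache[key] = mat
            return mat

    w, _, _, c_pos, m_pos = grid.valid_combos()
    n_combo = len(w)
    quads = np.array([(a.color_level, a.material_level,
                       b.color_level, b.material_level) for a, b in pairs])
    L = np.empty((n_combo, len(pairs)))
    chunk = max(1, int(6e5 // len(pairs)))
    for s in range(0, n_combo, chunk):
        e = min(s + chunk, n_combo)
        p1 = np.stack([c_pos[s:e][:, quads[:, 0] + 3],
                       m_pos[s:e][:, quads[:, 1] + 3]], axis=-1)
        p2 = np.stack([c_pos[s:e][:, quads[:, 2] + 3],
                       m_pos[s:e][:, quads[:, 3] + 3]], axis=-1)
        L[s:e] = table.interpolate(w[s:e, None], p1, p2)
    mat = LikelihoodMatrix(pairs, L)
    _matrix_cache[key] = mat
    if cache_file is not None:
        cache_file.parent.mkdir(parents=True, exist_ok=True)
        np.save(cache_file, mat.L)
    return mat


@dataclass
class QuestState:
    """Posterior over valid grid combos plus the candidate-pair likelihoods."""

    grid: QuestParameterGrid
    stimulus_range: int
    posterior: np.ndarray
    matrix: LikelihoodMatrix
    pair_index: dict[StimulusPair, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.pair_index:
            self.pair_index = {p: i for i, p in enumerate(self.matrix.pairs)}
        total = self.posterior.sum()
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"posterior sums to {total}, expected 1")

    @property
    def entropy(self) -> float:
        return float(-xlogy(self.posterior, self.posterior).sum())


def init_quest(
    grid: QuestParameterGrid,
    stimulus_range: int,
    table: ChoiceLookupTable,
    cache_dir: str | Path | None = None,
) -> QuestState:
    """Uniform prior over valid combos; candidate pairs within the range."""
    matrix = compute_likelihood_matrix(grid, table, stimulus_range, cache_dir)
    n = matrix.L.shape[0]
    return QuestState(grid, stimulus_range, np.full(n, 1.0 / n), matrix)


def expected_entropies(state: QuestState) -> np.ndarray:
    """Expected posterior entropy after one trial, per candidate pair."""
    post = state.posterior
    L, M1, M2 = state.matrix.L, state.matrix.M1, state.matrix.M2
    plogp = xlogy(post, post)
    sum_plogp = plogp.sum()
    s1 = L.T @ post                    # predictive P(choose 1)
    s1 = np.clip(s1, 1e-300, 1.0)
    s2 = np.clip(1.0 - s1, 1e-300, 1.0)
    t1 = M1.T @ post + L.T @ plogp     # sum p_i l_i log(p_i l_i)
    t2 = M2.T @ post + (sum_plogp - L.T @ plogp)
    h1 = np.log(s1) - t1 / s1
    h2 = np.log(s2) - t2 / s2
    return s1 * h1 + s2 * h2


def next_stimulus(state: QuestState) -> StimulusPair:
    """The candidate pair minimizing expected posterior entropy.

    Deterministic: equal-gain pairs resolve to the lowest pair index.
    """
    eh = expected_entropies(state)
    return state.matrix.pairs[int(np.argmin(eh))]


def update_posterior(
    state: QuestState, pair: StimulusPair, observed_choice: int
) -> QuestState:
    """Bayes update for one observed response; returns a new state."""
    if observed_choice not in (1, 2):
        raise ValueError("observed choice must be 1 or 2")
    try:
        col = state.pair_index[pair]
    except KeyError:
        try:
            col = state.pair_index[(pair[1], pair[0])]
            observed_choice = 3 - observed_choice
        except KeyError:
            raise ValueError(f"pair {pair} not in the candidate set") from None
    lik = state.matrix.L[:, col] if observed_choice == 1 \
        else 1.0 - state.matrix.L[:, col]
    post = state.posterior * np.maximum(lik, LIKELIHOOD_FLOOR)
    total = post.sum()
    if total <= 0.0:  # unreachable with the floor; guard regardless
        post = np.full_like(post, 1.0 / len(post))
    else:
        post = post / total
    return replace(state, posterior=post, pair_index=state.pair_index)


def posterior_mode(state: QuestState):
    """Grid parameters (w, color triple, material triple) at the MAP combo."""
    w, ct, mt, _, _ = state.grid.valid_combos()
    i = int(np.argmax(state.posterior))
    return float(w[i]), ct[i], mt[i]
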