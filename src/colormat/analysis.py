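"""Post-fit analyses: bootstrap CIs, trade-off curves, slope ratio, recovery.

The bootstrap resamples individual trials with replacement and refits the
chosen model, seeding each refit both with the default start set and with
the full-data solution; the central 68% interval of the bootstrapped
weights (the analogue of ±1 SEM for a Gaussian) summarizes the weight's
reliability.  Trade-off curves translate a solution into the predicted
probability that a color match beats a material match for every pairing
of design levels.  The color-material slope ratio — the ratio of the
least-squares slopes of perceptual position against nominal level on the
two dimensions — indexes relative positional expansion; across bootstrap
refits it trades off against the weight (higher weight, lower ratio),
which is the documented identifiability limit of this class of model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core_model import DESIGN_LEVELS, ModelSolution
from .fitting import FitConfig, FitFailure, TrialRecord, fit_model
from .likelihood_engine import ChoiceLookupTable
from .model_selection import SelectionResult, run_model_selection
from .questplus_engine import QuestParameterGrid
from .session_simulator import GeneratingObserver, SessionDesign, simulate_session


@dataclass
class BootstrapResult:
    """Weight distribution over bootstrap refits of one dataset."""

    weights: np.ndarray
    solutions: list[ModelSolution]
    ci_low: float
    ci_high: float
    mean_weight: float
    n_failures: int
    n_non_identifiable: int
    seed: int

    @property
    def n_iterations(self) -> int:
        return len(self.weights) + self.n_failures


def bootstrap_weights(
    trials: Sequence[TrialRecord],
    solution: ModelSolution,
    table: ChoiceLookupTable,
    n_iterations: int = 100,
    seed: int = 0,
    config: FitConfig | None = None,
) -> BootstrapResult:
    """Central 68% confidence interval of the color-material weight.

    Each iteration resamples N-of-N trials with replacement and refits
    ``solution.spec``; each refit's starts include the full-data solution
    plus the default coarse set.  Failed iterations are excluded and
    counted.
    """
    if config is None:
        config = FitConfig(n_starts=3)
    trials = list(trials)
    rng = np.random.default_rng(seed)
    weights: list[float] = []
    solutions: list[ModelSolution] = []
    n_failures = 0
    n_non_ident = 0
    for _ in range(n_iterations):
        idx = rng.integers(len(trials), size=len(trials))
        sample = [trials[i] for i in idx]
        it_config = FitConfig(
            n_starts=config.n_starts,
            seed=int(rng.integers(2**31)),
            max_iterations=config.max_iterations,
            tol=config.tol,
            extra_starts=config.extra_starts + [solution],
        )
        try:
            fit = fit_model(sample, solution.spec, table, it_config)
        except FitFailure:
            n_failures += 1
            continue
        if not fit.identifiable:
            n_non_ident += 1
        weights.append(fit.w)
        solutions.append(fit)
    w = np.array(weights)
    if len(w) == 0:
        raise FitFailure([f"all {n_iterations} bootstrap iterations failed"])
    lo, hi = np.percentile(w, [16.0, 84.0])
    return BootstrapResult(
        weights=w, solutions=solutions, ci_low=float(lo), ci_high=float(hi),
        mean_weight=float(w.mean()), n_failures=n_failures,
        n_non_identifiable=n_non_ident, seed=seed,
    )


@dataclass
class TradeoffCurves:
    """P(color match chosen) for each (color-match M level, material-match C level).

    ``probabilities[i, j]`` pairs the color match C0 M=levels[i] against
    the material match C=levels[j] M0.
    """

    levels: np.ndarray
    probabilities: np.ndarray

    def curve(self, material_level: int) -> np.ndarray:
        return self.probabilities[int(material_level) + 3]


def tradeoff_functions(
    solution: ModelSolution, table: ChoiceLookupTable
) -> TradeoffCurves:
    """Predicted color-match-vs-material-match choice probabilities.

    A color match shares the target's color and differs in material
    (perceptual position (0, pM)); a material match shares the target's
    material and differs in color (position (pC, 0)).  Entry (i, j) is
    the probability the color match at material level i is chosen over
    the material match at color level j.
    """
    if solution.spec.metric != table.metric:
        raise ValueError("solution metric does not match table metric")
    pc = solution.mapping.positions("color")
    pm = solution.mapping.positions("material")
    zeros = np.zeros(7)
    # color match positions: (0, pM_i); material match: (pC_j, 0)
    p1 = np.stack([np.zeros((7, 7)), np.broadcast_to(pm[:, None], (7, 7))],
                  axis=-1)
    p2 = np.stack([np.broadcast_to(pc[None, :], (7, 7)), np.zeros((7, 7))],
                  axis=-1)
    probs = table.interpolate(solution.w, p1, p2)
    return TradeoffCurves(levels=DESIGN_LEVELS.copy(), probabilities=probs)


def dimension_slope(positions: np.ndarray,
                    levels: np.ndarray = DESIGN_LEVELS) -> float:
    """Least-squares slope of perceptual position against nominal level."""
    lv = np.asarray(levels, dtype=float)
    x = lv - lv.mean()
    y = np.asarray(positions, dtype=float)
    return float((x * (y - y.mean())).sum() / (x * x).sum())


def slope_ratio(solution: ModelSolution) -> float:
    """Color slope / material slope over the 7 design levels."""
    c = dimension_slope(solution.mapping.positions("color"))
    m = dimension_slope(solution.mapping.positions("material"))
    if m <= 0:
        raise ValueError("material slope must be positive under monotonicity")
    return c / m


@dataclass
class RecoveryReport:
    """Generating vs recovered parameters for one simulated observer."""

    observer: GeneratingObserver
    n_trials: int
    selection: SelectionResult
    solution: ModelSolution
    bootstrap: BootstrapResult | None = None

    @property
    def recovered_w(self) -> float:
        return self.solution.w

    @property
    def generating_w(self) -> float:
        return self.observer.w


def recovery_study(
    observers: Sequence[GeneratingObserver],
    design: SessionDesign | None = None,
    grid: QuestParameterGrid | None = None,
    tables: dict[str, ChoiceLookupTable] | None = None,
    seed: int = 0,
    fit_config: FitConfig | None = None,
    n_bootstrap: int = 0,
    cache_dir=None,
) -> list[RecoveryReport]:
    """Full pipeline per observer: simulate, select, fit, optional bootstrap.

    Each observer's session is driven by the Euclidean table (as in the
    experiment); model selection then runs over all 8 specs with both
    metrics' tables and the winning spec is refit to the full data.
    """
    if tables is None or "euclidean" not in tables or "cityblock" not in tables:
        raise ValueError("tables must hold both 'euclidean' and 'cityblock'")
    if design is None:
        design = SessionDesign()
    if grid is None:
        grid = QuestParameterGrid()
    if fit_config is None:
        fit_config = FitConfig()
    reports: list[RecoveryReport] = []
    seeds = np.random.SeedSequence(seed).spawn(len(observers))
    for observer, ss in zip(observers, seeds):
        sim_seed, sel_seed, boot_seed = (
            int(s) for s in ss.generate_state(3) % (2**31)
        )
        trials = simulate_session(observer, design, grid,
                                  tables["euclidean"], seed=sim_seed,
                                  cache_dir=cache_dir)
        config = FitConfig(n_starts=fit_config.n_starts, seed=sel_seed,
                           max_iterations=fit_config.max_iterations,
                           tol=fit_config.tol)
        selection = run_model_selection(trials, tables, config)
        solution = selection.solutions[selection.best_spec]
        boot = None
        if n_bootstrap > 0:
            boot = bootstrap_weights(
                trials, solution, tables[solution.spec.metric],
                n_iterations=n_bootstrap, seed=boot_seed,
            )
        reports.append(RecoveryReport(
            observer=observer, n_trials=len(trials), selection=selection,
            solution=solution, bootstrap=boot,
        ))
    return reports
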