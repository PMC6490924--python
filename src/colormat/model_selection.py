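"""Cross-validated model selection across mapping variants and metrics.

The selection procedure compares the four positional variants within each
distance metric by 8-fold cross-validation on one shared data partition,
descending a ladder from the most complex variant: full vs cubic, then
cubic vs quadratic, then quadratic vs linear.  A more complex variant
survives only if its fold-paired one-tailed t-test is significant at
α = 0.05; otherwise it is eliminated and the comparison proceeds.  The
winning variant of each metric is then compared by mean held-out
log-likelihood (higher mean wins regardless of significance), with a
post-hoc two-tailed paired t-test reported against the
multiple-comparison-corrected α = 0.05/12.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .core_model import METRICS, VARIANTS, Metric, ModelSpec, Variant
from .fitting import FitConfig, TrialRecord, fit_model, negative_log_likelihood
from .likelihood_engine import ChoiceLookupTable

LADDER: tuple[Variant, ...] = ("full", "cubic", "quadratic", "linear")

#: post-hoc metric-comparison significance level (0.05 / 12 observers)
METRIC_ALPHA = 0.05 / 12


@dataclass(frozen=True)
class CrossValidationPlan:
    """A fixed 8-fold partition reused across all variants and metrics."""

    n_folds: int
    fold_assignment: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        counts = np.bincount(self.fold_assignment, minlength=self.n_folds)
        if counts.min() == 0:
            raise ValueError("every fold must contain at least one trial")
        if counts.max() - counts.min() > 1:
            raise ValueError("fold sizes must differ by at most 1")


@dataclass
class SelectionResult:
    """Outcome of the full selection ladder over the 8 model specs."""

    best_spec: ModelSpec
    mean_cv_log_likelihood: dict[ModelSpec, float]
    fold_scores: dict[ModelSpec, np.ndarray]
    ladder_p_values: dict[Metric, dict[str, float]]
    best_variant_by_metric: dict[Metric, Variant]
    metric_p_value: float
    metric_significant: bool
    solutions: dict[ModelSpec, object] = field(default_factory=dict)


def make_cv_plan(
    trials: Sequence[TrialRecord], n_folds: int = 8, seed: int = 0
) -> CrossValidationPlan:
    """Random fold assignment, stratified by trial source.

    Trials are permuted within each source stream before being dealt
    round-robin into folds, so no fold is dominated by restricted-range or
    random trials.  Fold sizes differ by at most one.
    """
    n = len(trials)
    if n < n_folds:
        raise ValueError(f"{n} trials cannot fill {n_folds} folds")
    rng = np.random.default_rng(seed)
    sources = np.array([t.source for t in trials])
    assignment = np.empty(n, dtype=int)
    # deal each source's trials round-robin starting from a rotating offset
    offset = int(rng.integers(n_folds))
    for src in sorted(set(sources.tolist())):
        idx = np.nonzero(sources == src)[0]
        idx = rng.permutation(idx)
        assignment[idx] = (np.arange(len(idx)) + offset) % n_folds
        offset += len(idx)
    # rebalance: move trials from over-full folds into under-full ones
    counts = np.bincount(assignment, minlength=n_folds)
    target_lo, target_hi = n // n_folds, -(-n // n_folds)
    for f_over in np.argsort(-counts):
        while counts[f_over] > target_hi:
            f_under = int(np.argmin(counts))
            movable = np.nonzero(assignment == f_over)[0]
            assignment[rng.choice(movable)] = f_under
            counts = np.bincount(assignment, minlength=n_folds)
    return CrossValidationPlan(n_folds, assignment, seed)


def held_out_log_likelihood(
    solution, held: Sequence[TrialRecord], table: ChoiceLookupTable
) -> float:
    return -negative_log_likelihood(solution, held, table)


def cross_validate(
    trials: Sequence[TrialRecord],
    spec: ModelSpec,
    plan: CrossValidationPlan,
    table: ChoiceLookupTable,
    config: FitConfig | None = None,
    warm_start=None,
) -> np.ndarray:
    """Held-out log-likelihood per fold (train on 7/8, evaluate on 1/8).

    ``warm_start`` (typically the full-data fit of the same spec) is added
    to each fold's start list so fold fits stay cheap without losing the
    multi-start protection.
    """
    if plan.fold_assignment.shape[0] != len(trials):
        raise ValueError("plan does not cover the trial list")
    if config is None:
        config = FitConfig()
    scores = np.empty(plan.n_folds)
    trials = list(trials)
    for fold in range(plan.n_folds):
        held_mask = plan.fold_assignment == fold
        train = [t for t, h in zip(trials, held_mask) if not h]
        held = [t for t, h in zip(trials, held_mask) if h]
        fold_config = FitConfig(
            n_starts=config.n_starts,
            seed=config.seed + fold,
            max_iterations=config.max_iterations,
            tol=config.tol,
            extra_starts=(config.extra_starts
                          + ([warm_start] if warm_start is not None else [])),
        )
        solution = fit_model(train, spec, table, fold_config)
        scores[fold] = held_out_log_likelihood(solution, held, table)
    return scores


def _paired_one_tailed_p(complex_scores, simple_scores) -> float:
    """P-value that the complex variant's fold scores exceed the simple's.

    Zero-variance differences degenerate the t statistic: a constant
    positive difference counts as significant evidence for the complex
    variant (p -> 0), a constant zero or negative difference as none
    (p -> 1), matching the test's limiting behavior.
    """
    diff = np.asarray(complex_scores) - np.asarray(simple_scores)
    if np.allclose(diff.std(ddof=1), 0.0):
        return 0.0 if diff.mean() > 0 else 1.0
    return float(stats.ttest_rel(complex_scores, simple_scores,
                                 alternative="greater").pvalue)


def select_positional_variant(
    fold_scores: Mapping[Variant, np.ndarray], alpha: float = 0.05
) -> tuple[Variant, dict[str, float]]:
    """Descend the complexity ladder full -> cubic -> quadratic -> linear."""
    missing = [v for v in LADDER if v not in fold_scores]
    if missing:
        raise ValueError(f"missing fold scores for variants: {missing}")
    p_values: dict[str, float] = {}
    for i in range(len(LADDER) - 1):
        complex_v, simple_v = LADDER[i], LADDER[i + 1]
        p = _paired_one_tailed_p(fold_scores[complex_v], fold_scores[simple_v])
        p_values[f"{complex_v}_vs_{simple_v}"] = p
        if p < alpha:
            return complex_v, p_values
    return LADDER[-1], p_values


def select_metric(
    euclidean_scores: np.ndarray, cityblock_scores: np.ndarray
) -> tuple[Metric, float, bool]:
    """Best metric by mean held-out log-likelihood, plus the post-hoc test.

    The winner is whichever metric's best variant has the higher mean CV
    log-likelihood, regardless of significance; exact ties prefer
    Euclidean (the arbitrary default used to drive the adaptive
    procedure).  The two-tailed paired p-value is reported with its
    significance at α = 0.05/12.
    """
    e_mean = float(np.mean(euclidean_scores))
    c_mean = float(np.mean(cityblock_scores))
    diff = np.asarray(euclidean_scores) - np.asarray(cityblock_scores)
    if np.allclose(diff.std(ddof=1), 0.0):
        p = 0.0 if abs(diff.mean()) > 0 else 1.0
    else:
        p = float(stats.ttest_rel(euclidean_scores, cityblock_scores).pvalue)
    best: Metric = "cityblock" if c_mean > e_mean else "euclidean"
    return best, p, bool(p < METRIC_ALPHA)


def run_model_selection(
    trials: Sequence[TrialRecord],
    tables: Mapping[Metric, ChoiceLookupTable],
    config: FitConfig | None = None,
    plan: CrossValidationPlan | None = None,
    cv_config: FitConfig | None = None,
) -> SelectionResult:
    """Full preregistered ladder over all 8 specs on one shared partition.

    Each spec is first fit to the full data (multi-start per ``config``);
    that solution seeds the fold fits (``cv_config``, fewer starts by
    default).  Returns the winning spec together with per-spec CV scores,
    ladder p-values and the metric comparison.
    """
    if config is None:
        config = FitConfig()
    if plan is None:
        plan = make_cv_plan(trials, seed=config.seed)
    if cv_config is None:
        cv_config = FitConfig(n_starts=1, seed=config.seed,
                              max_iterations=config.max_iterations,
                              tol=config.tol)
    fold_scores: dict[ModelSpec, np.ndarray] = {}
    solutions: dict[ModelSpec, object] = {}
    for metric in METRICS:
        table = tables[metric]
        for variant in VARIANTS:
            spec = ModelSpec(variant, metric)
            full_fit = fit_model(trials, spec, table, config)
            solutions[spec] = full_fit
            fold_scores[spec] = cross_validate(
                trials, spec, plan, table, cv_config, warm_start=full_fit
            )
    ladder_p: dict[Metric, dict[str, float]] = {}
    best_variant: dict[Metric, Variant] = {}
    for metric in METRICS:
        by_variant = {v: fold_scores[ModelSpec(v, metric)] for v in VARIANTS}
        best_variant[metric], ladder_p[metric] = select_positional_variant(
            by_variant
        )
    best_metric, metric_p, significant = select_metric(
        fold_scores[ModelSpec(best_variant["euclidean"], "euclidean")],
        fold_scores[ModelSpec(best_variant["cityblock"], "cityblock")],
    )
    best_spec = ModelSpec(best_variant[best_metric], best_metric)
    return SelectionResult(
        best_spec=best_spec,
        mean_cv_log_likelihood={s: float(v.mean())
                                for s, v in fold_scores.items()},
        fold_scores=fold_scores,
        ladder_p_values=ladder_p,
        best_variant_by_metric=best_variant,
        metric_p_value=metric_p,
        metric_significant=significant,
        solutions=solutions,
    )
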