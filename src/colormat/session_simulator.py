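"""Synthetic experiments: simulate full sessions from a generating observer.

The default design mirrors the experiment: 8 blocks of 270 trials, each
block made of 9 interleaved sub-blocks of 30 trials — six adaptive
streams over the full ±3 stimulus range, one over ±2, one over ±1, and
one sub-block sampling pairs at random.  Trials run in groups of 9, one
trial per sub-block in random order within each group.  Adaptive streams
keep their own posterior state and, by default, persist it across blocks.

Responses are generated by the observer model itself — fresh noisy draws
of target and tests on every trial decided by the weighted-distance rule
— not from the lookup-table approximation, so the simulator embodies the
generative process the table approximates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_model import (
    Metric,
    ModelSolution,
    NominalStimulus,
    PositionalMapping,
    decide_trial,
)
from .fitting import TrialRecord
from .likelihood_engine import ChoiceLookupTable
from .questplus_engine import (
    QuestParameterGrid,
    candidate_pairs,
    init_quest,
    next_stimulus,
    update_posterior,
)


@dataclass(frozen=True)
class SessionDesign:
    """Block/sub-block composition of one simulated experiment."""

    n_blocks: int = 8
    quest_full_subblocks: int = 6
    quest_restricted2_subblocks: int = 1
    quest_restricted1_subblocks: int = 1
    random_subblocks: int = 1
    trials_per_subblock: int = 30
    reset_quest_each_block: bool = False
    seed: int = 0

    @property
    def n_subblocks(self) -> int:
        return (self.quest_full_subblocks + self.quest_restricted2_subblocks
                + self.quest_restricted1_subblocks + self.random_subblocks)

    @property
    def trials_per_block(self) -> int:
        return self.n_subblocks * self.trials_per_subblock

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass(frozen=True)
class GeneratingObserver:
    """True parameters of a simulated observer."""

    w: float
    mapping: PositionalMapping
    metric: Metric = "euclidean"

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w={self.w} outside [0, 1]")
        self.mapping.validate()

    def as_solution(self, log_likelihood: float = 0.0) -> ModelSolution:
        from .core_model import ModelSpec

        return ModelSolution(ModelSpec(self.mapping.variant, self.metric),
                             self.w, self.mapping, log_likelihood)


def _respond(
    observer: GeneratingObserver,
    pair: tuple[NominalStimulus, NominalStimulus],
    rng: np.random.Generator,
) -> int:
    """One stochastic response: noisy draws of target and both tests."""
    positions = observer.mapping.stimulus_positions(
        np.array([pair[0].astuple(), pair[1].astuple()])
    )
    target_draw = rng.standard_normal(2)
    t1_draw = positions[0] + rng.standard_normal(2)
    t2_draw = positions[1] + rng.standard_normal(2)
    return decide_trial(target_draw, t1_draw, t2_draw, observer.w,
                        observer.metric, rng)


def simulate_session(
    observer: GeneratingObserver,
    design: SessionDesign | None = None,
    grid: QuestParameterGrid | None = None,
    table: ChoiceLookupTable | None = None,
    seed: int | None = None,
    cache_dir=None,
) -> list[TrialRecord]:
    """Simulate a complete experiment for one generating observer.

    ``table`` must be the Euclidean lookup table (it drives the adaptive
    streams, matching the experimental convention).  ``seed`` overrides
    ``design.seed``.  Returns one :class:`TrialRecord` per trial, labeled
    with block, sub-block and source.
    """
    if design is None:
        design = SessionDesign()
    if grid is None:
        grid = QuestParameterGrid()
    if table is None:
        raise ValueError("a Euclidean lookup table is required")
    rng = np.random.default_rng(design.seed if seed is None else seed)

    # sub-block layout: sources and adaptive ranges, in fixed label order
    layout: list[tuple[str, int | None]] = (
        [("questFull", 3)] * design.quest_full_subblocks
        + [("questRestricted2", 2)] * design.quest_restricted2_subblocks
        + [("questRestricted1", 1)] * design.quest_restricted1_subblocks
        + [("random", None)] * design.random_subblocks
    )

    def fresh_states():
        return [init_quest(grid, r, table, cache_dir) if r is not None else None
                for _, r in layout]

    states = fresh_states()
    full_pairs = candidate_pairs(3)
    records: list[TrialRecord] = []
    for block in range(design.n_blocks):
        if design.reset_quest_each_block and block > 0:
            states = fresh_states()
        # random sub-blocks: 30 pairs without replacement within the block
        random_draws = {
            i: [full_pairs[j] for j in rng.choice(
                len(full_pairs), size=design.trials_per_subblock,
                replace=False)]
            for i, (src, r) in enumerate(layout) if r is None
        }
        for group in range(design.trials_per_subblock):
            order = rng.permutation(design.n_subblocks)
            for sub in order:
                source, r = layout[sub]
                if r is None:
                    pair = random_draws[sub][group]
                else:
                    pair = next_stimulus(states[sub])
                choice = _respond(observer, pair, rng)
                if r is not None:
                    states[sub] = update_posterior(states[sub], pair, choice)
                records.append(TrialRecord(
                    test1=pair[0], test2=pair[1], choice=choice,
                    block=block, sub_block=int(sub), source=source,
                ))
    return records


def simulate_fixed_pairs(
    observer: GeneratingObserver,
    pairs,
    n_repeats: int,
    seed: int = 0,
) -> list[TrialRecord]:
    """Method-of-constants harness: each pair shown ``n_repeats`` times.

    Presentation order is shuffled; responses are stochastic draws from
    the observer's true choice process.
    """
    if not pairs:
        raise ValueError("pairs must be nonempty")
    rng = np.random.default_rng(seed)
    schedule = [p for p in pairs for _ in range(n_repeats)]
    schedule = [schedule[i] for i in rng.permutation(len(schedule))]
    return [
        TrialRecord(test1=p[0], test2=p[1],
                    choice=_respond(observer, p, rng), source="fixed")
        for p in schedule
    ]
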