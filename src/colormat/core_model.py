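"""Domain types and the noisy-observer decision rule.

The observer model represents each stimulus as a bivariate Gaussian in a
latent color x material perceptual space.  The target sits at the origin;
the noise standard deviation is fixed at 1 per dimension, which sets the
units of the space.  On each ternary trial the observer draws a noisy
sample of the target and of both tests and picks the test whose sample is
closer to the target's sample under a weighted distance: color differences
are scaled by the color-material weight ``w`` and material differences by
``1 - w``, combined with either a Euclidean or a city-block norm.

Nominal stimulus levels are integers in [-3, +3] per dimension (49 design
stimuli); a positional mapping (linear / quadratic / cubic polynomial
through the origin, or a free per-level "full" map) carries nominal levels
to mean perceptual positions, constrained to be monotone, to stay within
+/-20 noise units and to keep adjacent levels at least 0.25 apart.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

Metric = Literal["euclidean", "cityblock"]
Variant = Literal["linear", "quadratic", "cubic", "full"]

METRICS: tuple[Metric, ...] = ("euclidean", "cityblock")
VARIANTS: tuple[Variant, ...] = ("linear", "quadratic", "cubic", "full")

#: free positional parameters per dimension for each mapping variant
PARAMS_PER_DIMENSION: dict[str, int] = {
    "linear": 1,
    "quadratic": 2,
    "cubic": 3,
    "full": 6,
}

#: nominal design levels per dimension
DESIGN_LEVELS = np.arange(-3, 4)

#: levels carrying a free parameter in the full variant (0 is pinned to 0)
FULL_LEVELS = np.array([-3, -2, -1, 1, 2, 3])


class ConstraintViolation(ValueError):
    """A positional mapping breaks monotonicity, spacing or range bounds."""


@dataclass(frozen=True)
class ModelConventions:
    """Fixed conventions that set the origin and scale of the model.

    These are not fittable: the target defines the origin and the unit
    perceptual noise defines the scale, so only relative geometry and the
    weight carry information.
    """

    noise_sd: float = 1.0
    position_bound: float = 20.0
    min_spacing: float = 0.25


CONVENTIONS = ModelConventions()


@dataclass(frozen=True)
class NominalStimulus:
    """A test object identified by integer (color, material) design levels."""

    color_level: int
    material_level: int

    def __post_init__(self) -> None:
        for name, v in (("color_level", self.color_level),
                        ("material_level", self.material_level)):
            if not -3 <= int(v) <= 3:
                raise ValueError(f"{name}={v} outside the design range [-3, 3]")

    @property
    def is_target(self) -> bool:
        return self.color_level == 0 and self.material_level == 0

    def astuple(self) -> tuple[int, int]:
        return (self.color_level, self.material_level)


TARGET = NominalStimulus(0, 0)


@dataclass(frozen=True)
class ModelSpec:
    """One of the 8 model variants: positional mapping x distance metric."""

    variant: Variant
    metric: Metric

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")

    @property
    def n_parameters(self) -> int:
        """Total free parameters: the weight plus both dimensions' mapping."""
        return 1 + 2 * PARAMS_PER_DIMENSION[self.variant]


ALL_SPECS: tuple[ModelSpec, ...] = tuple(
    ModelSpec(v, m) for m in METRICS for v in VARIANTS
)


def map_positions(
    variant: Variant,
    params: Sequence[float],
    levels: Sequence[int] | np.ndarray,
) -> np.ndarray:
    """Map nominal levels to mean perceptual positions for one dimension.

    Polynomial variants evaluate ``a1*s + a2*s^2 (+ a3*s^3)`` — no affine
    term, so level 0 maps to 0 exactly.  The full variant stores one free
    position per non-zero level (ordered as levels -3,-2,-1,+1,+2,+3) with
    level 0 pinned at 0.

    The returned positions are *not* validated here; use
    :func:`validate_positions` (fitting does so over the 7 design levels).
    """
    params = np.asarray(params, dtype=float)
    levels = np.asarray(levels)
    n_expected = PARAMS_PER_DIMENSION[variant]
    if params.shape != (n_expected,):
        raise ValueError(
            f"{variant} variant takes {n_expected} parameters per dimension, "
            f"got shape {params.shape}"
        )
    if np.any(levels < -3) or np.any(levels > 3):
        raise ValueError("nominal levels must lie in [-3, 3]")
    if variant == "full":
        lookup = np.zeros(7)
        lookup[FULL_LEVELS + 3] = params
        return lookup[levels + 3]
    s = levels.astype(float)
    out = params[0] * s
    if variant in ("quadratic", "cubic"):
        out = out + params[1] * s**2
    if variant == "cubic":
        out = out + params[2] * s**3
    return out


def validate_positions(
    positions: np.ndarray,
    *,
    conventions: ModelConventions = CONVENTIONS,
    dimension: str = "",
) -> None:
    """Check monotonicity, minimum spacing and range over the design levels.

    ``positions`` must be the implied positions at the 7 design levels in
    order.  Raises :class:`ConstraintViolation` naming the offending
    adjacent pair.
    """
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (7,):
        raise ValueError("expected positions at the 7 design levels")
    prefix = f"{dimension} dimension: " if dimension else ""
    if np.any(np.abs(positions) > conventions.position_bound):
        i = int(np.argmax(np.abs(positions) > conventions.position_bound))
        raise ConstraintViolation(
            f"{prefix}position {positions[i]:.3f} at level {DESIGN_LEVELS[i]} "
            f"outside [-{conventions.position_bound}, {conventions.position_bound}]"
        )
    gaps = np.diff(positions)
    bad = np.nonzero(gaps < conventions.min_spacing - 1e-12)[0]
    if bad.size:
        i = int(bad[0])
        word = "non-monotone" if gaps[i] <= 0 else "under-spaced"
        raise ConstraintViolation(
            f"{prefix}{word} adjacent pair (level {DESIGN_LEVELS[i]} -> "
            f"{DESIGN_LEVELS[i + 1]}): positions {positions[i]:.3f}, "
            f"{positions[i + 1]:.3f} (gap {gaps[i]:.3f} < "
            f"{conventions.min_spacing})"
        )


@dataclass(frozen=True)
class PositionalMapping:
    """Nominal-to-perceptual mapping for both dimensions.

    ``color_params`` and ``material_params`` have the per-dimension arity
    of the variant (1 linear, 2 quadratic, 3 cubic, 6 full).
    """

    variant: Variant
    color_params: tuple[float, ...]
    material_params: tuple[float, ...]

    def __post_init__(self) -> None:
        n = PARAMS_PER_DIMENSION[self.variant]
        for name, p in (("color_params", self.color_params),
                        ("material_params", self.material_params)):
            if len(p) != n:
                raise ValueError(
                    f"{name}: {self.variant} variant needs {n} values, got {len(p)}"
                )

    def positions(self, dimension: Literal["color", "material"],
                  levels: Sequence[int] | np.ndarray = DESIGN_LEVELS) -> np.ndarray:
        params = self.color_params if dimension == "color" else self.material_params
        return map_positions(self.variant, params, levels)

    def validate(self, conventions: ModelConventions = CONVENTIONS) -> None:
        for dim in ("color", "material"):
            validate_positions(self.positions(dim), conventions=conventions,
                               dimension=dim)

    def stimulus_positions(self, stimuli: np.ndarray) -> np.ndarray:
        """Perceptual (pC, pM) for an (n, 2) array of nominal levels."""
        stimuli = np.asarray(stimuli)
        pc = self.positions("color", stimuli[..., 0])
        pm = self.positions("material", stimuli[..., 1])
        return np.stack([pc, pm], axis=-1)


def linear_mapping(color_slope: float = 1.0,
                   material_slope: float | None = None) -> PositionalMapping:
    """Convenience constructor for a linear mapping (unit slopes by default)."""
    if material_slope is None:
        material_slope = color_slope
    return PositionalMapping("linear", (float(color_slope),),
                             (float(material_slope),))


@dataclass(frozen=True)
class ModelSolution:
    """A fitted (or generating) parameter set for one model spec."""

    spec: ModelSpec
    w: float
    mapping: PositionalMapping
    log_likelihood: float = 0.0
    identifiable: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"w={self.w} outside [0, 1]")
        if self.mapping.variant != self.spec.variant:
            raise ValueError("mapping variant does not match spec variant")


def weighted_distance(w: float, delta_c, delta_m, metric: Metric):
    """Weighted target-test distance from per-dimension differences.

    Euclidean: sqrt((w*dC)^2 + ((1-w)*dM)^2); city-block: w|dC| + (1-w)|dM|.
    Vectorized over ``delta_c`` / ``delta_m``.
    """
    if not 0.0 <= w <= 1.0:
        raise ValueError(f"w={w} outside [0, 1]")
    delta_c = np.asarray(delta_c, dtype=float)
    delta_m = np.asarray(delta_m, dtype=float)
    if metric == "euclidean":
        return np.hypot(w * delta_c, (1.0 - w) * delta_m)
    if metric == "cityblock":
        return w * np.abs(delta_c) + (1.0 - w) * np.abs(delta_m)
    raise ValueError(f"unknown metric {metric!r}")


def decide_trial(
    target_draw,
    test1_draw,
    test2_draw,
    w: float,
    metric: Metric,
    rng: np.random.Generator | None = None,
) -> int:
    """Choose the test whose noisy draw is closer to the target's draw.

    Draws are (pC, pM) samples (mean position + unit-SD noise).  Exact
    distance ties — a measure-zero event under continuous noise — are
    broken 50/50 from ``rng`` so that Monte-Carlo estimates stay unbiased.
    """
    t = np.asarray(target_draw, dtype=float)
    d1 = weighted_distance(w, t[0] - test1_draw[0], t[1] - test1_draw[1], metric)
    d2 = weighted_distance(w, t[0] - test2_draw[0], t[1] - test2_draw[1], metric)
    if d1 < d2:
        return 1
    if d2 < d1:
        return 2
    if rng is None:
        rng = np.random.default_rng()
    return 1 if rng.random() < 0.5 else 2
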