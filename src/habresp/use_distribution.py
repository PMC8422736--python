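"""Combine per-category log odds ratios into a multinomial use distribution.

Each non-reference land-cover category i has a fitted baseline-category
logit model providing the log odds ratio f_i of using i over the
reference, evaluated at that category's own relative availability in a
scenario.  The choice probabilities follow from the multinomial logit
link

    pi_i = exp(f_i) / (1 + sum_s exp(f_s)),    f_reference = 0,

so that the probabilities over all K categories sum to one.  Sweeping
the focal category's availability over its observed range (with the
background categories rescaled proportionally) traces the proportional
use curve to which Holling types are fitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

import numpy as np

__all__ = [
    "AvailabilityScenario",
    "UseDistribution",
    "UseCurve",
    "ConstantLogOdds",
    "make_scenario",
    "combine",
    "use_curve",
]


class LogOddsPredictor(Protocol):
    """Anything able to predict a log odds ratio for its focal category."""

    focal_category: str

    def predict_log_or(
        self, hour: int, month: int, sex: str, rel_availability: float, *, extrapolate: bool = False
    ) -> float: ...


@dataclass(frozen=True)
class ConstantLogOdds:
    """Stub predictor with a fixed log OR plus the availability offset.

    Useful for analytic checks: with ``include_offset`` the predicted
    log OR is ``value + log(x)`` (pure proportionality); without it the
    prediction is the constant ``value``.
    """

    focal_category: str
    value: float
    include_offset: bool = False

    def predict_log_or(self, hour, month, sex, rel_availability, *, extrapolate=False):
        if self.include_offset:
            return self.value + float(np.log(rel_availability))
        return self.value


@dataclass(frozen=True)
class AvailabilityScenario:
    """Availability simplex with one designated focal category."""

    focal_category: str
    focal_availability: float
    background: dict[str, float]  # availabilities of all other categories

    def __post_init__(self):
        total = self.focal_availability + sum(self.background.values())
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"availabilities must sum to 1 (got {total!r})")
        if self.focal_availability <= 0 or any(v < 0 for v in self.background.values()):
            raise ValueError("availabilities must be nonnegative (focal strictly positive)")

    def availability_of(self, category: str) -> float:
        if category == self.focal_category:
            return self.focal_availability
        return self.background[category]


@dataclass(frozen=True)
class UseDistribution:
    """Choice probabilities pi over categories at one time slot / scenario."""

    hour: int
    month: int
    sex: str
    scenario: AvailabilityScenario
    pi: dict[str, float]

    def __post_init__(self):
        s = sum(self.pi.values())
        if abs(s - 1.0) > 1e-10:
            raise ValueError(f"use distribution must sum to 1 (got {s!r})")


@dataclass(frozen=True)
class UseCurve:
    """Proportional use of the focal category over an availability grid."""

    focal_category: str
    hour: int
    month: int
    sex: str
    x: np.ndarray
    use: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.x) <= 0):
            raise ValueError("x grid must be strictly increasing")
        if np.any(self.use < -1e-12) or np.any(self.use > 1 + 1e-12):
            raise ValueError("proportional use must lie in [0, 1]")


def make_scenario(
    focal: str, x: float, mean_background: Mapping[str, float]
) -> AvailabilityScenario:
    """Scenario with focal availability x; backgrounds rescaled to 1 - x.

    Background categories keep their relative mix from
    ``mean_background`` (typically per-sex mean observed availability)
    but are scaled so that the whole simplex sums to one.
    """
    if not 0 < x < 1:
        raise ValueError("focal availability must lie strictly within (0, 1)")
    bg = {c: float(v) for c, v in mean_background.items() if c != focal}
    if not bg:
        raise ValueError("at least one background category is required")
    if any(v < 0 for v in bg.values()):
        raise ValueError("background availabilities must be nonnegative")
    total = sum(bg.values())
    if total <= 0:
        raise ValueError("background availabilities must not all be zero")
    scale = (1.0 - x) / total
    return AvailabilityScenario(focal, x, {c: v * scale for c, v in bg.items()})


def combine(
    models: Sequence[LogOddsPredictor],
    hour: int,
    month: int,
    sex: str,
    scenario: AvailabilityScenario,
    reference_category: str,
    *,
    extrapolate: bool = False,
) -> UseDistribution:
    """Multinomial use distribution from all K-1 log-odds models.

    Each model's log OR f_s is evaluated at its *own* category's
    availability in the scenario; the reference contributes f = 0.
    """
    cats = {m.focal_category for m in models}
    expected = set(scenario.background) | {scenario.focal_category}
    expected.discard(reference_category)
    missing = expected - cats
    if missing:
        raise ValueError(f"missing log-odds model(s) for categories: {sorted(missing)}")
    f = {}
    for m in models:
        x_own = scenario.availability_of(m.focal_category)
        val = m.predict_log_or(hour, month, sex, x_own, extrapolate=extrapolate)
        if not np.isfinite(val):
            raise ValueError(f"non-finite log OR for category {m.focal_category!r}")
        f[m.focal_category] = float(val)
    denom = 1.0 + sum(np.exp(v) for v in f.values())
    pi = {c: float(np.exp(v) / denom) for c, v in f.items()}
    pi[reference_category] = float(1.0 / denom)
    return UseDistribution(hour, month, sex, scenario, pi)


def use_curve(
    models: Sequence[LogOddsPredictor],
    hour: int,
    month: int,
    sex: str,
    focal: str,
    x_grid,
    mean_background: Mapping[str, float],
    reference_category: str,
    *,
    extrapolate: bool = False,
) -> UseCurve:
    """Proportional-use curve for the focal category over an x grid."""
    x_grid = np.atleast_1d(np.asarray(x_grid, dtype=float))
    use = np.empty_like(x_grid)
    for i, x in enumerate(x_grid):
        scen = make_scenario(focal, float(x), mean_background)
        dist = combine(models, hour, month, sex, scen, reference_category, extrapolate=extrapolate)
        use[i] = dist.pi[focal]
    return UseCurve(focal, hour, month, sex, x_grid, use)
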