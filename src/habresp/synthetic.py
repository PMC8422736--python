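"""Synthetic telemetry with known Holling-type functional responses.

Real multi-year GPS telemetry of large herbivores is rarely shareable,
so every downstream stage of the pipeline is exercised against
generated data whose ground truth is known.  The generative model
targets the same estimand as the analysis: the expected proportional
use of a land-cover category is a Holling curve of that category's
relative availability within the animal-month home range, optionally
modulated by time of day / month of year, sex, and individual- and
year-level random variation in prevalence (on the odds scale, mean
zero, so the population-median curve is the truth curve itself).

Fixes are drawn i.i.d. within an animal-month — emulating telemetry
thinned to long (> 25 h) inter-fix intervals, under which every point
of the home range is reachable and no movement autocorrelation
remains.  The reference category absorbs the residual probability
mass; scenarios in which that mass is not strictly positive fail
loudly rather than being silently renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .holling import eval_holling

__all__ = [
    "TruthCurve",
    "SimScenario",
    "dirichlet_sampler",
    "fixed_sampler",
    "generate_availability_vectors",
    "generate_telemetry",
]

# sampler signature: (rng, n, k, reference_index) -> (n, k) simplex rows
AvailabilitySampler = Callable[[np.random.Generator, int, int, int], np.ndarray]


def dirichlet_sampler(alpha: float = 1.0, min_reference: float = 0.05) -> AvailabilitySampler:
    """Symmetric Dirichlet(alpha) sampler rejecting low reference availability.

    The floor on the reference category keeps the log-availability
    offset finite for the reference in every generated home range.
    """

    def sample(rng: np.random.Generator, n: int, k: int, ref: int) -> np.ndarray:
        rows = []
        got = 0
        while got < n:
            batch = rng.dirichlet(np.full(k, alpha), size=max(n - got, 16))
            ok = batch[batch[:, ref] >= min_reference]
            rows.append(ok)
            got += len(ok)
        return np.concatenate(rows)[:n]

    return sample


def fixed_sampler(vector: Sequence[float]) -> AvailabilitySampler:
    """Degenerate sampler returning the same availability vector always."""
    v = np.asarray(vector, dtype=float)
    if abs(v.sum() - 1.0) > 1e-12 or np.any(v < 0):
        raise ValueError("fixed availability vector must be a simplex point")

    def sample(rng, n, k, ref):
        if k != len(v):
            raise ValueError("vector length does not match category count")
        return np.tile(v, (n, 1))

    return sample


@dataclass(frozen=True)
class TruthCurve:
    """Ground-truth functional response for one non-reference category.

    ``temporal_modifier(hour, month)`` and ``sex_modifier[sex]`` multiply
    the baseline Holling use; both default to 1.
    """

    category: str
    holling_type: str
    a: float
    b: float | None = None
    temporal_modifier: Callable[[int, int], float] | None = None
    sex_modifier: Mapping[str, float] | None = None

    def __post_init__(self):
        if not 0 <= self.a <= 1:
            raise ValueError("a must lie in [0, 1]")
        if self.holling_type in ("II", "III"):
            if self.b is None or not 0 <= self.b <= 1:
                raise ValueError("types II/III require b in [0, 1]")
        elif self.holling_type != "I":
            raise ValueError(f"unknown Holling type {self.holling_type!r}")

    def expected_use(self, x, hour: int | None = None, month: int | None = None,
                     sex: str | None = None) -> np.ndarray | float:
        """Expected proportional use before renormalization / random effects."""
        base = eval_holling(self.holling_type, self.a, self.b, x)
        factor = 1.0
        if self.temporal_modifier is not None and hour is not None and month is not None:
            factor *= self.temporal_modifier(hour, month)
        if self.sex_modifier is not None and sex is not None:
            factor *= self.sex_modifier[sex]
        if factor <= 0:
            raise ValueError("modifiers must be strictly positive")
        return base * factor


@dataclass(frozen=True)
class SimScenario:
    """Design of one synthetic study.

    ``n_individuals`` animals per sex are tracked for ``n_months``
    consecutive months (months beyond December roll into the next
    calendar year) with ``fixes_per_month`` fixes each.  Availability
    vectors over ``categories`` (last-named ``reference_category``
    absorbs residual use) are drawn per animal-month from
    ``availability_sampler``.  ``individual_prevalence_sd`` and
    ``year_effect_sd`` are standard deviations of mean-zero normal
    random intercepts on the log-odds scale.
    """

    n_individuals: int = 20
    n_months: int = 6
    fixes_per_month: int = 50
    categories: Sequence[str] = ("meadow", "old_mixed")
    reference_category: str = "old_mixed"
    availability_sampler: AvailabilitySampler | None = None
    individual_prevalence_sd: float = 0.3
    year_effect_sd: float = 0.1
    seed: int = 0
    start_year: int = 2005
    start_month: int = 1
    sexes: Sequence[str] = ("female", "male")

    def __post_init__(self):
        if len(self.categories) < 2:
            raise ValueError("need at least 2 categories (focal + reference)")
        if self.reference_category not in self.categories:
            raise ValueError("reference_category must be among categories")
        if self.n_individuals < 1 or self.n_months < 1 or self.fixes_per_month < 1:
            raise ValueError("counts must be positive")

    @property
    def reference_index(self) -> int:
        return list(self.categories).index(self.reference_category)

    def calendar(self) -> list[tuple[int, int]]:
        """(year, month) pairs for the tracked months."""
        out = []
        for i in range(self.n_months):
            m0 = self.start_month - 1 + i
            out.append((self.start_year + m0 // 12, m0 % 12 + 1))
        return out

    def animal_ids(self) -> list[tuple[str, str]]:
        """(id, sex) pairs, stable ordering."""
        ids = []
        for sex in self.sexes:
            for j in range(self.n_individuals):
                ids.append((f"{sex[0]}{j + 1:03d}", sex))
        return ids


def generate_availability_vectors(scenario: SimScenario) -> pd.DataFrame:
    """One availability simplex vector per animal-month.

    Returns a long table (id, sex, year, month, category, proportion);
    rows of one animal-month sum to 1.  Deterministic given the
    scenario seed.
    """
    rng = np.random.default_rng(scenario.seed)
    sampler = scenario.availability_sampler or dirichlet_sampler()
    animals = scenario.animal_ids()
    calendar = scenario.calendar()
    k = len(scenario.categories)
    n = len(animals) * len(calendar)
    vectors = sampler(rng, n, k, scenario.reference_index)
    if vectors.shape != (n, k) or np.any(vectors < 0):
        raise ValueError("sampler must return nonnegative rows of shape (n, k)")
    if np.max(np.abs(vectors.sum(axis=1) - 1.0)) > 1e-9:
        raise ValueError("sampler rows must sum to 1")
    rows = []
    i = 0
    for aid, sex in animals:
        for year, month in calendar:
            for c, cat in enumerate(scenario.categories):
                rows.append((aid, sex, year, month, cat, vectors[i, c]))
            i += 1
    return pd.DataFrame(rows, columns=["id", "sex", "year", "month", "category", "proportion"])


def _implied_use(
    scenario: SimScenario,
    truths: Mapping[str, TruthCurve],
    avail: np.ndarray,
    hour: int,
    month: int,
    sex: str,
    log_odds_shift: np.ndarray,
) -> np.ndarray:
    """Use probabilities over categories for one fix context.

    The truth curves give baseline use for each non-reference category
    at its own availability; the reference absorbs the remainder.
    Random intercepts (``log_odds_shift``, full category length with 0
    at the reference) shift the per-category log odds against the
    reference, after which probabilities are renormalized (mean-zero
    shifts leave the median curve at the truth).
    """
    cats = list(scenario.categories)
    ref = scenario.reference_index
    u = np.zeros(len(cats))
    for c, cat in enumerate(cats):
        if c == ref:
            continue
        u[c] = truths[cat].expected_use(avail[c], hour, month, sex)
    p_ref = 1.0 - u.sum()
    if p_ref <= 0:
        raise ValueError(
            "implied reference-category probability is not positive "
            f"(sex={sex}, month={month}, availabilities={np.round(avail, 4).tolist()})"
        )
    odds = u / p_ref
    odds = odds * np.exp(log_odds_shift)
    denom = 1.0 + odds.sum()
    pi = odds / denom
    pi[ref] = 1.0 / denom
    return pi


def generate_telemetry(
    scenario: SimScenario,
    truths: Sequence[TruthCurve],
    truth_grid: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw telemetry fixes from the implied multinomial use distribution.

    Returns ``(telemetry, truth_export)``: telemetry has columns
    id, sex, year, month, hour, x, y, category; truth_export records
    per-category expected proportional use over an availability grid
    (baseline: modifiers 1, random effects 0) for scoring estimators.
    """
    non_ref = [c for c in scenario.categories if c != scenario.reference_category]
    by_cat = {t.category: t for t in truths}
    if set(by_cat) != set(non_ref):
        raise ValueError(
            f"need exactly one TruthCurve per non-reference category {non_ref}; "
            f"got {sorted(by_cat)}"
        )
    avail_long = generate_availability_vectors(scenario)
    avail = avail_long.pivot_table(
        index=["id", "sex", "year", "month"], columns="category", values="proportion",
        sort=False,
    )[list(scenario.categories)]

    rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 1]))
    animals = scenario.animal_ids()
    calendar = scenario.calendar()
    years = sorted({y for y, _ in calendar})
    k_nr = len(non_ref)
    eps = {aid: rng.normal(0.0, scenario.individual_prevalence_sd, size=k_nr)
           for aid, _ in animals}
    gam = {y: rng.normal(0.0, scenario.year_effect_sd, size=k_nr) for y in years}

    cats = list(scenario.categories)
    nr_index = [cats.index(c) for c in non_ref]
    records = []
    for a_i, (aid, sex) in enumerate(animals):
        cx, cy = 2000.0 * a_i, 0.0  # placeholder home-range centers
        for year, month in calendar:
            v = avail.loc[(aid, sex, year, month)].to_numpy()
            shift = np.zeros(len(cats))
            shift[nr_index] = eps[aid] + gam[year]
            hours = rng.integers(0, 24, size=scenario.fixes_per_month)
            xy = rng.normal([cx, cy], 150.0, size=(scenario.fixes_per_month, 2))
            static = all(by_cat[c].temporal_modifier is None for c in non_ref)
            if static:
                pi = _implied_use(scenario, by_cat, v, 0, month, sex, shift)
                assert abs(pi.sum() - 1.0) <= 1e-12
                draws = rng.choice(len(cats), size=scenario.fixes_per_month, p=pi)
            else:
                draws = np.empty(scenario.fixes_per_month, dtype=int)
                for f, h in enumerate(hours):
                    pi = _implied_use(scenario, by_cat, v, int(h), month, sex, shift)
                    assert abs(pi.sum() - 1.0) <= 1e-12
                    draws[f] = rng.choice(len(cats), p=pi)
            for f in range(scenario.fixes_per_month):
                records.append(
                    (aid, sex, year, month, int(hours[f]), xy[f, 0], xy[f, 1], cats[draws[f]])
                )
    telemetry = pd.DataFrame(
        records, columns=["id", "sex", "year", "month", "hour", "x", "y", "category"]
    )

    if truth_grid is None:
        truth_grid = np.linspace(0.01, 0.95, 100)
    t_rows = []
    for c in non_ref:
        t = by_cat[c]
        for x in truth_grid:
            t_rows.append((c, float(x), float(eval_holling(t.holling_type, t.a, t.b, x))))
    truth_export = pd.DataFrame(t_rows, columns=["category", "x", "expected_use"])
    return telemetry, truth_export
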