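"""Holling type I/II/III functional-response curves for habitat use.

The functional response of habitat selection describes how the
proportional use y of a land-cover type changes with its relative
availability x within the home range:

* type I   (linear):            h_I(x)   = a * x
* type II  (concave/saturating): h_II(x)  = a * x / (b + x)
* type III (sigmoid):            h_III(x) = a * x^2 / (b^2 + x^2)

a is the maximum proportional use (an asymptote for II/III, the slope
for I), and b the availability at which use reaches half of its
maximum (the Michaelis-Menten constant for type II).  Curves are fitted
to a predicted use-vs-availability curve by bounded least squares; the
type with the smallest residual sum of squares wins.

Derived diagnostics (type II, a > b): the tipping point x* = a - b at
which use switches from disproportionately high to disproportionately
low; (type III, b < a/2): the crossings x_{1,2} = a/2 +- sqrt((a/2)^2
- b^2) of the identity line and the inflection point b/sqrt(3).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = [
    "HollingModel",
    "HollingResults",
    "Diagnostics",
    "eval_holling",
    "fit_type",
    "select_type",
    "diagnostics",
]

_TYPES = ("I", "II", "III")

# regime labels
LOW_EVERYWHERE = "disproportionate_low_everywhere"
SWITCH = "switch_at_x_star"
PROPORTIONAL = "proportional_everywhere"


def eval_holling(holling_type: str, a: float, b: float | None, x) -> np.ndarray | float:
    """Evaluate a Holling curve at availability x (scalar or array).

    For types II/III with b = 0 the value at x = 0 is taken as the
    limit 0 (the curve is the constant a for x > 0 when b = 0).
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if holling_type == "I":
        y = a * x
    elif holling_type == "II":
        if b is None:
            raise ValueError("type II requires b")
        denom = b + x
        with np.errstate(invalid="ignore", divide="ignore"):
            y = np.where(denom > 0, a * x / np.where(denom > 0, denom, 1.0), 0.0)
    elif holling_type == "III":
        if b is None:
            raise ValueError("type III requires b")
        denom = b * b + x * x
        with np.errstate(invalid="ignore", divide="ignore"):
            y = np.where(denom > 0, a * x * x / np.where(denom > 0, denom, 1.0), 0.0)
    else:
        raise ValueError(f"unknown Holling type {holling_type!r}")
    return float(y[0]) if scalar else y


@dataclass(frozen=True)
class Diagnostics:
    """Ecological diagnostics derived from a fitted Holling curve."""

    a_over_b: float | None  # +inf sentinel when b == 0; None for type I
    x_star: float | None  # tipping point a - b (type II, a > b)
    crossings: tuple[float, float] | None  # type III identity crossings
    inflection: float | None  # b / sqrt(3), type III only
    regime: str


@dataclass
class HollingResults:
    """Fit of one Holling type to a use-availability curve.

    Attributes
    ----------
    holling_type : {"I", "II", "III"}
    a, b : float
        Fitted parameters (``b`` is None for type I).
    rss : float
        Residual sum of squares at the fitted parameters.
    n_points : int
    """

    holling_type: str
    a: float
    b: float | None
    rss: float
    n_points: int
    diagnostics: Diagnostics = field(init=False)

    def __post_init__(self) -> None:
        self.diagnostics = diagnostics(self)

    def predict(self, x) -> np.ndarray | float:
        return eval_holling(self.holling_type, self.a, self.b, x)

    def summary(self) -> str:
        d = self.diagnostics
        lines = [
            "Holling functional-response fit",
            "=" * 34,
            f"type:        {self.holling_type}",
            f"a (max use): {self.a:.4f}",
        ]
        if self.b is not None:
            lines.append(f"b (half-sat): {self.b:.4f}")
            ab = "inf" if d.a_over_b == math.inf else f"{d.a_over_b:.4f}"
            lines.append(f"a/b:          {ab}")
        lines.append(f"rss:         {self.rss:.6g}  (n={self.n_points})")
        if d.x_star is not None:
            lines.append(f"tipping point x* = a - b = {d.x_star:.4f}")
        if d.crossings is not None:
            lines.append(f"use=availability at x1={d.crossings[0]:.4f}, x2={d.crossings[1]:.4f}")
        if d.inflection is not None:
            lines.append(f"inflection at b/sqrt(3) = {d.inflection:.4f}")
        lines.append(f"regime:      {d.regime}")
        return "\n".join(lines)


class HollingModel:
    """Bounded least-squares Holling-curve model for one use curve.

    Parameters
    ----------
    x : array-like
        Relative availabilities (distinct, in [0, 1]).
    y : array-like
        Proportional use at each availability.
    """

    def __init__(self, x, y):
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")
        if len(x) < 3:
            raise ValueError("need at least 3 points to fit a Holling curve")
        if len(np.unique(x)) != len(x):
            raise ValueError("availability values must be distinct")
        order = np.argsort(x)
        self.x = x[order]
        self.y = y[order]

    # -- fitting ---------------------------------------------------------
    def _basis(self, holling_type: str, b: np.ndarray) -> np.ndarray:
        """Unit-a curve values, shape (len(b), len(x))."""
        x = self.x[None, :]
        b = np.asarray(b, dtype=float)[:, None]
        if holling_type == "II":
            denom = b + x
        else:
            denom = b * b + x * x
            x = x * x
        with np.errstate(divide="ignore", invalid="ignore"):
            M = np.where(denom > 0, x / np.where(denom > 0, denom, 1.0), 0.0)
        return M

    def _profile_fit(self, holling_type: str, n_b: int = 1001) -> tuple[float, float, float]:
        """Best (a, b, rss) over a dense b grid with a solved in closed form."""
        bgrid = np.linspace(0.0, 1.0, n_b)
        M = self._basis(holling_type, bgrid)
        S2 = (M * M).sum(axis=1)
        S1 = (M * self.y[None, :]).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a_opt = np.where(S2 > 0, S1 / np.where(S2 > 0, S2, 1.0), 0.0)
        a_opt = np.clip(a_opt, 0.0, 1.0)
        rss = (self.y * self.y).sum() - 2 * a_opt * S1 + a_opt * a_opt * S2
        i = int(np.argmin(rss))
        return float(a_opt[i]), float(bgrid[i]), float(rss[i])

    def fit(self, holling_type: str | None = None) -> HollingResults:
        """Fit one type, or all three and select by smallest RSS.

        Optimization for types II/III is multi-start L-BFGS-B within the
        box [0,1]^2 (a 3x3 grid of starts plus a profile-grid start);
        type I has the closed-form bounded solution.  Ties between types
        (|dRSS| <= 1e-12) go to the lower type number.
        """
        if holling_type is None:
            fits = [self.fit(t) for t in _TYPES]
            best = fits[0]
            for f in fits[1:]:
                if f.rss < best.rss - 1e-12:
                    best = f
            return best
        if holling_type == "I":
            sxx = float(self.x @ self.x)
            a = float(np.clip((self.x @ self.y) / sxx, 0.0, 1.0))
            rss = float(np.sum((a * self.x - self.y) ** 2))
            return HollingResults("I", a, None, rss, len(self.x))
        if holling_type not in ("II", "III"):
            raise ValueError(f"unknown Holling type {holling_type!r}")

        x, y = self.x, self.y

        def rss_fn(p):
            return float(np.sum((eval_holling(holling_type, p[0], p[1], x) - y) ** 2))

        starts = [(ai, bi) for ai in (0.2, 0.5, 0.8) for bi in (0.2, 0.5, 0.8)]
        a0, b0, rss0 = self._profile_fit(holling_type)
        starts.append((a0, b0))
        best = (a0, b0, rss0)
        n_fail = 0
        for s in starts:
            res = minimize(rss_fn, np.asarray(s), method="L-BFGS-B", bounds=[(0, 1), (0, 1)])
            if not res.success:
                n_fail += 1
            if np.isfinite(res.fun) and res.fun < best[2]:
                best = (float(res.x[0]), float(res.x[1]), float(res.fun))
        if n_fail == len(starts) and not np.isfinite(best[2]):
            raise RuntimeError(
                f"Holling type {holling_type} optimization failed on all "
                f"{len(starts)} starts (n={len(x)} points)"
            )
        a, b, rss = best
        return HollingResults(holling_type, a, b, rss, len(x))


def fit_type(x, y, holling_type: str) -> HollingResults:
    """Fit a single Holling type to curve points by bounded least squares."""
    return HollingModel(x, y).fit(holling_type)


def select_type(x, y) -> HollingResults:
    """Fit all three Holling types and return the smallest-RSS fit."""
    return HollingModel(x, y).fit()


def diagnostics(fit: HollingResults) -> Diagnostics:
    """Derive tipping point, crossings, inflection, and use regime."""
    t, a, b = fit.holling_type, fit.a, fit.b
    if t == "I":
        regime = PROPORTIONAL if a >= 1.0 else LOW_EVERYWHERE
        return Diagnostics(None, None, None, None, regime)
    assert b is not None
    a_over_b = a / b if b > 0 else math.inf
    if t == "II":
        if a > b:
            return Diagnostics(a_over_b, a - b, None, None, SWITCH)
        return Diagnostics(a_over_b, None, None, None, LOW_EVERYWHERE)
    # type III
    inflection = b / math.sqrt(3.0)
    half = a / 2.0
    if b < half:
        root = math.sqrt(half * half - b * b)
        crossings = (half - root, half + root)
        return Diagnostics(a_over_b, None, crossings, inflection, SWITCH)
    return Diagnostics(a_over_b, None, None, inflection, LOW_EVERYWHERE)
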