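"""Focal-vs-reference logit models with an availability offset.

For each non-reference land-cover category a binary dataset is built:
fixes in the focal category (present = 1) versus fixes in the
reference category (present = 0), each row carrying the *focal*
category's relative availability in the recording animal-month.  The
log odds ratio of using the focal over the reference type is modelled
as

    f(x) = alpha + beta * sex + s1(hour, month) + s2(availability)
           + log(availability)          [offset, coefficient fixed at 1]
           + eps_id + gamma_year        [random intercepts]

The offset encodes the null hypothesis of use proportional to
availability; any fitted deviation s2 (parametric in log availability,
or a penalized spline with fixed smoothing parameter, default
lambda = 2) is the functional response.  The seasonal/diurnal term s1
is a cyclic tensor-product smooth with periods 24 h and 12 months.
Random intercepts for individual and year are fitted as ridge-penalized
group indicators whose variance is chosen by a Laplace-approximate
marginal-likelihood grid search.

Estimation is penalized iteratively reweighted least squares (PIRLS);
for unpenalized specifications it agrees with an ordinary binomial GLM.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from ._splines import BSplineBasis, CyclicBasis, tensor_design, tensor_penalty

__all__ = [
    "ModelSpec",
    "FocalLogitModel",
    "FocalLogitResults",
    "CVResult",
    "build_pairwise_dataset",
    "fit_logodds_model",
    "predict_log_or",
    "cross_validate",
    "default_candidate_specs",
]

_AVAIL_TERMS = ("offset_only", "parametric_log", "smooth")
_TEMPORAL_TERMS = ("none", "cyclic_hour_month", "cyclic_hour_month_by_sex")


@dataclass(frozen=True)
class ModelSpec:
    """Structure of one candidate focal-vs-reference model.

    The log-availability offset is always present; ``availability_term``
    controls the modelled deviation from proportionality.
    """

    availability_term: str = "smooth"
    smooth_penalty: float = 2.0
    availability_basis: int = 8
    temporal_term: str = "none"
    temporal_penalty: float = 2.0
    hour_basis: int = 8
    month_basis: int = 6
    sex_main: bool = False
    availability_by_sex: bool = False
    random_id: bool = True
    random_year: bool = True

    def __post_init__(self):
        if self.availability_term not in _AVAIL_TERMS:
            raise ValueError(f"availability_term must be one of {_AVAIL_TERMS}")
        if self.temporal_term not in _TEMPORAL_TERMS:
            raise ValueError(f"temporal_term must be one of {_TEMPORAL_TERMS}")
        if self.availability_by_sex and self.availability_term == "offset_only":
            raise ValueError("availability_by_sex requires an availability term")
        if self.smooth_penalty < 0 or self.temporal_penalty < 0:
            raise ValueError("penalties must be nonnegative")

    def label(self) -> str:
        bits = [self.availability_term, self.temporal_term]
        if self.sex_main:
            bits.append("sex")
        if self.availability_by_sex:
            bits.append("avail:sex")
        re = [n for n, f in (("id", self.random_id), ("year", self.random_year)) if f]
        bits.append("re(" + ",".join(re) + ")" if re else "no-re")
        return "+".join(bits)


def default_candidate_specs() -> list[ModelSpec]:
    """The default candidate grid for model selection.

    All combinations of availability term {offset_only, parametric_log,
    smooth} x temporal term {none, cyclic, cyclic-by-sex} with a sex
    main effect, plus availability-by-sex interactions where legal, and
    three variants without the year random intercept.
    """
    specs = []
    for av in _AVAIL_TERMS:
        for tt in _TEMPORAL_TERMS:
            specs.append(ModelSpec(availability_term=av, temporal_term=tt, sex_main=True))
    for av in ("parametric_log", "smooth"):
        for tt in _TEMPORAL_TERMS:
            specs.append(
                ModelSpec(availability_term=av, temporal_term=tt, sex_main=True,
                          availability_by_sex=True)
            )
    for av in _AVAIL_TERMS:
        specs.append(
            ModelSpec(availability_term=av, temporal_term="none", sex_main=True,
                      random_year=False)
        )
    return specs


# -- dataset construction ------------------------------------------------


def build_pairwise_dataset(
    telemetry: pd.DataFrame,
    availability: pd.DataFrame,
    focal: str,
    reference: str,
) -> tuple[pd.DataFrame, int]:
    """Focal-vs-reference rows with the focal availability joined in.

    Keeps fixes whose category is the focal (present = 1) or the
    reference (present = 0) type; every row receives the *focal*
    category's relative availability in the recording animal-month.
    Rows with zero focal availability are dropped (the log offset is
    undefined there); the count of such drops is returned alongside.
    """
    if focal == reference:
        raise ValueError("focal and reference categories must differ")
    av = availability[availability["category"] == focal]
    key = ["id", "year", "month"]
    av = av.drop_duplicates(subset=key).set_index(key)["proportion"]
    sub = telemetry[telemetry["category"].isin([focal, reference])].copy()
    mi = pd.MultiIndex.from_frame(sub[key])
    missing = ~mi.isin(av.index)
    if missing.any():
        bad = sub.loc[missing, key].drop_duplicates().head(3)
        raise ValueError(
            "availability table does not cover all telemetry animal-months, "
            f"e.g. {bad.to_dict('records')}"
        )
    sub["rel_availability"] = av.reindex(mi).to_numpy()
    sub["present"] = (sub["category"] == focal).astype(int)
    n_dropped = int((sub["rel_availability"] <= 0).sum())
    sub = sub[sub["rel_availability"] > 0]
    if sub.empty:
        raise ValueError(f"no usable rows for focal category {focal!r}")
    cols = ["present", "rel_availability", "hour", "month", "sex", "id", "year"]
    out = sub[cols].reset_index(drop=True)
    out.insert(1, "focal_category", focal)
    return out, n_dropped


# -- design matrices -----------------------------------------------------


@dataclass
class _Block:
    name: str
    kind: str  # "fixed", "smooth", "random"
    sl: slice
    penalty: np.ndarray | None  # constrained penalty (identity for random)
    lam: float  # multiplier (lambda for smooths; tau for random, set in fit)
    Q: np.ndarray | None = None  # sum-to-zero constraint reparameterization
    levels: list | None = None  # for random blocks


class _Design:
    """Design matrix + penalty assembly for one ModelSpec on one dataset."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        self.spec = spec
        x = data["rel_availability"].to_numpy(dtype=float)
        self.x_range = (float(x.min()), float(x.max()))
        self.sex_levels = sorted(data["sex"].unique().tolist())
        self.avail_basis: BSplineBasis | None = None
        if spec.availability_term == "smooth":
            lo, hi = self.x_range
            if hi <= lo:  # single availability value: no deviation estimable
                warnings.warn("availability has a single value; smooth dropped")
            else:
                self.avail_basis = BSplineBasis(lo, hi, spec.availability_basis)
        self.hour_basis = CyclicBasis(24.0, spec.hour_basis)
        self.month_basis = CyclicBasis(12.0, spec.month_basis)
        self.blocks: list[_Block] = []
        self._assemble(data)

    # fixed-effect (non-random) part of a design for arbitrary rows
    def _male(self, sex: np.ndarray) -> np.ndarray:
        if len(self.sex_levels) < 2:
            return np.zeros(len(sex))
        return (np.asarray(sex) == self.sex_levels[1]).astype(float)

    def _fixed_parts(self, x, hour, month, sex) -> list[tuple[str, str, np.ndarray, np.ndarray | None, float]]:
        """(name, kind, matrix, penalty, lambda) for each non-random block."""
        spec = self.spec
        n = len(x)
        parts = [("intercept", "fixed", np.ones((n, 1)), None, 0.0)]
        male = self._male(sex)
        if spec.sex_main and len(self.sex_levels) > 1:
            parts.append(("sex", "fixed", male[:, None], None, 0.0))
        if spec.availability_term == "parametric_log":
            lx = np.log(x)[:, None]
            parts.append(("log_avail", "fixed", lx, None, 0.0))
            if spec.availability_by_sex and len(self.sex_levels) > 1:
                parts.append(("log_avail:sex", "fixed", lx * male[:, None], None, 0.0))
        elif spec.availability_term == "smooth" and self.avail_basis is not None:
            B = self.avail_basis.design(x)
            S = self.avail_basis.penalty()
            parts.append(("s(avail)", "smooth", B, S, spec.smooth_penalty))
            if spec.availability_by_sex and len(self.sex_levels) > 1:
                parts.append(("s(avail):sex", "smooth", B * male[:, None], S, spec.smooth_penalty))
        if spec.temporal_term != "none":
            H = self.hour_basis.design(np.asarray(hour, dtype=float))
            M = self.month_basis.design(np.asarray(month, dtype=float) - 1.0)
            T = tensor_design(H, M)
            St = tensor_penalty(self.hour_basis.penalty(), self.month_basis.penalty())
            parts.append(("te(hour,month)", "smooth", T, St, spec.temporal_penalty))
            if spec.temporal_term == "cyclic_hour_month_by_sex" and len(self.sex_levels) > 1:
                parts.append(("te(hour,month):sex", "smooth", T * male[:, None], St,
                              spec.temporal_penalty))
        return parts

    def _assemble(self, data: pd.DataFrame) -> None:
        x = data["rel_availability"].to_numpy(dtype=float)
        parts = self._fixed_parts(x, data["hour"].to_numpy(), data["month"].to_numpy(),
                                  data["sex"].to_numpy())
        # sum-to-zero constraints: the constant function lies in both the
        # span and the penalty null space of every smooth basis, so it is
        # projected out (reparameterization by the null space of the
        # column-mean vector); interaction blocks reuse the base block's Q.
        from scipy.linalg import null_space

        Qs: dict[str, np.ndarray] = {}
        mats, col = [], 0
        for name, kind, M, S, lam in parts:
            Q = None
            if kind == "smooth":
                base = name.split(":")[0]
                if base in Qs:
                    Q = Qs[base]
                else:
                    c = M.mean(axis=0)[None, :]
                    Q = null_space(c)
                    Qs[base] = Q
                M = M @ Q
                S = Q.T @ S @ Q
            sl = slice(col, col + M.shape[1])
            col += M.shape[1]
            self.blocks.append(_Block(name, kind, sl, S, lam, Q))
            mats.append(M)
        self.n_fixed_cols = col
        for gname, flag in (("id", self.spec.random_id), ("year", self.spec.random_year)):
            if not flag:
                continue
            levels = sorted(data[gname].unique().tolist())
            if len(levels) < 2:
                warnings.warn(f"random intercept for {gname!r} dropped: <2 levels")
                continue
            idx = pd.Categorical(data[gname], categories=levels).codes
            Z = np.zeros((len(data), len(levels)))
            Z[np.arange(len(data)), idx] = 1.0
            sl = slice(col, col + len(levels))
            col += len(levels)
            self.blocks.append(_Block(f"re({gname})", "random", sl, None, 1.0, None, levels=levels))
            mats.append(Z)
        self.X = np.concatenate(mats, axis=1)
        self.n_cols = col

    def penalty_matrix(self, taus: dict[str, float]) -> np.ndarray:
        S = np.zeros((self.n_cols, self.n_cols))
        for b in self.blocks:
            if b.kind == "smooth":
                S[b.sl, b.sl] += b.lam * b.penalty
            elif b.kind == "random":
                S[b.sl, b.sl] += taus[b.name] * np.eye(b.sl.stop - b.sl.start)
        return S

    def fixed_row(self, hour, month, sex, x) -> np.ndarray:
        """Population-level design row (random intercepts at zero)."""
        parts = self._fixed_parts(
            np.asarray([float(x)]), np.asarray([hour]), np.asarray([month]), np.asarray([sex])
        )
        row = np.zeros(self.n_cols)
        by_name = {b.name: b for b in self.blocks}
        for name, kind, M, _, _ in parts:
            b = by_name.get(name)
            if b is None:
                continue
            v = M[0]
            if b.Q is not None:
                v = v @ b.Q
            row[b.sl] = v
        return row


# -- PIRLS ---------------------------------------------------------------


def _pirls(X, y, offset, S, beta0=None, max_iter=200, tol=1e-9):
    """Penalized IRLS for a Bernoulli logit with fixed offset.

    Newton steps on the penalized deviance with step halving, which
    keeps the iteration stable when weakly penalized spline directions
    would otherwise overshoot.  Returns (beta, mu, XtWX_at_solution).
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()

    def pen_dev(b):
        mu = np.clip(expit(X @ b + offset), 1e-10, 1 - 1e-10)
        dev = -2 * float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
        return dev + float(b @ S @ b), mu

    f_cur, mu = pen_dev(beta)
    for _ in range(max_iter):
        eta = X @ beta + offset
        w = mu * (1 - mu)
        z = eta - offset + (y - mu) / w
        XtW = X.T * w
        H = XtW @ X + S
        try:
            beta_new = np.linalg.solve(H, XtW @ z)
        except np.linalg.LinAlgError as e:
            raise np.linalg.LinAlgError(f"singular penalized system: {e}") from e
        step = beta_new - beta
        t = 1.0
        improved = False
        while t > 1e-12:
            f_cand, mu_cand = pen_dev(beta + t * step)
            if f_cand <= f_cur + 1e-12:
                improved = True
                break
            t *= 0.5
        if not improved:
            break
        beta = beta + t * step
        done = abs(f_cur - f_cand) < tol * (abs(f_cand) + 1)
        f_cur, mu = f_cand, mu_cand
        if done:
            break
    w = mu * (1 - mu)
    XtWX = (X.T * w) @ X
    return beta, mu, XtWX


def _loglik(y, mu):
    return float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


# -- model / results -----------------------------------------------------


class FocalLogitModel:
    """Baseline-category logit model for one focal land-cover type.

    Parameters
    ----------
    data : DataFrame
        Pairwise observations as produced by
        :func:`build_pairwise_dataset` (columns present,
        rel_availability, hour, month, sex, id, year).
    spec : ModelSpec
    focal_category : str, optional
        Defaults to the ``focal_category`` column of ``data``.
    """

    #: grid of candidate random-intercept standard deviations
    SIGMA_GRID = (0.05, 0.08, 0.12, 0.18, 0.27, 0.4, 0.6, 0.8, 1.0, 1.3, 1.7, 2.2)

    def __init__(self, data: pd.DataFrame, spec: ModelSpec | None = None,
                 focal_category: str | None = None, min_rows: int = 50):
        spec = spec or ModelSpec()
        if focal_category is None:
            focal_category = (
                str(data["focal_category"].iloc[0]) if "focal_category" in data else "focal"
            )
        y = data["present"].to_numpy(dtype=float)
        if len(data) < min_rows:
            raise ValueError(f"need at least {min_rows} rows (got {len(data)})")
        if y.min() == y.max():
            raise ValueError("both response levels (focal and reference) must be present")
        if (data["rel_availability"] <= 0).any():
            raise ValueError("rel_availability must be strictly positive")
        self.data = data.reset_index(drop=True)
        self.spec = spec
        self.focal_category = focal_category
        self.y = y
        self.offset = np.log(self.data["rel_availability"].to_numpy(dtype=float))
        self.design = _Design(self.data, spec)

    @classmethod
    def from_telemetry(cls, telemetry: pd.DataFrame, availability: pd.DataFrame,
                       focal: str, reference: str, spec: ModelSpec | None = None,
                       **kwargs) -> "FocalLogitModel":
        data, _ = build_pairwise_dataset(telemetry, availability, focal, reference)
        return cls(data, spec, focal_category=focal, **kwargs)

    def fit(self) -> "FocalLogitResults":
        d = self.design
        random_blocks = [b for b in d.blocks if b.kind == "random"]
        taus = {b.name: 1.0 / 0.3**2 for b in random_blocks}

        def run(taus, beta0=None):
            S = d.penalty_matrix(taus)
            beta, mu, XtWX = _pirls(d.X, self.y, self.offset, S, beta0)
            return beta, mu, XtWX, S

        try:
            beta, mu, XtWX, S = run(taus)
            if random_blocks:
                # coordinate-wise marginal-likelihood grid search per factor
                for b in random_blocks:
                    best, best_score = None, -np.inf
                    for sigma in self.SIGMA_GRID:
                        trial = dict(taus)
                        trial[b.name] = 1.0 / sigma**2
                        bt, mt, Xt, St = run(trial, beta)
                        ng = b.sl.stop - b.sl.start
                        score = (
                            _loglik(self.y, mt)
                            - 0.5 * float(bt @ St @ bt)
                            + 0.5 * ng * math.log(trial[b.name])
                            - 0.5 * float(np.linalg.slogdet(Xt + St)[1])
                        )
                        if score > best_score:
                            best, best_score = trial[b.name], score
                    taus[b.name] = best
                beta, mu, XtWX, S = run(taus, beta)
        except np.linalg.LinAlgError:
            if random_blocks:
                warnings.warn(
                    "singular random-effect fit; falling back to no random intercepts"
                )
                spec2 = ModelSpec(**{**asdict(self.spec), "random_id": False,
                                     "random_year": False})
                m2 = FocalLogitModel(self.data, spec2, self.focal_category, min_rows=1)
                return m2.fit()
            raise

        # quasi-complete separation: unpenalized coefficients blowing up
        unpen = [b for b in d.blocks if b.kind == "fixed"]
        if any(np.any(np.abs(beta[b.sl]) > 15) for b in unpen):
            raise ValueError(
                "quasi-complete separation detected: coefficients diverged; "
                "use a coarser model specification or more data"
            )
        H = XtWX + S
        edf = float(np.trace(np.linalg.solve(H, XtWX)))
        dev = -2 * _loglik(self.y, mu)
        sigmas = {b.name: 1.0 / math.sqrt(taus[b.name]) for b in random_blocks}
        return FocalLogitResults(self, beta, dev, edf, sigmas)


class FocalLogitResults:
    """Fitted focal-vs-reference log-odds model."""

    def __init__(self, model: FocalLogitModel, params: np.ndarray, deviance: float,
                 edf: float, re_sigmas: dict[str, float]):
        self.model = model
        self.focal_category = model.focal_category
        self.spec = model.spec
        self.params = params
        self.deviance = deviance
        self.edf = edf
        self.re_sigmas = re_sigmas
        self.nobs = len(model.y)
        self.training_range = model.design.x_range

    # random-effect point estimates by level
    def random_effects(self, factor: str) -> pd.Series:
        for b in self.model.design.blocks:
            if b.name == f"re({factor})":
                return pd.Series(self.params[b.sl], index=b.levels)
        raise KeyError(f"no random intercept for {factor!r}")

    def predict_log_or(self, hour: int, month: int, sex: str, rel_availability: float,
                       *, extrapolate: bool = False) -> float:
        """Population-level log odds ratio, including the offset.

        ``rel_availability`` must lie inside the training range unless
        ``extrapolate=True``.
        """
        lo, hi = self.training_range
        x = float(rel_availability)
        if x <= 0:
            raise ValueError("rel_availability must be positive")
        if not extrapolate and not (lo - 1e-12 <= x <= hi + 1e-12):
            raise ValueError(
                f"rel_availability {x:.4g} outside training range [{lo:.4g}, {hi:.4g}]; "
                "pass extrapolate=True to override"
            )
        row = self.model.design.fixed_row(hour, month, sex, x)
        return float(row @ self.params + math.log(x))

    def summary(self) -> str:
        d = self.model.design
        lines = [
            f"Focal-vs-reference logit: {self.focal_category}",
            "=" * 46,
            f"spec:       {self.spec.label()}",
            f"n obs:      {self.nobs}   deviance: {self.deviance:.2f}   edf: {self.edf:.2f}",
            f"avail range: [{self.training_range[0]:.4f}, {self.training_range[1]:.4f}]"
            "  (offset log(avail) fixed at 1)",
        ]
        for b in d.blocks:
            if b.kind == "fixed":
                vals = ", ".join(f"{v:+.4f}" for v in self.params[b.sl])
                lines.append(f"  {b.name:<22s} {vals}")
            elif b.kind == "smooth":
                lines.append(f"  {b.name:<22s} penalized ({b.sl.stop - b.sl.start} basis fns, "
                             f"lambda={b.lam:g})")
        for name, s in self.re_sigmas.items():
            lines.append(f"  {name:<22s} sigma = {s:.3f}")
        return "\n".join(lines)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = self.model.design
        return {
            "focal_category": self.focal_category,
            "spec": asdict(self.spec),
            "params": self.params.tolist(),
            "deviance": self.deviance,
            "edf": self.edf,
            "re_sigmas": self.re_sigmas,
            "nobs": self.nobs,
            "training_range": list(self.training_range),
            "sex_levels": d.sex_levels,
            "blocks": [
                {
                    "name": b.name, "kind": b.kind,
                    "start": b.sl.start, "stop": b.sl.stop,
                    "Q": None if b.Q is None else b.Q.tolist(),
                }
                for b in d.blocks
            ],
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


class SerializedLogOdds:
    """Log-odds predictor rebuilt from a serialized model dictionary.

    Supports population-level prediction only (random intercepts at
    zero), which is all the downstream use-distribution stage needs.
    """

    def __init__(self, d: dict):
        self.focal_category = d["focal_category"]
        self.spec = ModelSpec(**d["spec"])
        self.params = np.asarray(d["params"], dtype=float)
        self.training_range = tuple(d["training_range"])
        self.sex_levels = d["sex_levels"]
        self.blocks = d["blocks"]
        lo, hi = self.training_range
        self.avail_basis = (
            BSplineBasis(lo, hi, self.spec.availability_basis)
            if self.spec.availability_term == "smooth" and hi > lo
            else None
        )
        self.hour_basis = CyclicBasis(24.0, self.spec.hour_basis)
        self.month_basis = CyclicBasis(12.0, self.spec.month_basis)

    @classmethod
    def load(cls, path) -> "SerializedLogOdds":
        with open(path) as fh:
            return cls(json.load(fh))

    def predict_log_or(self, hour, month, sex, rel_availability, *, extrapolate=False):
        lo, hi = self.training_range
        x = float(rel_availability)
        if x <= 0:
            raise ValueError("rel_availability must be positive")
        if not extrapolate and not (lo - 1e-12 <= x <= hi + 1e-12):
            raise ValueError(
                f"rel_availability {x:.4g} outside training range [{lo:.4g}, {hi:.4g}]"
            )
        male = float(len(self.sex_levels) > 1 and sex == self.sex_levels[1])
        vals: dict[str, np.ndarray] = {"intercept": np.ones(1)}
        if self.spec.sex_main and len(self.sex_levels) > 1:
            vals["sex"] = np.array([male])
        if self.spec.availability_term == "parametric_log":
            vals["log_avail"] = np.array([math.log(x)])
            vals["log_avail:sex"] = np.array([male * math.log(x)])
        elif self.avail_basis is not None:
            B = self.avail_basis.design(np.array([x]))[0]
            vals["s(avail)"] = B
            vals["s(avail):sex"] = B * male
        if self.spec.temporal_term != "none":
            T = tensor_design(
                self.hour_basis.design(np.array([float(hour)])),
                self.month_basis.design(np.array([float(month) - 1.0])),
            )[0]
            vals["te(hour,month)"] = T
            vals["te(hour,month):sex"] = T * male
        eta = 0.0
        for b in self.blocks:
            if b["kind"] == "random" or b["name"] not in vals:
                continue
            v = vals[b["name"]]
            if b["Q"] is not None:
                v = v @ np.asarray(b["Q"])
            eta += float(v @ self.params[b["start"]:b["stop"]])
        return eta + math.log(x)


# -- functional wrappers -------------------------------------------------


def fit_logodds_model(data: pd.DataFrame, spec: ModelSpec | None = None,
                      **kwargs) -> FocalLogitResults:
    """Fit a focal-vs-reference logit model (see :class:`FocalLogitModel`)."""
    return FocalLogitModel(data, spec, **kwargs).fit()


def predict_log_or(results: FocalLogitResults, hour, month, sex, rel_availability,
                   *, extrapolate: bool = False) -> float:
    return results.predict_log_or(hour, month, sex, rel_availability,
                                  extrapolate=extrapolate)


# -- cross-validation ----------------------------------------------------


@dataclass
class CVResult:
    ranking: pd.DataFrame  # columns: spec_index, label, score, edf
    chosen: ModelSpec
    chosen_index: int
    k: int


def cross_validate(data: pd.DataFrame, candidate_specs: Sequence[ModelSpec],
                   k: int = 10, seed: int = 0, min_rows: int = 1) -> CVResult:
    """Rank candidate model structures by grouped k-fold log loss.

    Folds are grouped by animal id (all rows of one animal fall in the
    same fold) to avoid leakage across folds; the score is the mean
    over folds of the held-out log loss of population-level
    predictions.  The best (lowest) mean score wins; ties (within 1e-9)
    go to the candidate with fewer effective parameters, then to the
    earlier-listed one.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if not candidate_specs:
        raise ValueError("candidate_specs must be nonempty")
    ids = np.array(sorted(data["id"].unique()))
    if len(ids) < k:
        warnings.warn(f"only {len(ids)} animals; reducing folds from {k} to {len(ids)}")
        k = len(ids)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    fold_of = {aid: i % k for i, aid in enumerate(ids[perm])}
    folds = data["id"].map(fold_of).to_numpy()

    rows = []
    for si, spec in enumerate(candidate_specs):
        losses, edfs = [], []
        for f in range(k):
            train = data[folds != f]
            test = data[folds == f]
            if train["present"].nunique() < 2 or test.empty:
                continue
            try:
                res = FocalLogitModel(train, spec, min_rows=min_rows).fit()
            except (ValueError, np.linalg.LinAlgError):
                losses.append(np.inf)
                continue
            eta = np.array([
                res.predict_log_or(h, m, s, x, extrapolate=True)
                for h, m, s, x in zip(test["hour"], test["month"], test["sex"],
                                      test["rel_availability"])
            ])
            p = np.clip(expit(eta), 1e-12, 1 - 1e-12)
            yv = test["present"].to_numpy(dtype=float)
            losses.append(float(-np.mean(yv * np.log(p) + (1 - yv) * np.log(1 - p))))
            edfs.append(res.edf)
        rows.append({
            "spec_index": si,
            "label": spec.label(),
            "score": float(np.mean(losses)) if losses else np.inf,
            "edf": float(np.mean(edfs)) if edfs else np.nan,
        })
    ranking = pd.DataFrame(rows)
    order = ranking.sort_values(
        by=["score", "edf", "spec_index"], kind="stable"
    ).reset_index(drop=True)
    best_score = order.loc[0, "score"]
    tied = ranking[np.abs(ranking["score"] - best_score) <= 1e-9]
    min_edf = tied["edf"].min()
    tied2 = tied[np.abs(tied["edf"] - min_edf) <= 1e-9] if np.isfinite(min_edf) else tied
    chosen_index = int(tied2["spec_index"].min())
    return CVResult(order, candidate_specs[chosen_index], chosen_index, k)
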