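"""Wood lactation-curve fitting.

The Wood model describes daily yield as a gamma-shaped function of day in
milk t:

    W(t) = a * t**b * exp(-c * t),      k = ln(a)

``a`` scales the curve (it is related to total production), ``b`` governs the
sharpness of the early rise, and ``c`` the rate of decline after the peak.
The curve peaks at t_max = b/c with maximum yield maxY = a * (b/c)**b *
exp(-b); a flat-start curve (b = 0) peaks at t = 0 with maxY = a.

The model is log-linear, ln W = k + b ln t - c t, so ordinary least squares
on the log scale gives a closed-form fit which a natural-scale nonlinear
least-squares refinement can polish.  A two-stage population fit (per-curve
estimates shrunk toward fixed-effect-adjusted means with inverse-variance
weights) approximates a nonlinear mixed model with a random ewe-by-lactation
effect while staying deterministic and unit-testable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "WoodParams",
    "UnfittableCurveError",
    "predict_yield",
    "peak",
    "fit_wood_loglinear",
    "fit_wood_nls",
    "fit_population",
    "WoodCurveModel",
    "PopulationWoodModel",
    "PopulationWoodResults",
]

TRAITS_RAW = ("MY", "protein%", "fat%", "lactose%", "SCC")


class UnfittableCurveError(ValueError):
    """Raised when a lactation has too few positive records to fit."""


@dataclass(frozen=True)
class WoodParams:
    """Parameters of one fitted Wood curve.

    Attributes
    ----------
    a, k, b, c :
        Curve parameters; ``k = ln(a)`` always.  ``c <= 0`` marks a
        non-declining fit and is retained with the ``non_declining`` flag
        rather than dropped (downstream persistency is then undefined).
    n_obs :
        Number of positive-yield records used in the fit.
    rss :
        Residual sum of squares on the scale the fit was performed on.
    """

    a: float
    b: float
    c: float
    n_obs: int = 0
    rss: float = np.nan
    flags: tuple[str, ...] = ()
    cov_kbc: np.ndarray | None = field(default=None, compare=False, repr=False)

    @property
    def k(self) -> float:
        return float(np.log(self.a))

    def __post_init__(self):
        if not (self.a > 0):
            raise ValueError("Wood scale parameter a must be positive")
        if self.b < 0:
            raise ValueError("Wood rise exponent b must be nonnegative")
        if self.n_obs and self.n_obs < 3:
            raise ValueError("a Wood fit needs at least 3 observations")

    @property
    def non_declining(self) -> bool:
        return self.c <= 0 or "non_declining" in self.flags

    def with_flags(self, *extra: str) -> "WoodParams":
        return replace(self, flags=tuple(dict.fromkeys(self.flags + extra)))


def predict_yield(p: WoodParams, t):
    """Expected yield W(t) = a t^b e^{-ct}; t must be positive."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0):
        raise ValueError("day in milk must be positive")
    w = p.a * t**p.b * np.exp(-p.c * t)
    return float(w) if w.ndim == 0 else w


def peak(p: WoodParams) -> tuple[float, float]:
    """(t_max, maxY): day of maximum and maximum expected yield.

    t_max = b/c and maxY = a (b/c)^b e^{-b}; for b = 0 the maximum sits on
    the boundary t -> 0 with maxY = a.
    """
    if p.b == 0:
        return 0.0, p.a
    if p.c <= 0:
        # no interior maximum for a non-declining curve
        return np.inf, np.inf
    t_max = p.b / p.c
    return t_max, p.a * t_max**p.b * np.exp(-p.b)


def _positive_records(records: pd.DataFrame):
    days = records["day"].to_numpy(dtype=float)
    vals = records["value"].to_numpy(dtype=float)
    if np.any(days < 1):
        raise ValueError("day in milk must be >= 1")
    keep = vals > 0
    return days[keep], vals[keep], int((~keep).sum())


def fit_wood_loglinear(records: pd.DataFrame) -> WoodParams:
    """OLS fit of ln W = k + b ln t - c t to one lactation.

    ``records`` is a long-format frame with columns ``day`` and ``value``;
    zero yields are excluded (counted in a ``zeros_excluded:<n>`` flag).
    """
    t, y, n_zero = _positive_records(records)
    if t.size < 3 or np.unique(t).size < 3:
        raise UnfittableCurveError(
            f"need >= 3 positive records on distinct days, got {t.size}"
        )
    X = np.column_stack([np.ones_like(t), np.log(t), -t])
    z = np.log(y)
    beta, _, _, _ = np.linalg.lstsq(X, z, rcond=None)
    k, b, c = beta
    resid = z - X @ beta
    rss = float(resid @ resid)
    dof = t.size - 3
    cov = None
    if dof > 0:
        xtx_inv = np.linalg.pinv(X.T @ X)
        cov = xtx_inv * (rss / dof)
    flags = []
    if n_zero:
        flags.append(f"zeros_excluded:{n_zero}")
    if b < 0:
        b = 0.0
        flags.append("b_clipped")
    if c <= 0:
        flags.append("non_declining")
    return WoodParams(
        a=float(np.exp(k)),
        b=float(b),
        c=float(c),
        n_obs=t.size,
        rss=rss,
        flags=tuple(flags),
        cov_kbc=cov,
    )


def fit_wood_nls(records: pd.DataFrame, init: WoodParams) -> WoodParams:
    """Refine a Wood fit by nonlinear least squares on the natural scale.

    Parameterised as (k, b, c) with a = e^k so the scale stays positive.
    Returns ``init`` flagged ``non_converged`` if the optimiser fails; the
    natural-scale RSS never exceeds that of ``init``.
    """
    t, y, n_zero = _positive_records(records)
    if t.size < 3:
        raise UnfittableCurveError("need >= 3 positive records")

    def resid(theta):
        k, b, c = theta
        return np.exp(k) * t**b * np.exp(-c * t) - y

    x0 = np.array([init.k, init.b, init.c])
    lower = np.array([-np.inf, 0.0, -np.inf])
    try:
        sol = least_squares(resid, x0, bounds=(lower, np.inf), max_nfev=400)
    except Exception:  # pragma: no cover - optimiser failure path
        sol = None
    rss0 = float(np.sum(resid(x0) ** 2))
    flags = tuple(f for f in init.flags if f != "non_declining")
    if n_zero and not any(f.startswith("zeros_excluded") for f in flags):
        flags = flags + (f"zeros_excluded:{n_zero}",)
    if sol is None or not np.isfinite(sol.cost) or 2 * sol.cost > rss0 + 1e-12:
        return replace(init, rss=rss0, flags=flags + ("non_converged",))
    k, b, c = sol.x
    rss = float(2 * sol.cost)
    new_flags = list(flags)
    if c <= 0:
        new_flags.append("non_declining")
    if b <= 1e-12 and c <= 1e-10:
        new_flags.append("boundary_flat")
    return WoodParams(
        a=float(np.exp(k)),
        b=float(max(b, 0.0)),
        c=float(c),
        n_obs=t.size,
        rss=rss,
        flags=tuple(dict.fromkeys(new_flags)),
        cov_kbc=init.cov_kbc,
    )


class WoodCurveModel:
    """Wood model for a single ewe-by-lactation record set.

    Parameters
    ----------
    records : DataFrame
        Long-format yield records with columns ``day`` and ``value``.

    Examples
    --------
    >>> fit = WoodCurveModel(recs).fit()          # doctest: +SKIP
    >>> fit.params.c, fit.t_max, fit.max_yield    # doctest: +SKIP
    """

    def __init__(self, records: pd.DataFrame):
        self.records = records

    def fit(self, method: str = "nls") -> WoodParams:
        ll = fit_wood_loglinear(self.records)
        if method == "loglinear":
            return ll
        if method != "nls":
            raise ValueError(f"unknown method {method!r}")
        return fit_wood_nls(self.records, ll)


# ---------------------------------------------------------------------------
# Two-stage population fit with fixed-effect standardisation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FixedEffectSpec:
    """Categorical covariates per lactation with stated reference levels."""

    factors: tuple[str, ...] = ()
    reference_levels: dict = field(default_factory=dict)

    def __post_init__(self):
        for f in self.factors:
            if f not in self.reference_levels:
                raise ValueError(f"no reference level for factor {f!r}")


@dataclass
class PopulationWoodResults:
    """Per-lactation shrunk parameters plus population-level estimates.

    ``per_lactation`` holds one row per ewe x lactation with raw and shrunk
    (k, b, c), shrinkage weights and flags; ``population_means`` are the
    fixed-effect-adjusted means at the reference levels; ``effects`` the
    estimated additive factor-level effects per parameter.
    """

    per_lactation: pd.DataFrame
    population_means: dict
    effects: pd.DataFrame
    non_estimable: list

    def summary(self) -> str:
        lines = ["Population Wood fit (two-stage shrinkage)"]
        lines.append(f"  lactations: {len(self.per_lactation)}")
        for par, mu in self.population_means.items():
            lines.append(f"  mean {par} (reference levels): {mu: .4f}")
        if self.non_estimable:
            lines.append(f"  non-estimable levels pooled: {self.non_estimable}")
        return "\n".join(lines)


def _shrink(raw: np.ndarray, fitted_mean: np.ndarray, s2: np.ndarray):
    resid = raw - fitted_mean
    tau2 = max(float(np.var(resid, ddof=1) - np.nanmean(s2)), 0.0)
    w = tau2 / (tau2 + s2)
    return fitted_mean + w * resid, w


def fit_population(
    records: pd.DataFrame,
    spec: FixedEffectSpec | None = None,
    covariates: pd.DataFrame | None = None,
    method: str = "nls",
) -> PopulationWoodResults:
    """Fit all lactations and shrink (k, b, c) toward adjusted means.

    Stage one fits each ewe-by-lactation curve separately; stage two
    regresses each parameter on the fixed-effect factors (treatment coding
    at the stated reference levels) and shrinks each raw estimate toward its
    fitted mean with weight tau^2 / (tau^2 + s_j^2), where s_j^2 is the
    per-curve sampling variance and tau^2 a method-of-moments
    between-lactation variance.  Reported parameters are standardised to the
    reference levels by subtracting the estimated factor effects.
    """
    import statsmodels.api as sm

    groups = list(records.groupby(["ewe_id", "lactation_id"], sort=True))
    if len(groups) < 2:
        raise ValueError("population fit needs at least 2 lactations")
    rows = []
    for (ewe, lact), sub in groups:
        try:
            pars = fit_wood_nls(sub, fit_wood_loglinear(sub)) if method == "nls" \
                else fit_wood_loglinear(sub)
        except UnfittableCurveError:
            continue
        s2 = (
            np.diag(pars.cov_kbc)
            if pars.cov_kbc is not None
            else np.full(3, np.nan)
        )
        rows.append(
            dict(
                ewe_id=ewe,
                lactation_id=lact,
                k=pars.k,
                b=pars.b,
                c=pars.c,
                n_obs=pars.n_obs,
                rss=pars.rss,
                s2_k=s2[0],
                s2_b=s2[1],
                s2_c=s2[2],
                flags=";".join(pars.flags),
            )
        )
    per = pd.DataFrame(rows)
    if len(per) < 2:
        raise ValueError("fewer than 2 fittable lactations")

    spec = spec or FixedEffectSpec()
    non_estimable: list = []
    design_cols: list[str] = []
    X = pd.DataFrame(index=per.index)
    X["const"] = 1.0
    if spec.factors:
        if covariates is None:
            raise ValueError("fixed-effect spec given but no covariates")
        cov = per[["ewe_id", "lactation_id"]].merge(
            covariates, on=["ewe_id", "lactation_id"], how="left"
        )
        for f in spec.factors:
            ref = spec.reference_levels[f]
            levels = cov[f].fillna(ref).astype(str)
            counts = levels.value_counts()
            # a level represented by a single lactation is not estimable;
            # pool it with the reference level
            for lev, cnt in counts.items():
                if cnt < 2 and lev != str(ref):
                    non_estimable.append((f, lev))
                    levels = levels.replace(lev, str(ref))
            for lev in sorted(levels.unique()):
                if lev == str(ref):
                    continue
                col = f"{f}[{lev}]"
                X[col] = (levels == lev).astype(float).to_numpy()
                design_cols.append(col)

    pop_means: dict = {}
    eff_rows = []
    for par in ("k", "b", "c"):
        y = per[par].to_numpy(dtype=float)
        fit = sm.OLS(y, X.to_numpy()).fit()
        fitted = fit.fittedvalues
        s2 = per[f"s2_{par}"].to_numpy(dtype=float)
        s2 = np.where(np.isfinite(s2), s2, np.nanmax(s2[np.isfinite(s2)]) if np.isfinite(s2).any() else 0.0)
        shrunk, w = _shrink(y, fitted, s2)
        adjustment = fitted - fit.params[0]  # deviation from reference-level mean
        per[f"{par}_shrunk"] = shrunk
        per[f"{par}_adj"] = shrunk - adjustment
        per[f"w_{par}"] = w
        pop_means[par] = float(fit.params[0])
        for name, est, se in zip(X.columns, fit.params, fit.bse):
            if name == "const":
                continue
            eff_rows.append(dict(parameter=par, term=name, estimate=est, se=se))
    effects = pd.DataFrame(eff_rows, columns=["parameter", "term", "estimate", "se"])
    per["a_adj"] = np.exp(per["k_adj"])
    return PopulationWoodResults(
        per_lactation=per,
        population_means=pop_means,
        effects=effects,
        non_estimable=non_estimable,
    )


class PopulationWoodModel:
    """statsmodels-style wrapper around :func:`fit_population`."""

    def __init__(self, records, spec=None, covariates=None):
        self.records = records
        self.spec = spec
        self.covariates = covariates

    @classmethod
    def from_dataframe(cls, records, spec=None, covariates=None):
        return cls(records, spec=spec, covariates=covariates)

    def fit(self, method: str = "nls") -> PopulationWoodResults:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return fit_population(
                self.records, self.spec, self.covariates, method=method
            )
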