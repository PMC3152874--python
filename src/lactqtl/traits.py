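"""Derived lactation traits: persistency, extended lactation, component yields.

All shape traits derive from the fitted Wood curve, not from raw-data
interpolation:

* cumulative yield   CumY(T) = a c^{-(b+1)} gamma_lower(b+1, cT)
* persistency        PersY(T) = W(T) / maxY, evaluated at T = 100 days
* extended lactation [CumY(300) - CumY(100)] / CumY(100)

Component yields combine composition percentages with milk yield:
PY = protein% * MY / 100 (likewise FY, LY), SCS = log10(SCC), SCY = SCS * MY,
and useful yield UY = FY + 1.85 * PY (a cheese-merit index).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammainc, gamma as gamma_fn

from .wood import WoodParams, peak, predict_yield

__all__ = [
    "YIELD_TRAITS",
    "cumulative_yield",
    "persistency",
    "extended_lactation",
    "component_yields",
    "derive_trait_table",
    "summarize_traits",
    "trait_correlations",
]

YIELD_TRAITS = ("MY", "PY", "FY", "LY", "UY", "SCY")

#: default reference day for persistency and the extended-lactation window
T_PERSISTENCY = 100.0
T_EXTENDED = 300.0


def cumulative_yield(p: WoodParams, T: float) -> float:
    """Exact integral of the Wood curve over [0, T].

    Uses the lower incomplete gamma function: with u = ct,
    int_0^T a t^b e^{-ct} dt = a c^{-(b+1)} gamma_lower(b+1, cT).
    """
    if T < 0:
        raise ValueError("T must be nonnegative")
    if T == 0:
        return 0.0
    if p.c <= 0:
        raise ValueError("cumulative yield undefined for non-declining fit")
    s = p.b + 1.0
    return float(p.a * p.c ** (-s) * gammainc(s, p.c * T) * gamma_fn(s))


def persistency(p: WoodParams, T: float = T_PERSISTENCY) -> float:
    """PersY(T) = W(T)/maxY in (0, 1]; NaN for non-declining fits."""
    if p.non_declining:
        return np.nan
    _, max_y = peak(p)
    if not np.isfinite(max_y) or max_y <= 0:
        return np.nan
    return float(predict_yield(p, T) / max_y) if T > 0 else np.nan


def extended_lactation(
    p: WoodParams, T0: float = T_PERSISTENCY, T1: float = T_EXTENDED
) -> float:
    """[CumY(T1) - CumY(T0)] / CumY(T0); larger = more extended lactation."""
    if p.non_declining:
        return np.nan
    c0 = cumulative_yield(p, T0)
    if c0 <= 0:
        return np.nan
    return float((cumulative_yield(p, T1) - c0) / c0)


def component_yields(MY, protein_pct=None, fat_pct=None, lactose_pct=None, SCC=None):
    """Per-record component yields from milk yield and composition.

    Returns a dict with PY, FY, LY, SCS, SCY, UY (entries NaN where the
    needed input is absent; SCS/SCY are NaN for nonpositive SCC).
    """
    MY = np.asarray(MY, dtype=float)
    if np.any(MY < 0):
        raise ValueError("milk yield must be nonnegative")

    def pct_yield(pct):
        if pct is None:
            return np.full_like(MY, np.nan)
        pct = np.asarray(pct, dtype=float)
        if np.any((pct < 0) | (pct > 100)):
            raise ValueError("composition percentages must lie in [0, 100]")
        return pct * MY / 100.0

    PY = pct_yield(protein_pct)
    FY = pct_yield(fat_pct)
    LY = pct_yield(lactose_pct)
    if SCC is None:
        SCS = np.full_like(MY, np.nan)
    else:
        SCC = np.asarray(SCC, dtype=float)
        SCS = np.where(SCC > 0, np.log10(np.where(SCC > 0, SCC, 1.0)), np.nan)
    SCY = SCS * MY
    UY = FY + 1.85 * PY
    out = dict(PY=PY, FY=FY, LY=LY, SCS=SCS, SCY=SCY, UY=UY)
    return {k: (float(v) if v.ndim == 0 else v) for k, v in out.items()}


def derive_trait_table(fits: dict, T: float = T_PERSISTENCY) -> pd.DataFrame:
    """Per-ewe persistency/extended-lactation table from fitted curves.

    ``fits`` maps (ewe_id, trait) -> WoodParams for trait in YIELD_TRAITS.
    Rows with non-declining fits carry NaN and a reason code.
    """
    rows = []
    for (ewe, trait), p in sorted(fits.items(), key=lambda kv: (str(kv[0][0]), kv[0][1])):
        reason = ""
        if p.non_declining:
            pers = ext = c100 = c300 = tmax = maxy = np.nan
            reason = "non_declining_fit"
        else:
            pers = persistency(p, T)
            ext = extended_lactation(p)
            c100 = cumulative_yield(p, T)
            c300 = cumulative_yield(p, T_EXTENDED)
            tmax, maxy = peak(p)
        rows.append(
            dict(
                ewe_id=ewe,
                trait=trait,
                persistency=pers,
                extended_lactation=ext,
                cum100=c100,
                cum300=c300,
                t_max=tmax,
                maxY=maxy,
                reason=reason,
            )
        )
    return pd.DataFrame(rows)


def summarize_traits(table: pd.DataFrame) -> pd.DataFrame:
    """Descriptive statistics (n, mean, SD, min, max) per trait x measure."""
    if table.empty:
        raise ValueError("empty trait table")
    rows = []
    for measure in ("persistency", "extended_lactation"):
        for trait, sub in table.groupby("trait", sort=False):
            v = sub[measure].dropna()
            if v.empty:
                continue
            rows.append(
                dict(
                    measure=measure,
                    trait=trait,
                    n=len(v),
                    mean=v.mean(),
                    SD=v.std(ddof=1) if len(v) > 1 else 0.0,
                    min=v.min(),
                    max=v.max(),
                )
            )
    return pd.DataFrame(rows)


def trait_correlations(table: pd.DataFrame, min_pairs: int = 3) -> pd.DataFrame:
    """Pairwise-complete correlations among persistency/extended columns.

    Columns are ``<measure>:<trait>``; cells with fewer than ``min_pairs``
    complete pairs are NaN.
    """
    wide = {}
    for measure in ("persistency", "extended_lactation"):
        piv = table.pivot_table(
            index="ewe_id", columns="trait", values=measure, aggfunc="mean"
        )
        for trait in piv.columns:
            wide[f"{measure}:{trait}"] = piv[trait]
    W = pd.DataFrame(wide)
    corr = W.corr(min_periods=min_pairs)
    np.fill_diagonal(corr.values, 1.0)
    return corr
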