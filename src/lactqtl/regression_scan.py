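"""Half-sib regression interval mapping (Haley–Knott style).

In a single-sire backcross the daughters form one half-sib family, so the
regression scan reduces to one within-family regression of the trait on the
signed transmission score x_i = 2 P_i(A) - 1 at each position:

    F(pos) = [(RSS0 - RSS1) / 1] / [RSS1 / (n - 2)]

Significance is assessed against permutation distributions of the
chromosome-wide maximum F (experiment-wide levels by Bonferroni adjustment
of the chromosome-wise alpha over the 26 autosomes), positional confidence
intervals by bootstrap resampling of daughters, QTL heritability from the
residual mean squares of the nested fits, and a two-QTL model by grid
search over position pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .results import ScanResults
from .mle_scan import support_interval, _flanking, _null_fit

__all__ = [
    "scan_regression",
    "permute_thresholds",
    "bootstrap_ci",
    "qtl_heritability",
    "scan_two_qtl",
    "PermutationThresholds",
    "TwoQTLResult",
    "HalfSibScanModel",
    "N_AUTOSOMES",
]

N_AUTOSOMES = 26


def _fstats(y, X):
    """1-df regression F at every column of X; NaN for zero-variance columns."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    yc = y - y.mean()
    Xc = X - X.mean(axis=0, keepdims=True)
    sxx = np.einsum("nm,nm->m", Xc, Xc)
    sxy = yc @ Xc
    rss0 = float(yc @ yc)
    with np.errstate(invalid="ignore", divide="ignore"):
        rss1 = rss0 - sxy**2 / sxx
        F = np.where(sxx > 1e-12, (rss0 - rss1) / (rss1 / (n - 2)), np.nan)
    return F, rss0, np.where(sxx > 1e-12, rss1, rss0), sxy, sxx


def scan_regression(
    y,
    grid,
    P,
    chromosome: int | None = None,
    lmap=None,
    min_n: int = 30,
) -> ScanResults:
    """Least-squares single-QTL scan; F statistic per grid position."""
    y = np.asarray(y, dtype=float)
    if y.size < min_n:
        raise ValueError(f"need >= {min_n} daughters")
    P = np.asarray(P, dtype=float)
    if P.shape[0] != y.size:
        P = P.T
    X = 2.0 * P - 1.0
    F, rss0, rss1, sxy, sxx = _fstats(y, X)
    grid = np.asarray(grid, dtype=float)
    skipped = ~np.isfinite(F)
    Fv = np.where(skipped, -np.inf, F)
    if not np.isfinite(Fv).any():
        raise ValueError("no informative position on chromosome")
    ipk = int(np.argmax(Fv))
    n = y.size
    beta = sxy[ipk] / sxx[ipk]
    sigma_p = float(np.std(y))  # no-QTL phenotypic SD
    # allele contrast = beta * (x(A)=+1 minus x(M)=-1) = 2 beta
    eff_sd = 2.0 * beta / sigma_p if sigma_p > 0 else np.nan
    se_beta = np.sqrt(rss1[ipk] / (n - 2) / sxx[ipk])
    lo, hi = support_interval(grid[~skipped], np.asarray(F)[~skipped],
                              drop=_f_drop_equivalent(F[ipk], n))
    profile = pd.DataFrame(
        dict(position_cM=grid, F=F, skipped=skipped)
    )
    return ScanResults(
        statistic="F",
        chromosome=chromosome,
        profile=profile,
        peak_position=float(grid[ipk]),
        peak_value=float(F[ipk]),
        support_interval=(lo, hi),
        effect_estimate=float(2.0 * beta),
        effect_sd_units=float(eff_sd),
        effect_se_sd_units=float(2.0 * se_beta / sigma_p) if sigma_p > 0 else np.nan,
        flanking_markers=_flanking(lmap, chromosome, float(grid[ipk])),
        n=n,
        metadata={
            "rss0": rss0,
            "rss1_peak": float(rss1[ipk]),
            "heritability": qtl_heritability(float(rss1[ipk]), rss0, n - 2,
                                             n - 1, warn=False),
            "n_skipped_positions": int(skipped.sum()),
        },
    )


def _f_drop_equivalent(f_peak, n):
    """F drop matching a 1-LOD drop at the peak (via LOD = (n/2)log10(RSS0/RSS1))."""
    lod_peak = (n / 2.0) * np.log10(1.0 + f_peak / (n - 2))
    lod_lo = max(lod_peak - 1.0, 0.0)
    f_lo = (n - 2) * (10.0 ** (2.0 * lod_lo / n) - 1.0)
    return float(f_peak - f_lo)


@dataclass
class PermutationThresholds:
    """Empirical thresholds for the chromosome-wide maximum F statistic."""

    chromosome: int | None
    thresholds: dict = field(default_factory=dict)
    n_permutations: int = 0
    seed: int | None = None
    trait: str | None = None

    def threshold(self, scope: str = "chromosome", alpha: float = 0.05) -> float:
        return self.thresholds[(scope, alpha)]

    def classify(self, f_value: float) -> str:
        """Star labels in increasing stringency, empty when below all."""
        stars = ""
        if f_value > self.thresholds[("chromosome", 0.05)]:
            stars = "*"
        if f_value > self.thresholds[("chromosome", 0.01)]:
            stars = "**"
        if f_value > self.thresholds[("experiment", 0.05)]:
            stars = "***"
        if f_value > self.thresholds[("experiment", 0.01)]:
            stars = "****"
        return stars


def permute_thresholds(
    y,
    grid,
    P,
    n: int = 1000,
    seed: int = 0,
    chromosome: int | None = None,
    alphas=(0.05, 0.01),
    n_autosomes: int = N_AUTOSOMES,
) -> PermutationThresholds:
    """Permutation thresholds for the chromosome-wide max F.

    Phenotypes are permuted against genotype rows ``n`` times; the maximum F
    over the chromosome grid is recorded per permutation and thresholds are
    its empirical quantiles.  Experiment-wide levels use chromosome-wise
    alpha / n_autosomes (Bonferroni over the autosomes).
    """
    if n < 100:
        raise ValueError("need at least 100 permutations")
    y = np.asarray(y, dtype=float)
    P = np.asarray(P, dtype=float)
    if P.shape[0] != y.size:
        P = P.T
    X = 2.0 * P - 1.0
    rng = np.random.default_rng(seed)
    nobs = y.size
    Xc = X - X.mean(axis=0, keepdims=True)
    sxx = np.einsum("nm,nm->m", Xc, Xc)
    good = sxx > 1e-12
    Xc = Xc[:, good]
    sxx = sxx[good]
    # permute y rows: (n_perm, n) index matrix
    idx = np.argsort(rng.random((n, nobs)), axis=1)
    Yp = y[idx]
    Yc = Yp - Yp.mean(axis=1, keepdims=True)
    rss0 = np.einsum("pn,pn->p", Yc, Yc)
    sxy = Yc @ Xc
    rss1 = rss0[:, None] - sxy**2 / sxx
    F = (rss0[:, None] - rss1) / (rss1 / (nobs - 2))
    fmax = F.max(axis=1)
    thresholds = {}
    for a in alphas:
        thresholds[("chromosome", a)] = float(np.quantile(fmax, 1.0 - a))
        thresholds[("experiment", a)] = float(
            np.quantile(fmax, 1.0 - a / n_autosomes)
        )
    return PermutationThresholds(
        chromosome=chromosome, thresholds=thresholds, n_permutations=n, seed=seed
    )


def bootstrap_ci(
    y,
    grid,
    P,
    n: int = 1000,
    seed: int = 0,
    level: float = 0.95,
    max_redraws: int = 100,
):
    """Bootstrap confidence interval for QTL position (percentile method).

    Daughters are resampled with replacement; the scan-peak position is
    recorded per resample and the CI is the central ``level`` quantile
    range.  Monomorphic resamples are redrawn (count logged in the result).
    """
    y = np.asarray(y, dtype=float)
    P = np.asarray(P, dtype=float)
    if P.shape[0] != y.size:
        P = P.T
    X = 2.0 * P - 1.0
    grid = np.asarray(grid, dtype=float)
    rng = np.random.default_rng(seed)
    nobs = y.size
    peaks = np.empty(n)
    redraws = 0
    for b in range(n):
        for _ in range(max_redraws + 1):
            take = rng.integers(0, nobs, size=nobs)
            Xb = X[take]
            Fb, *_ = _fstats(y[take], Xb)
            if np.isfinite(Fb).any():
                break
            redraws += 1
        peaks[b] = grid[int(np.nanargmax(np.where(np.isfinite(Fb), Fb, -np.inf)))]
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(peaks, [tail, 1.0 - tail])
    return dict(
        ci=(float(lo), float(hi)),
        peaks=peaks,
        n_resamples=n,
        n_redraws=redraws,
        level=level,
        seed=seed,
    )


def qtl_heritability(rss_full, rss_reduced, df_full, df_reduced,
                     warn: bool = True) -> float:
    """Proportion of phenotypic variance explained by the QTL.

    1 - (residual mean square full) / (residual mean square reduced),
    clipped at zero (with a warning) when the full model fits worse.
    """
    if df_full <= 0 or df_reduced <= 0:
        raise ValueError("degrees of freedom must be positive")
    rms_full = rss_full / df_full
    rms_red = rss_reduced / df_reduced
    if rms_full <= 0 or rms_red <= 0:
        raise ValueError("residual mean squares must be positive")
    h = 1.0 - rms_full / rms_red
    if h < 0:
        if warn:
            warnings.warn("negative QTL heritability clipped to 0",
                          stacklevel=2)
        return 0.0
    return float(h)


@dataclass
class TwoQTLResult:
    """Best two-QTL fit on one chromosome."""

    chromosome: int | None
    position_a: float
    position_b: float
    f_2v0: float
    f_2v1: float
    effect_a_sd: float
    effect_b_sd: float
    se_a_sd: float
    se_b_sd: float
    phase: str
    flanking_a: tuple | None = None
    flanking_b: tuple | None = None
    rss2: float = np.nan
    rss1: float = np.nan
    rss0: float = np.nan

    def summary(self) -> str:
        return "\n".join(
            [
                "Two-QTL fit",
                "=" * 40,
                f"chromosome:      {self.chromosome}",
                f"QTL A / QTL B:   {self.position_a:.1f} / {self.position_b:.1f} cM",
                f"F(2 vs 0):       {self.f_2v0:.2f}",
                f"F(2 vs 1):       {self.f_2v1:.2f}",
                f"effects (SD):    {self.effect_a_sd:+.2f} ({self.se_a_sd:.2f}), "
                f"{self.effect_b_sd:+.2f} ({self.se_b_sd:.2f})",
                f"phase:           {self.phase}",
            ]
        )


def scan_two_qtl(
    y,
    grid,
    P,
    chromosome: int | None = None,
    lmap=None,
    pair_step: float = 2.0,
    min_separation: float = 5.0,
) -> TwoQTLResult:
    """Grid search for the best additive two-QTL model on one chromosome.

    Full model y ~ x(A) + x(B) over ordered position pairs at least
    ``min_separation`` cM apart on a ``pair_step`` cM sub-grid;
    F(2vs0) tests both QTL jointly, F(2vs1) tests the second QTL against
    the best single-QTL fit on the chromosome.
    """
    y = np.asarray(y, dtype=float)
    P = np.asarray(P, dtype=float)
    if P.shape[0] != y.size:
        P = P.T
    grid = np.asarray(grid, dtype=float)
    # sub-grid at pair_step spacing (always including the end markers)
    keep = [0]
    for i in range(1, grid.size):
        if grid[i] - grid[keep[-1]] >= pair_step - 1e-9 or i == grid.size - 1:
            keep.append(i)
    keep = np.array(sorted(set(keep)))
    if keep.size < 3:
        raise ValueError("two-QTL scan needs >= 3 grid positions")
    pos = grid[keep]
    X = 2.0 * P[:, keep] - 1.0
    n = y.size
    yc = y - y.mean()
    rss0 = float(yc @ yc)
    F1, _, rss1_all, _, _ = _fstats(y, X)
    rss1_best = float(np.nanmin(rss1_all))
    best = None
    Xc = X - X.mean(axis=0, keepdims=True)
    for i in range(keep.size):
        for j in range(i + 1, keep.size):
            if pos[j] - pos[i] < min_separation:
                continue
            D = Xc[:, [i, j]]
            G = D.T @ D
            if np.linalg.cond(G) > 1e10:
                continue
            coef = np.linalg.solve(G, D.T @ yc)
            resid = yc - D @ coef
            rss2 = float(resid @ resid)
            if best is None or rss2 < best[0]:
                best = (rss2, i, j, coef, G)
    if best is None:
        raise ValueError("no admissible position pair")
    rss2, i, j, coef, G = best
    sigma2 = rss2 / (n - 3)
    cov = np.linalg.inv(G) * sigma2
    sigma_p = float(np.std(y))
    eff = 2.0 * coef / sigma_p
    se = 2.0 * np.sqrt(np.diag(cov)) / sigma_p
    f_2v0 = ((rss0 - rss2) / 2.0) / sigma2
    f_2v1 = ((rss1_best - rss2) / 1.0) / sigma2
    phase = "repulsion" if coef[0] * coef[1] < 0 else "coupling"
    return TwoQTLResult(
        chromosome=chromosome,
        position_a=float(pos[i]),
        position_b=float(pos[j]),
        f_2v0=float(f_2v0),
        f_2v1=float(f_2v1),
        effect_a_sd=float(eff[0]),
        effect_b_sd=float(eff[1]),
        se_a_sd=float(se[0]),
        se_b_sd=float(se[1]),
        phase=phase,
        flanking_a=_flanking(lmap, chromosome, float(pos[i])),
        flanking_b=_flanking(lmap, chromosome, float(pos[j])),
        rss2=rss2,
        rss1=rss1_best,
        rss0=rss0,
    )


class HalfSibScanModel:
    """statsmodels-style front end for the half-sib regression scan.

    ``fit()`` runs the single-QTL scan; ``permutation_thresholds()``,
    ``bootstrap_ci()`` and ``fit_two_qtl()`` expose the resampling and
    two-QTL machinery on the same data.
    """

    def __init__(self, y, grid, P, chromosome=None, lmap=None, log_transform=False):
        if log_transform:
            from .mle_scan import transform_trait

            y, self._transform_meta = transform_trait(y)
        else:
            self._transform_meta = {"transform": "identity"}
        self.y = np.asarray(y, dtype=float)
        self.grid = np.asarray(grid, dtype=float)
        self.P = np.asarray(P, dtype=float)
        self.chromosome = chromosome
        self.lmap = lmap

    @classmethod
    def from_study(cls, trait_values, geno, lmap, chromosome, step=1.0,
                   log_transform=True):
        from .linkage import transmission_prob_grid

        grid, P = transmission_prob_grid(geno, lmap, chromosome, step=step)
        return cls(trait_values, grid, P, chromosome=chromosome, lmap=lmap,
                   log_transform=log_transform)

    def fit(self) -> ScanResults:
        res = scan_regression(self.y, self.grid, self.P,
                              chromosome=self.chromosome, lmap=self.lmap)
        res.metadata.update(self._transform_meta)
        return res

    def permutation_thresholds(self, n=1000, seed=0, **kw) -> PermutationThresholds:
        return permute_thresholds(self.y, self.grid, self.P, n=n, seed=seed,
                                  chromosome=self.chromosome, **kw)

    def bootstrap_ci(self, n=1000, seed=0, level=0.95):
        return bootstrap_ci(self.y, self.grid, self.P, n=n, seed=seed, level=level)

    def fit_two_qtl(self, **kw) -> TwoQTLResult:
        return scan_two_qtl(self.y, self.grid, self.P,
                            chromosome=self.chromosome, lmap=self.lmap, **kw)
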