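"""Linkage map, sire-transmission genotypes and transmitted-allele probabilities.

The mapping family is a single-sire backcross: an F1 (Awassi x Merino) ram
mated to Merino ewes.  At every autosomal locus each daughter inherits either
the Awassi ("A") or the Merino ("M") allele from the sire, so the sire meiosis
is a two-state process along each chromosome.  Given the transmitted alleles
observed at microsatellite markers, the probability that the Awassi allele was
transmitted at an arbitrary chromosomal position is obtained by conditioning
on the nearest informative flanking markers under the Haldane map function
(no crossover interference).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ALLELE_A = "A"
ALLELE_M = "M"
MISSING = {"", "NA", "N", "nan", "-", "?"}

__all__ = [
    "LinkageMap",
    "TransmissionMatrix",
    "haldane",
    "kosambi",
    "recombination_fraction",
    "transmission_prob",
    "transmission_prob_grid",
    "scan_grid",
]


def haldane(d):
    """Map distance (cM) -> recombination fraction under Haldane.

    r = (1 - exp(-2d/100)) / 2, in [0, 0.5).
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(r) if r.ndim == 0 else r


def kosambi(d):
    """Map distance (cM) -> recombination fraction under Kosambi."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("map distance must be nonnegative")
    r = 0.5 * np.tanh(2.0 * d / 100.0)
    return float(r) if r.ndim == 0 else r


def recombination_fraction(d, map_function: str = "haldane"):
    if map_function == "haldane":
        return haldane(d)
    if map_function == "kosambi":
        return kosambi(d)
    raise ValueError(f"unknown map function: {map_function!r}")


@dataclass
class LinkageMap:
    """Framework marker map over the 26 sheep autosomes.

    Stored as a DataFrame with columns ``chromosome`` (int), ``marker`` (str)
    and ``position_cM`` (float, nondecreasing within chromosome).
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        t = self.table
        required = {"chromosome", "marker", "position_cM"}
        if not required.issubset(t.columns):
            raise ValueError(f"map table needs columns {sorted(required)}")
        if t["marker"].duplicated().any():
            dups = t.loc[t["marker"].duplicated(), "marker"].tolist()
            raise ValueError(f"duplicate marker names: {dups}")
        if (t["position_cM"] < 0).any():
            raise ValueError("marker positions must be nonnegative")
        t = t.sort_values(["chromosome", "position_cM"], kind="stable")
        self.table = t.reset_index(drop=True)

    @property
    def chromosomes(self) -> list[int]:
        return sorted(self.table["chromosome"].unique().tolist())

    @property
    def n_markers(self) -> int:
        return len(self.table)

    def markers(self, chromosome: int) -> pd.DataFrame:
        sub = self.table[self.table["chromosome"] == chromosome]
        if sub.empty:
            raise KeyError(f"chromosome {chromosome} not in map")
        return sub.reset_index(drop=True)

    @classmethod
    def from_csv(cls, path) -> "LinkageMap":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class TransmissionMatrix:
    """Daughter x marker matrix of transmitted sire alleles ('A'/'M'/NaN)."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        d = self.data
        vals = d.to_numpy(dtype=object).ravel()
        bad = {
            v
            for v in vals
            if not (v is None or (isinstance(v, float) and np.isnan(v)))
            and str(v) not in (ALLELE_A, ALLELE_M)
            and str(v) not in MISSING
        }
        if bad:
            raise ValueError(f"unexpected allele codes: {sorted(map(str, bad))}")
        d = d.astype(object)
        d[d.isin(list(MISSING))] = np.nan
        self.data = d

    @property
    def daughters(self) -> list:
        return self.data.index.tolist()

    @property
    def marker_names(self) -> list[str]:
        return self.data.columns.tolist()

    def column(self, marker: str) -> pd.Series:
        return self.data[marker]

    @classmethod
    def from_csv(cls, path) -> "TransmissionMatrix":
        return cls(pd.read_csv(path, index_col=0, dtype=str))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index_label="daughter_id")


def scan_grid(lmap: LinkageMap, chromosome: int, step: float = 1.0) -> np.ndarray:
    """Evaluation positions along one chromosome.

    A regular grid of spacing ``step`` from the first to the last marker,
    with every marker position inserted; strictly increasing.
    """
    mk = lmap.markers(chromosome)
    pos = mk["position_cM"].to_numpy(dtype=float)
    lo, hi = pos[0], pos[-1]
    if step <= 0:
        raise ValueError("step must be positive")
    grid = np.arange(lo, hi, step)
    grid = np.unique(np.concatenate([grid, pos, [hi]]))
    return grid


def _flank_indices(marker_pos: np.ndarray, informative: np.ndarray, q: float):
    """Indices of nearest informative markers at-or-left / at-or-right of q."""
    left = right = None
    for j in np.nonzero(informative)[0]:
        if marker_pos[j] <= q:
            left = j
        if marker_pos[j] >= q and right is None:
            right = j
    return left, right


def transmission_prob(
    alleles,
    positions,
    query: float,
    map_function: str = "haldane",
) -> float:
    """P(transmitted sire allele = A at ``query``) for one daughter.

    Conditions on the nearest informative flanking markers only.  ``alleles``
    is a sequence of 'A'/'M'/missing codes aligned with ``positions`` (cM).
    Returns 0.5 when no informative marker exists on the chromosome.
    """
    positions = np.asarray(positions, dtype=float)
    codes = np.array(
        [
            1.0 if str(a) == ALLELE_A else 0.0 if str(a) == ALLELE_M else np.nan
            for a in alleles
        ]
    )
    informative = ~np.isnan(codes)
    if positions.size and not (query >= positions[0] - 1e-9) & (
        query <= positions[-1] + 1e-9
    ):
        raise ValueError("query position outside chromosome span")
    if not informative.any():
        return 0.5
    left, right = _flank_indices(positions, informative, query)
    # P(A | left) and likelihood ratio from the right side, two-state chain
    if left is not None and abs(positions[left] - query) < 1e-12:
        return float(codes[left])
    if right is not None and abs(positions[right] - query) < 1e-12:
        return float(codes[right])

    def side(j):
        r = recombination_fraction(abs(positions[j] - query), map_function)
        # P(marker allele | state A at query), P(... | state M)
        if codes[j] == 1.0:
            return (1.0 - r, r)
        return (r, 1.0 - r)

    like_a = like_m = 1.0
    for j in (left, right):
        if j is not None:
            la, lm = side(j)
            like_a *= la
            like_m *= lm
    prior = 0.5  # sire transmits either haplotype with equal probability
    num = prior * like_a
    return float(num / (num + prior * like_m))


def transmission_prob_grid(
    geno: TransmissionMatrix,
    lmap: LinkageMap,
    chromosome: int,
    step: float = 1.0,
    map_function: str = "haldane",
):
    """P(A) for every daughter at every grid position on one chromosome.

    Returns ``(grid, P)`` where ``P`` has shape (n_daughters, n_positions).
    Daughters with no informative marker on the chromosome get 0.5 throughout.
    """
    mk = lmap.markers(chromosome)
    names = [m for m in mk["marker"] if m in geno.data.columns]
    sub = mk[mk["marker"].isin(names)]
    positions = sub["position_cM"].to_numpy(dtype=float)
    grid = scan_grid(lmap, chromosome, step=step)
    G = geno.data[sub["marker"].tolist()].to_numpy(dtype=object)
    codes = np.full(G.shape, np.nan)
    codes[G == ALLELE_A] = 1.0
    codes[G == ALLELE_M] = 0.0
    n = G.shape[0]
    P = np.empty((n, grid.size))
    for i in range(n):
        P[i] = _daughter_grid_probs(codes[i], positions, grid, map_function)
    return grid, P


def _daughter_grid_probs(codes, positions, grid, map_function):
    """Vectorised flanking-marker probabilities for one daughter."""
    inf = ~np.isnan(codes)
    if not inf.any():
        return np.full(grid.size, 0.5)
    pos_i = positions[inf]
    code_i = codes[inf]
    left = np.searchsorted(pos_i, grid, side="right") - 1
    right = np.searchsorted(pos_i, grid, side="left")
    like_a = np.ones(grid.size)
    like_m = np.ones(grid.size)
    for idx, valid in ((left, left >= 0), (right, right < pos_i.size)):
        j = np.clip(idx, 0, pos_i.size - 1)
        r = recombination_fraction(np.abs(pos_i[j] - grid), map_function)
        la = np.where(code_i[j] == 1.0, 1.0 - r, r)
        lm = np.where(code_i[j] == 1.0, r, 1.0 - r)
        like_a = np.where(valid, like_a * la, like_a)
        like_m = np.where(valid, like_m * lm, like_m)
    # when left == right the query sits on an informative marker; the two
    # factors are then identical and the double-counting cancels in the ratio
    return like_a / (like_a + like_m)
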