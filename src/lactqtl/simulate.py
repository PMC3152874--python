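"""Synthetic (Awassi x Merino) x Merino backcross studies.

Generates complete study bundles — a microsatellite framework map, sire
transmission genotypes, and Wood-shaped longitudinal phenotype records with
configurable QTL effects — with the statistical structure the mapping
pipeline assumes: a single phase-known sire, two-state meiosis under the
Haldane map function without interference, milk yield recorded every second
day, composition weekly, and per-ewe lactation lengths with sharp attrition
after day 100.

A QTL may act on a Wood parameter (the biologically natural mode; e.g. the
decline rate c shifts persistency) or directly on the derived trait (the
statistically clean mode used for calibration studies); in either mode the
shift is scaled so the realised genotype-class contrast of the derived trait
equals the configured effect in phenotypic-SD units.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq

from .linkage import LinkageMap, TransmissionMatrix, haldane
from .wood import WoodParams
from .traits import persistency, extended_lactation

__all__ = [
    "QTLSpec",
    "SimulationConfig",
    "simulate_map",
    "simulate_backcross",
    "simulate_lactations",
    "simulate_trait_values",
    "end_to_end_fixture",
]


@dataclass
class QTLSpec:
    """One simulated QTL: where it sits, what it moves and by how much."""

    chromosome: int = 11
    position_cM: float = 35.0
    target: str = "direct"  # "direct" or one of "k", "b", "c"
    trait: str = "MY"
    measure: str = "persistency"  # or "extended_lactation"
    effect_sd: float = 0.0


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic backcross.

    Defaults emulate the resource family: 172 daughters genotyped at 189
    microsatellites over 26 autosomes, milk yield every second day and
    composition weekly, lactation lengths with sharp attrition past day 100.
    """

    n_daughters: int = 172
    n_chromosomes: int = 26
    n_markers: int = 189
    chrom_length_max: float = 250.0
    chrom_length_min: float = 40.0
    marker_informativeness: float = 0.9
    missing_rate: float = 0.05
    qtl: list = field(default_factory=list)
    # Wood population distribution for the milk-yield curve (log-scale k)
    mean_k: float = 0.35
    mean_b: float = 0.35
    mean_c: float = 0.025
    sd_k: float = 0.35
    sd_b: float = 0.10
    sd_c: float = 0.005
    noise_sd_log: float = 0.15
    n_lactations: int = 2
    my_interval_days: int = 2
    composition_interval_days: int = 7
    lactation_min_days: float = 100.0
    lactation_attrition_scale: float = 90.0
    lactation_max_days: float = 300.0
    # composition baselines (percent) and their slow drift over lactation
    protein_pct: float = 5.5
    fat_pct: float = 7.0
    lactose_pct: float = 4.8
    pct_slope_per_day: float = 0.004
    pct_noise_sd: float = 0.25
    scc_log10_mean: float = 5.3
    scc_log10_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        for rate in (self.marker_informativeness, self.missing_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        self.qtl = [
            q if isinstance(q, QTLSpec) else QTLSpec(**q) for q in self.qtl
        ]

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def _rngs(seed, n):
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def _chrom_lengths(config):
    return np.linspace(
        config.chrom_length_max, config.chrom_length_min, config.n_chromosomes
    )


def simulate_map(config: SimulationConfig, rng=None) -> LinkageMap:
    """Framework map: markers allocated round-robin over the autosomes,
    positions uniform within sheep-like chromosome lengths."""
    rng = rng or np.random.default_rng(config.seed)
    counts = np.full(config.n_chromosomes, config.n_markers // config.n_chromosomes)
    counts[: config.n_markers % config.n_chromosomes] += 1
    lengths = _chrom_lengths(config)
    rows = []
    m = 0
    for chrom in range(1, config.n_chromosomes + 1):
        k = counts[chrom - 1]
        pos = np.sort(rng.uniform(0.0, lengths[chrom - 1], size=k))
        pos[0] = 0.0  # map origin at the first mapped marker
        for p in pos:
            m += 1
            rows.append(dict(chromosome=chrom, marker=f"MK{m:03d}",
                             position_cM=round(float(p), 2)))
    return LinkageMap(pd.DataFrame(rows))


def simulate_backcross(
    lmap: LinkageMap, config: SimulationConfig, rng=None
) -> tuple[TransmissionMatrix, pd.DataFrame]:
    """Simulate transmitted sire haplotypes and genotype observations.

    Returns the observed transmission matrix (with uninformative markers and
    missing calls masked) and the true transmitted states at each configured
    QTL position (1 = Awassi allele) for recovery tests.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    daughters = [f"EW{i:03d}" for i in range(1, config.n_daughters + 1)]
    geno_cols = {}
    qtl_states = {}
    for chrom in lmap.chromosomes:
        mk = lmap.markers(chrom)
        loci = [(p, ("marker", name)) for name, p in
                zip(mk["marker"], mk["position_cM"])]
        for iq, q in enumerate(config.qtl):
            if q.chromosome == chrom:
                loci.append((q.position_cM, ("qtl", iq)))
        loci.sort(key=lambda lp: lp[0])
        pos = np.array([lp[0] for lp in loci])
        switch_p = haldane(np.diff(pos)) if pos.size > 1 else np.empty(0)
        n = config.n_daughters
        states = np.empty((n, pos.size), dtype=int)
        states[:, 0] = rng.integers(0, 2, size=n)
        for j, r in enumerate(switch_p, start=1):
            flip = rng.random(n) < r
            states[:, j] = states[:, j - 1] ^ flip
        for j, (_, (kind, ident)) in enumerate(loci):
            if kind == "marker":
                geno_cols[ident] = states[:, j]
            else:
                qtl_states[f"qtl{ident}"] = states[:, j]
    # observation model: some markers uninformative, some calls missing
    cols = {}
    for name in lmap.table["marker"]:
        col = np.where(geno_cols[name] == 1, "A", "M").astype(object)
        if rng.random() > config.marker_informativeness:
            col[:] = np.nan
        else:
            col[rng.random(config.n_daughters) < config.missing_rate] = np.nan
        cols[name] = col
    alleles = pd.DataFrame(cols, index=daughters)
    truth = pd.DataFrame(qtl_states, index=daughters)
    return TransmissionMatrix(alleles), truth


def _draw_params(config, rng, size):
    k = rng.normal(config.mean_k, config.sd_k, size)
    b = np.clip(rng.normal(config.mean_b, config.sd_b, size), 0.02, None)
    c = np.clip(rng.normal(config.mean_c, config.sd_c, size), 0.004, None)
    return k, b, c


def _measure(k, b, c, measure):
    p = WoodParams(a=float(np.exp(k)), b=float(b), c=float(c), n_obs=3)
    return persistency(p) if measure == "persistency" else extended_lactation(p)


def _baseline_sd(config, measure, n=2000):
    """Population SD of a derived measure under the baseline (no-QTL) draws."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 9151]))
    k, b, c = _draw_params(config, rng, n)
    vals = np.array([_measure(k[i], b[i], c[i], measure) for i in range(n)])
    return float(np.nanstd(vals, ddof=1))


def _calibrated_shift(config, q: QTLSpec) -> float:
    """Additive shift on the derived measure giving an ``effect_sd``
    phenotypic-SD genotype contrast once the QTL variance is included."""
    sd0 = _baseline_sd(config, q.measure)
    e = q.effect_sd
    if abs(e) >= 2.0:
        raise ValueError("effect beyond 2 phenotypic SD is not representable")
    return e * sd0 / np.sqrt(1.0 - e**2 / 4.0)


def _solve_c_shift(k, b, c, measure, delta):
    """c adjustment moving the derived measure by ``delta`` for one ewe."""
    base = _measure(k, b, c, measure)
    target = base + delta
    lo, hi = 0.0041, 0.4

    def f(cc):
        return _measure(k, b, cc, measure) - target

    try:
        if f(lo) * f(hi) > 0:  # target unreachable; saturate
            return lo if abs(f(lo)) < abs(f(hi)) else hi
        return brentq(f, lo, hi, xtol=1e-10)
    except ValueError:
        return c


def simulate_trait_values(
    truth: pd.DataFrame, config: SimulationConfig, rng=None
) -> pd.DataFrame:
    """Analysis-ready per-ewe derived-trait values (direct QTL mode).

    Each ewe gets the derived measure implied by her drawn Wood parameters;
    every configured direct-mode QTL adds its calibrated shift to carriers
    of the Awassi allele.  Columns are ``<measure>:<trait>``.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    n = len(truth)
    out = pd.DataFrame(index=truth.index)
    for iq, q in enumerate(config.qtl):
        if q.target != "direct":
            continue
        k, b, c = _draw_params(config, rng, n)
        base = np.array([_measure(k[i], b[i], c[i], q.measure) for i in range(n)])
        delta = _calibrated_shift(config, q)
        states = truth[f"qtl{iq}"].to_numpy()
        out[f"{q.measure}:{q.trait}"] = base + delta * states
    if out.empty:  # no QTL configured: still emit a baseline milk column
        k, b, c = _draw_params(config, rng, n)
        out["persistency:MY"] = [
            _measure(k[i], b[i], c[i], "persistency") for i in range(n)
        ]
    return out


def simulate_lactations(
    truth: pd.DataFrame, config: SimulationConfig, rng=None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Longitudinal phenotype records for every ewe.

    Per ewe and lactation, Wood parameters are drawn from the population
    distribution, QTL effects are applied (parameter-target QTL shift the
    parameter itself; direct-target QTL move the decline rate c by a
    per-ewe amount solved so the derived measure shifts by the calibrated
    effect), and records are laid on the recording grids with multiplicative
    lognormal noise.  Returns (records, true per-lactation parameters).
    """
    rng = rng or np.random.default_rng(config.seed + 3)
    shifts = {}
    for iq, q in enumerate(config.qtl):
        shifts[iq] = _calibrated_shift(config, q) if q.target == "direct" else None
    param_deltas = {
        iq: _param_delta(config, q)
        for iq, q in enumerate(config.qtl)
        if q.target in ("k", "b", "c")
    }
    records = []
    true_rows = []
    for ewe in truth.index:
        for lact in range(1, config.n_lactations + 1):
            k, b, c = (float(v[0]) for v in _draw_params(config, rng, 1))
            for iq, q in enumerate(config.qtl):
                state = int(truth.loc[ewe, f"qtl{iq}"])
                if not state:
                    continue
                if q.target == "direct":
                    c = _solve_c_shift(k, b, c, q.measure, shifts[iq])
                elif q.target == "c":
                    c = max(c + param_deltas[iq], 0.0041)
                elif q.target == "b":
                    b = max(b + param_deltas[iq], 0.02)
                elif q.target == "k":
                    k = k + param_deltas[iq]
            a = float(np.exp(k))
            length = min(
                config.lactation_min_days
                + rng.exponential(config.lactation_attrition_scale),
                config.lactation_max_days,
            )
            my_days = np.arange(config.my_interval_days, length + 1e-9,
                                config.my_interval_days)
            w = a * my_days**b * np.exp(-c * my_days)
            my = w * np.exp(rng.normal(0.0, config.noise_sd_log, my_days.size))
            for d, v in zip(my_days, my):
                records.append((ewe, lact, int(d), "MY", float(v)))
            comp_days = np.arange(config.composition_interval_days, length + 1e-9,
                                  config.composition_interval_days)
            for d in comp_days:
                drift = config.pct_slope_per_day * d
                for trait, base in (
                    ("protein%", config.protein_pct),
                    ("fat%", config.fat_pct),
                    ("lactose%", config.lactose_pct),
                ):
                    v = base + drift + rng.normal(0.0, config.pct_noise_sd)
                    records.append((ewe, lact, int(d), trait,
                                    float(np.clip(v, 0.1, 100.0))))
                scc = 10.0 ** rng.normal(config.scc_log10_mean,
                                         config.scc_log10_sd)
                records.append((ewe, lact, int(d), "SCC", float(scc)))
            true_rows.append(dict(ewe_id=ewe, lactation_id=lact, a=a, k=k, b=b,
                                  c=c, length=float(length)))
    rec = pd.DataFrame(records,
                       columns=["ewe_id", "lactation_id", "day", "trait", "value"])
    return rec, pd.DataFrame(true_rows)


def _param_delta(config: SimulationConfig, q: QTLSpec) -> float:
    """Shift on a Wood parameter whose effect on the derived measure at the
    population-mean curve equals the calibrated trait shift."""
    delta_measure = _calibrated_shift(config, q)
    k0, b0, c0 = config.mean_k, config.mean_b, config.mean_c

    def measure_at(dp):
        kk, bb, cc = k0, b0, c0
        if q.target == "k":
            kk += dp
        elif q.target == "b":
            bb = max(bb + dp, 0.02)
        else:
            cc = max(cc + dp, 0.0041)
        return _measure(kk, bb, cc, q.measure)

    base = measure_at(0.0)

    def f(dp):
        return measure_at(dp) - base - delta_measure

    span = {"k": 3.0, "b": 1.0, "c": 0.05}[q.target]
    lo, hi = -span, span
    try:
        if f(lo) * f(hi) > 0:
            return 0.0
        return float(brentq(f, lo, hi, xtol=1e-10))
    except ValueError:
        return 0.0


def end_to_end_fixture(config: SimulationConfig, outdir) -> dict:
    """Write a complete, reproducible study bundle.

    Emits map.csv, genotypes.csv, phenotypes.csv, traits_direct.csv, a
    truth.json (QTL specs, per-ewe states and per-lactation parameters) and
    the config as YAML.  Returns the in-memory objects.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_map, rng_bc, rng_tv, rng_lact = _rngs(config.seed, 4)
    lmap = simulate_map(config, rng_map)
    geno, truth = simulate_backcross(lmap, config, rng_bc)
    values = simulate_trait_values(truth, config, rng_tv)
    records, true_params = simulate_lactations(truth, config, rng_lact)
    lmap.to_csv(outdir / "map.csv")
    geno.to_csv(outdir / "genotypes.csv")
    records.to_csv(outdir / "phenotypes.csv", index=False)
    values.to_csv(outdir / "traits_direct.csv", index_label="ewe_id")
    truth_doc = {
        "seed": config.seed,
        "qtl": [dataclasses.asdict(q) for q in config.qtl],
        "qtl_states": {c: truth[c].astype(int).tolist() for c in truth.columns},
        "daughters": truth.index.tolist(),
        "per_lactation_params": true_params.to_dict(orient="records"),
    }
    (outdir / "truth.json").write_text(json.dumps(truth_doc, indent=1))
    config.to_yaml(outdir / "config.yaml")
    return dict(map=lmap, genotypes=geno, truth=truth, trait_values=values,
                records=records, true_params=true_params)
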