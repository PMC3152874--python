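"""Pipeline orchestration: simulate -> fit -> derive -> scan -> report.

Stages communicate through plain CSV/JSON files in the output directory and
every run writes a manifest (config hash, per-stage seeds, input checksums,
status and timings) so deterministic stages are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as lio
from .linkage import LinkageMap, TransmissionMatrix, transmission_prob_grid
from .mle_scan import MixtureScanModel, classify_lod
from .regression_scan import HalfSibScanModel
from .simulate import SimulationConfig, end_to_end_fixture
from .traits import (
    YIELD_TRAITS,
    component_yields,
    derive_trait_table,
    summarize_traits,
    trait_correlations,
)
from .wood import UnfittableCurveError, fit_wood_loglinear, fit_wood_nls

__all__ = ["AnalysisConfig", "run_pipeline", "validate_inputs", "derive_study_traits"]


@dataclasses.dataclass
class AnalysisConfig:
    """Knobs of the mapping stages (scan step, resampling sizes, reporting)."""

    step: float = 2.0
    measures: tuple = ("persistency", "extended_lactation")
    traits: tuple = ("MY",)
    n_permutations: int = 1000
    n_bootstrap: int = 1000
    two_qtl: str = "detected"  # "detected" | "all" | "none"
    make_plots: bool = True
    seed: int = 0


def validate_inputs(
    lmap: LinkageMap, geno: TransmissionMatrix, phenotypes: pd.DataFrame
) -> dict:
    """Cross-check marker names, daughter ids, alleles and day ranges."""
    errors, warnings_ = [], []
    map_markers = set(lmap.table["marker"])
    extra = [m for m in geno.marker_names if m not in map_markers]
    if extra:
        errors.append(f"genotype markers absent from map: {extra}")
    unmapped = [m for m in map_markers if m not in geno.marker_names]
    if unmapped:
        warnings_.append(f"map markers without genotypes: {sorted(unmapped)}")
    pheno_ewes = set(phenotypes["ewe_id"].astype(str))
    geno_ewes = set(map(str, geno.daughters))
    orphans = sorted(pheno_ewes - geno_ewes)
    if orphans:
        warnings_.append(
            f"{len(orphans)} phenotyped ewes lack genotypes (excluded from "
            f"scans, kept in descriptive tables): {orphans[:10]}"
        )
    if (phenotypes["day"] < 1).any():
        errors.append("phenotype day < 1")
    return {"errors": errors, "warnings": warnings_}


def _interp_my(my_sub: pd.DataFrame, days: np.ndarray) -> np.ndarray:
    d = my_sub["day"].to_numpy(dtype=float)
    v = my_sub["value"].to_numpy(dtype=float)
    order = np.argsort(d)
    return np.interp(days, d[order], v[order])


def derive_study_traits(phenotypes: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fit Wood curves per ewe x lactation x yield trait and derive
    persistency / extended lactation.

    Component-yield records are built by combining weekly composition with
    milk yield interpolated to the composition days; per-ewe values average
    over lactations.  Returns (per-ewe trait table, per-curve fit table).
    """
    fit_rows = []
    derived: dict = {}
    for (ewe, lact), sub in phenotypes.groupby(["ewe_id", "lactation_id"]):
        my = sub[sub["trait"] == "MY"]
        if my.empty:
            continue
        series: dict[str, pd.DataFrame] = {"MY": my[["day", "value"]]}
        comp = sub[sub["trait"] != "MY"]
        if not comp.empty:
            wide = comp.pivot_table(index="day", columns="trait", values="value")
            days = wide.index.to_numpy(dtype=float)
            my_at = _interp_my(my, days)
            cy = component_yields(
                my_at,
                protein_pct=wide.get("protein%"),
                fat_pct=wide.get("fat%"),
                lactose_pct=wide.get("lactose%"),
                SCC=wide.get("SCC"),
            )
            for tr in ("PY", "FY", "LY", "UY", "SCY"):
                vals = np.asarray(cy[tr], dtype=float)
                ok = np.isfinite(vals)
                if ok.sum() >= 3:
                    series[tr] = pd.DataFrame(
                        {"day": days[ok].astype(int), "value": vals[ok]}
                    )
        for trait, recs in series.items():
            try:
                pars = fit_wood_nls(recs, fit_wood_loglinear(recs))
            except UnfittableCurveError:
                continue
            fit_rows.append(
                dict(ewe_id=ewe, lactation_id=lact, trait=trait, a=pars.a,
                     k=pars.k, b=pars.b, c=pars.c, n_obs=pars.n_obs,
                     rss=pars.rss, flags=";".join(pars.flags))
            )
            derived.setdefault((ewe, trait), []).append(pars)
    fits = pd.DataFrame(fit_rows)
    table_fits = {}
    for (ewe, trait), parlist in derived.items():
        # one representative curve per ewe: the first declining lactation,
        # else the first fit (flagged)
        chosen = next((p for p in parlist if not p.non_declining), parlist[0])
        table_fits[(ewe, trait)] = chosen
    trait_table = derive_trait_table(table_fits)
    return trait_table, fits


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    sim_config: SimulationConfig | None = None,
    analysis: AnalysisConfig | None = None,
    inputs: dict | None = None,
    outdir="lactqtl_run",
) -> dict:
    """Run the full study: simulate (or load), fit, derive, scan, report.

    ``inputs`` may supply paths {"map", "genotypes", "phenotypes"} instead of
    a simulation config.  Returns a dict of the main result objects; all
    publication-shaped tables, per-chromosome profiles and the manifest are
    written under ``outdir``.
    """
    analysis = analysis or AnalysisConfig()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seeds": {"analysis": analysis.seed}}
    t_all = time.time()

    def stage(name):
        manifest["stages"][name] = {"status": "running", "seconds": None}
        return time.time()

    def done(name, t0):
        manifest["stages"][name] = {
            "status": "ok",
            "seconds": round(time.time() - t0, 3),
        }

    try:
        # --- inputs -------------------------------------------------------
        t0 = stage("inputs")
        if inputs is not None:
            lmap = lio.read_map(inputs["map"])
            geno = lio.read_genotypes(inputs["genotypes"])
            phenotypes = lio.read_phenotypes(inputs["phenotypes"])
            manifest["input_checksums"] = {
                k: _sha256(Path(v)) for k, v in inputs.items()
            }
        else:
            sim_config = sim_config or SimulationConfig()
            bundle = end_to_end_fixture(sim_config, outdir / "simulated")
            lmap, geno = bundle["map"], bundle["genotypes"]
            phenotypes = bundle["records"]
            manifest["seeds"]["simulation"] = sim_config.seed
            manifest["config_hash"] = hashlib.sha256(
                yaml.safe_dump(dataclasses.asdict(sim_config),
                               sort_keys=True).encode()
            ).hexdigest()
        report = validate_inputs(lmap, geno, phenotypes)
        if report["errors"]:
            raise ValueError("input validation failed: " + "; ".join(report["errors"]))
        manifest["validation_warnings"] = report["warnings"]
        done("inputs", t0)

        # --- curves and derived traits -----------------------------------
        t0 = stage("fit_curves")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            trait_table, fits = derive_study_traits(phenotypes)
        lio.write_table(fits, outdir / "wood_fits.csv")
        lio.write_table(trait_table, outdir / "derived_traits.csv")
        summary = summarize_traits(trait_table)
        lio.write_table(summary, outdir / "trait_summary.csv")
        corr = trait_correlations(trait_table)
        lio.write_table(corr, outdir / "trait_correlations.csv", index=True)
        done("fit_curves", t0)

        # --- scans --------------------------------------------------------
        t0 = stage("scans")
        geno_ewes = [str(d) for d in geno.daughters]
        mle_rows, reg_rows, two_rows = [], [], []
        scan_profiles = []
        rng = np.random.default_rng(analysis.seed)
        for measure in analysis.measures:
            for trait in analysis.traits:
                col = trait_table[trait_table["trait"] == trait].set_index("ewe_id")
                vals = col[measure].reindex(geno_ewes)
                keep = vals.notna().to_numpy()
                if keep.sum() < 30:
                    continue
                y = vals.to_numpy(dtype=float)[keep]
                sub_geno = TransmissionMatrix(geno.data.iloc[keep])
                label = f"{measure}:{trait}"
                for chrom in lmap.chromosomes:
                    grid, P = transmission_prob_grid(
                        sub_geno, lmap, chrom, step=analysis.step
                    )
                    mle = MixtureScanModel(y, grid, P, chromosome=chrom,
                                           lmap=lmap, log_transform=True).fit()
                    reg_model = HalfSibScanModel(y, grid, P, chromosome=chrom,
                                                 lmap=lmap, log_transform=True)
                    reg = reg_model.fit()
                    prof = mle.profile[["position_cM", "LOD"]].copy()
                    prof.insert(0, "chromosome", chrom)
                    prof.insert(0, "trait", label)
                    prof["F"] = reg.profile["F"].to_numpy()
                    scan_profiles.append(prof)
                    if mle.significance_class != "none":
                        mle_rows.append(
                            dict(trait=label, chromosome=chrom,
                                 position_cM=mle.peak_position,
                                 ci_lo=mle.support_interval[0],
                                 ci_hi=mle.support_interval[1],
                                 markers="-".join(mle.flanking_markers),
                                 LOD=round(mle.peak_value, 2),
                                 Est=round(mle.effect_estimate, 3),
                                 SD=round(mle.effect_sd_units, 2),
                                 significance=mle.significance_class)
                        )
                    thr = reg_model.permutation_thresholds(
                        n=analysis.n_permutations,
                        seed=int(rng.integers(2**31 - 1)),
                    )
                    stars = thr.classify(reg.peak_value)
                    if stars:
                        boot = reg_model.bootstrap_ci(
                            n=analysis.n_bootstrap,
                            seed=int(rng.integers(2**31 - 1)),
                        )
                        reg_rows.append(
                            dict(trait=label, chromosome=chrom,
                                 peak_cM=reg.peak_position,
                                 ci_lo=boot["ci"][0], ci_hi=boot["ci"][1],
                                 F=round(reg.peak_value, 2), stars=stars,
                                 effect_SD=round(reg.effect_sd_units, 2),
                                 SE=round(reg.effect_se_sd_units, 2),
                                 var_explained=round(
                                     reg.metadata["heritability"], 4),
                                 markers="-".join(reg.flanking_markers))
                        )
                        if analysis.two_qtl == "detected" and len(grid) >= 3:
                            try:
                                two = reg_model.fit_two_qtl()
                                two_rows.append(_two_row(label, two))
                            except ValueError:
                                pass
                    if analysis.two_qtl == "all" and len(grid) >= 3:
                        try:
                            two = reg_model.fit_two_qtl()
                            two_rows.append(_two_row(label, two))
                        except ValueError:
                            pass
        profiles = (
            pd.concat(scan_profiles, ignore_index=True)
            if scan_profiles
            else pd.DataFrame()
        )
        lio.write_table(profiles, outdir / "scan_profiles.csv")
        mle_peaks = pd.DataFrame(mle_rows)
        reg_peaks = pd.DataFrame(reg_rows)
        two_qtl = pd.DataFrame(two_rows)
        lio.write_table(mle_peaks, outdir / "mle_peaks.csv")
        lio.write_table(reg_peaks, outdir / "regression_peaks.csv")
        lio.write_table(two_qtl, outdir / "two_qtl.csv")
        done("scans", t0)

        # --- plots --------------------------------------------------------
        if analysis.make_plots and not profiles.empty:
            t0 = stage("plots")
            _plot_profiles(profiles, outdir / "plots")
            done("plots", t0)
    except Exception as exc:
        for name, st in manifest["stages"].items():
            if st["status"] == "running":
                st["status"] = f"failed: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise

    manifest["total_seconds"] = round(time.time() - t_all, 3)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return dict(
        trait_table=trait_table,
        fits=fits,
        summary=summary,
        correlations=corr,
        mle_peaks=mle_peaks,
        regression_peaks=reg_peaks,
        two_qtl=two_qtl,
        profiles=profiles,
        manifest=manifest,
    )


def _two_row(label, two):
    return dict(
        trait=label, chromosome=two.chromosome, qtl_a_cM=two.position_a,
        qtl_b_cM=two.position_b, F_2v0=round(two.f_2v0, 2),
        F_2v1=round(two.f_2v1, 2), effect_a_SD=round(two.effect_a_sd, 2),
        effect_b_SD=round(two.effect_b_sd, 2), se_a=round(two.se_a_sd, 2),
        se_b=round(two.se_b_sd, 2), phase=two.phase,
    )


def _plot_profiles(profiles: pd.DataFrame, plotdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    plotdir.mkdir(parents=True, exist_ok=True)
    for label, sub in profiles.groupby("trait"):
        fig, ax = plt.subplots(figsize=(10, 3))
        offset = 0.0
        ticks, labels = [], []
        for chrom, cs in sub.groupby("chromosome"):
            ax.plot(cs["position_cM"] + offset, cs["LOD"], lw=0.8)
            ticks.append(offset + cs["position_cM"].max() / 2)
            labels.append(str(chrom))
            offset += cs["position_cM"].max() + 10
        ax.axhline(1.75, ls="--", color="grey", lw=0.8)
        ax.set_xticks(ticks, labels, fontsize=6)
        ax.set_ylabel("LOD")
        ax.set_title(label)
        fig.tight_layout()
        fig.savefig(plotdir / f"scan_{label.replace(':', '_').replace('%', '')}.png",
                    dpi=120)
        plt.close(fig)
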