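"""Configuration-driven end-to-end run.

Chains the stages in analysis order — cohort input (simulated or loaded),
PRS scoring and standardization, baseline-hazard calibration, per-person
5-year absolute risks (PRS and Gail), four-way high-risk classification,
and the concordance report (summary table, risk comparison, Venn regions
for the full cohort and the under-50 subset, kappa matrix, incremental
age-group table).  Every artifact is reproducible bit-for-bit under a
fixed seed.
"""

from __future__ import annotations

import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .absolute_risk import (RiskFactorProfile, calibrate_baseline_hazard,
                            gail_absolute_risk, prs_five_year_risk)
from .classification import CRITERIA, DEFAULT_THRESHOLD, classify_high_risk, classify_ptv
from .concordance import (cohens_kappa, incremental_by_age, paired_signed_rank,
                          rank_correlation, venn_counts)
from .prs import ReferenceStats, compute_raw_prs, compute_reference_stats, standardize_prs
from .synthetic_cohort import (DEFAULT_PRS_BETA, SimulationConfig,
                               sample_cases_by_risk, simulate_cohort,
                               simulate_variant_records)

logger = logging.getLogger("riskstrat")

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Resolved pipeline settings (see ``from_yaml`` for the file layout)."""

    outdir: str | Path = "riskstrat_out"
    seed: int = 0
    # exactly one of (cohort_path [+ genotypes_path]) or simulation
    cohort_path: str | None = None
    genotypes_path: str | None = None
    variants_path: str | None = None
    simulation: dict | None = None
    weights_path: str | None = None          # default: bundled synthetic panel
    rates_path: str | None = None            # default: bundled Singapore-style rates
    rates_population: str = "overall"
    gail_params_path: str | None = None      # default: bundled AABCS file
    beta: float = DEFAULT_PRS_BETA
    threshold: float = DEFAULT_THRESHOLD
    quadrature_size: int = 64
    reference: dict | None = None            # {"mean": .., "sd": ..} override
    under_age_cut: float = 50.0
    plots: bool = False

    def __post_init__(self) -> None:
        has_files = self.cohort_path is not None
        has_sim = self.simulation is not None
        if has_files == has_sim:
            raise ValueError(
                "config must provide exactly one of an input cohort path or "
                "a simulation block")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**rio.load_yaml(path))

    def resolved(self) -> dict:
        def plain(v):
            if isinstance(v, Path):
                return str(v)
            if isinstance(v, np.generic):
                return v.item()
            if isinstance(v, np.ndarray):
                return v.tolist()
            if isinstance(v, dict):
                return {k: plain(x) for k, x in v.items()}
            return v

        d = {k: plain(v) for k, v in self.__dict__.items()}
        d["weights_path"] = self.weights_path or str(rio.bundled_path("prs_panel_synthetic.tsv"))
        d["rates_path"] = self.rates_path or str(rio.bundled_path("singapore_rates_synthetic.csv"))
        d["gail_params_path"] = self.gail_params_path or str(rio.bundled_path("gail_params_aabcs.txt"))
        return d


def _profile_from_row(row) -> RiskFactorProfile:
    return RiskFactorProfile(
        menarche=row["menarche"], first_birth=row["first_birth"],
        biopsy=row.get("biopsy", "unknown"),
        n_relatives_breast=int(bool(row["fh_breast"])),
        fh_ovarian=bool(row["fh_ovarian"]))


def _quantiles(x: np.ndarray) -> tuple[float, float, float]:
    return tuple(np.percentile(x, [50, 25, 75])) if x.size else (np.nan,) * 3


def _summarize_cohort(cohort: pd.DataFrame, cls: pd.DataFrame) -> pd.DataFrame:
    """Cohort-description table: counts and percents per category."""
    rows = []
    n = len(cohort)
    if "age" in cohort.columns:
        med, q1, q3 = _quantiles(cohort["age"].to_numpy(float))
        rows.append(("age", "median (IQR)", f"{med:.0f} ({q1:.0f}-{q3:.0f})", np.nan))
    for col in ("ethnicity", "case_type", "menarche", "first_birth", "biopsy",
                "fh_breast", "fh_ovarian", "ptv_carrier"):
        if col not in cohort.columns:
            continue
        counts = cohort[col].value_counts(dropna=False)
        for cat, c in counts.items():
            pct = 100.0 * c / n if n else np.nan
            rows.append((col, str(cat), str(int(c)), pct))
    for col, label in (("prs_risk_5y", "PRS 5-year risk %"),
                       ("gail_risk_5y", "Gail 5-year risk %")):
        if len(cls):
            med, q1, q3 = _quantiles(100 * cls[col].to_numpy(float))
            rows.append((label, "median (IQR)",
                         f"{med:.1f} ({q1:.1f}-{q3:.1f})", np.nan))
    return pd.DataFrame(rows, columns=["variable", "category", "value", "percent"])


def _risk_comparison(cls: pd.DataFrame, z: np.ndarray) -> pd.DataFrame:
    rows = []
    prs = cls["prs_risk_5y"].to_numpy(float)
    gail = cls["gail_risk_5y"].to_numpy(float)
    if len(cls) >= 3:
        corr = rank_correlation(prs, gail)
        rows.append(("spearman_rho", corr.rho, corr.status))
        sr = paired_signed_rank(prs, gail)
        rows.append(("wilcoxon_statistic", sr.statistic, sr.status))
        rows.append(("wilcoxon_p", sr.p_value, sr.status))
    else:
        rows.append(("spearman_rho", None, "degenerate"))
        rows.append(("wilcoxon_p", None, "degenerate"))
    for name, x in (("prs_risk_pct", 100 * prs), ("gail_risk_pct", 100 * gail),
                    ("risk_diff_pct", 100 * (prs - gail))):
        med, q1, q3 = _quantiles(x)
        rows.append((f"{name}_median", med, "ok"))
        rows.append((f"{name}_q1", q1, "ok"))
        rows.append((f"{name}_q3", q3, "ok"))
    rows.append(("case_mean_z", float(np.mean(z)) if z.size else None, "ok"))
    rows.append(("case_sd_z", float(np.std(z, ddof=1)) if z.size > 1 else None, "ok"))
    return pd.DataFrame(rows, columns=["quantity", "value", "status"])


def _kappa_matrix(cls: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for i, a in enumerate(CRITERIA):
        for b in CRITERIA[i + 1:]:
            if len(cls) >= 2:
                res = cohens_kappa(cls[a].to_numpy(bool), cls[b].to_numpy(bool))
                rows.append((a, b, res.kappa, res.p_value, res.status))
            else:
                rows.append((a, b, None, None, "degenerate"))
    return pd.DataFrame(rows, columns=["criterion_a", "criterion_b", "kappa",
                                       "p_value", "status"])


def _venn_frame(cls: pd.DataFrame) -> pd.DataFrame:
    summary = venn_counts({c: cls[c].to_numpy(bool) for c in CRITERIA})
    df = summary.to_frame()
    df.attrs["names"] = summary.names
    df["union"] = summary.union
    df["n"] = summary.n
    return df


def _age_tables(cls: pd.DataFrame, cohort: pd.DataFrame) -> pd.DataFrame:
    flags = {c: cls[c].to_numpy(bool) for c in CRITERIA}
    ages = cohort["age"].to_numpy(float)
    overall = incremental_by_age(flags, ages, CRITERIA)
    overall.insert(0, "stratum", "all")
    out = [overall]
    if "case_type" in cohort.columns and len(cohort):
        for ct, idx in cohort.groupby("case_type").groups.items():
            loc = cohort.index.get_indexer(idx)
            sub = incremental_by_age({k: v[loc] for k, v in flags.items()},
                                     ages[loc], CRITERIA)
            sub.insert(0, "stratum", str(ct))
            out.append(sub)
    return pd.concat(out, ignore_index=True)


def _plot_age_table(age_table: pd.DataFrame, path: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = age_table[age_table["stratum"] == "all"]
    cols = [c for c in sub.columns if c.startswith("+")]
    fig, ax = plt.subplots(figsize=(8, 4.5))
    x = np.arange(len(sub))
    prev = np.zeros(len(sub))
    for c in cols:
        vals = sub[c].to_numpy(float)
        ax.bar(x, vals - prev, bottom=prev, label=c)
        prev = np.nan_to_num(vals)
    ax.set_xticks(x, sub["age_group"])
    ax.set_ylabel("proportion identified high risk")
    ax.set_xlabel("age group at diagnosis")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full analysis; returns a dict of output paths.

    On any stage failure the (partial) output directory is removed and a
    :class:`StageError` naming the stage is raised.
    """
    outdir = Path(config.outdir)
    created = not outdir.exists()
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    stage = "setup"
    try:
        resolved = config.resolved()
        rio.dump_yaml(resolved, outdir / "config_resolved.yaml")
        logger.info("resolved config: %s", resolved)
        rng = np.random.default_rng(config.seed)
        stage_seeds = rng.integers(2 ** 31, size=4)

        stage = "input"
        weights = rio.load_weights(resolved["weights_path"])
        if config.simulation is not None:
            sim = dict(config.simulation)
            n_pop = int(sim.pop("n_population"))
            n_cases = int(sim.pop("n_cases", n_pop))
            if "allele_freqs" not in sim:
                _, freqs = rio.load_bundled_panel()
                sim["allele_freqs"] = freqs
            sim.setdefault("prs_log_or_per_sd", config.beta)
            sim_cfg = SimulationConfig(n_individuals=n_pop, seed=int(stage_seeds[0]),
                                       **sim)
            population, genotypes = simulate_cohort(sim_cfg)
            if genotypes.n_variants == len(weights):
                # label simulated columns with the scoring panel's variants
                genotypes = type(genotypes)(
                    sample_ids=genotypes.sample_ids, variant_ids=weights.ids,
                    counted_allele=weights.effect_allele,
                    other_allele=weights.other_allele, dosages=genotypes.dosages)
            raw = compute_raw_prs(genotypes, weights)
            ref = (compute_reference_stats(raw, population="simulated_controls")
                   if n_pop >= 2 else ReferenceStats(0.0, 1.0, "degenerate"))
            z_pop = standardize_prs(raw, ref)
            case_mask = sample_cases_by_risk(z_pop, config.beta, n_cases,
                                             seed=int(stage_seeds[1]))
            cohort = population.loc[case_mask].reset_index(drop=True)
            z = z_pop[case_mask]
            variants = simulate_variant_records(cohort, seed=int(stage_seeds[2]))
            logger.info("simulated population %d, sampled %d cases", n_pop, n_cases)
        else:
            cohort = rio.load_cohort(config.cohort_path)
            if config.genotypes_path is not None:
                gpath = str(config.genotypes_path)
                genotypes = (rio.load_vcf(gpath) if gpath.endswith(".vcf")
                             else rio.load_dosage_matrix(gpath))
                raw = compute_raw_prs(genotypes, weights)
            elif "raw_prs" in cohort.columns:
                raw = cohort["raw_prs"].to_numpy(float)
            else:
                raise ValueError("need genotypes_path or a raw_prs cohort column")
            if config.reference is not None:
                ref = ReferenceStats(float(config.reference["mean"]),
                                     float(config.reference["sd"]),
                                     str(config.reference.get("population", "supplied")))
            else:
                logger.warning("no control reference supplied; standardizing "
                               "against the loaded cohort itself")
                ref = compute_reference_stats(raw, population="self")
            z = standardize_prs(raw, ref)
            variants = (pd.read_csv(config.variants_path, sep="\t")
                        if config.variants_path else None)

        if variants is not None and len(cohort):
            cohort = cohort.copy()
            cohort["ptv_carrier"] = classify_ptv(variants, cohort["individual_id"])
        elif variants is not None:
            cohort = cohort.copy()
            cohort["ptv_carrier"] = np.zeros(0, dtype=bool)

        stage = "calibrate"
        rates = rio.load_rates(resolved["rates_path"],
                               population=config.rates_population)
        calib = calibrate_baseline_hazard(rates, config.beta,
                                          quadrature_size=config.quadrature_size)

        stage = "risk"
        gail_params = rio.load_gail_params(resolved["gail_params_path"])
        ages = cohort["age"].to_numpy(float) if len(cohort) else np.zeros(0)
        prs_risk = np.array([prs_five_year_risk(zi, a, calib)
                             for zi, a in zip(z, ages)])
        gail_risk = np.array([
            gail_absolute_risk(_profile_from_row(row), a, rates, gail_params)
            for (_, row), a in zip(cohort.iterrows(), ages)])

        stage = "classify"
        cls = classify_high_risk(cohort, prs_risk, gail_risk,
                                 threshold=config.threshold)

        stage = "report"
        paths: dict = {}

        def emit(name: str, df: pd.DataFrame) -> None:
            p = outdir / name
            df.to_csv(p, sep="\t", index=False, na_rep="NA")
            paths[name] = p

        scores = pd.DataFrame({"individual_id": cohort.get("individual_id", []),
                               "raw": raw[case_mask] if config.simulation is not None else raw,
                               "z": z,
                               "population": ref.population})
        emit("scores.tsv", scores)
        emit("classification.tsv", cls)
        emit("cohort_summary.tsv", _summarize_cohort(cohort, cls))
        emit("risk_comparison.tsv", _risk_comparison(cls, z))
        emit("kappa_matrix.tsv", _kappa_matrix(cls))
        emit("venn_all.tsv", _venn_frame(cls))
        young = ages < config.under_age_cut
        emit("venn_under50.tsv", _venn_frame(cls.loc[young]))
        emit("age_table.tsv", _age_tables(cls, cohort))
        rio.write_cohort(cohort, outdir / "cohort.tsv")
        paths["cohort.tsv"] = outdir / "cohort.tsv"
        if config.plots:
            _plot_age_table(pd.read_csv(paths["age_table.tsv"], sep="\t"),
                            outdir / "age_proportions.png")
            paths["age_proportions.png"] = outdir / "age_proportions.png"
        paths["run_log.txt"] = log_path
        paths["config_resolved.yaml"] = outdir / "config_resolved.yaml"
        logger.info("pipeline complete: %d individuals, %d high risk",
                    len(cls), int(cls["any_high"].sum()) if len(cls) else 0)
        return paths
    except Exception as exc:
        logger.removeHandler(handler)
        handler.close()
        handler = None
        if created:
            shutil.rmtree(outdir, ignore_errors=True)
        else:
            for p in outdir.iterdir():
                if p.is_dir():
                    shutil.rmtree(p, ignore_errors=True)
                else:
                    p.unlink(missing_ok=True)
        raise StageError(stage, exc) from exc
    finally:
        if handler is not None:
            logger.removeHandler(handler)
            handler.close()
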