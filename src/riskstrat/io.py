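"""Readers and writers for the pipeline's tabular formats.

Formats (all plain text):

* rates — CSV with header ``age_low,age_high,incidence_per_100k_py,
  mortality_per_100k_py,population``; hazards are converted to events per
  person-year internally.
* PRS weights — TSV with header ``id effect_allele other_allele weight``
  (an optional ``freq`` column carries the synthetic panel's allele
  frequencies).
* Gail parameters — key/value text, ``coef.<factor>.<segment>`` and
  ``ar.<segment>`` entries.
* cohort — TSV, one row per individual.
* genotypes — variant x individual dosage matrix TSV, or VCF with a DS
  FORMAT field (written/read through pysam).
"""

from __future__ import annotations

import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import pysam
import yaml

from .absolute_risk import GailParams, RatesTable
from .prs import GenotypeMatrix, PRSWeights

logger = logging.getLogger("riskstrat")

__all__ = [
    "load_rates", "write_rates", "load_weights", "write_weights",
    "load_gail_params", "write_gail_params", "load_cohort", "write_cohort",
    "load_dosage_matrix", "write_dosage_matrix", "load_vcf", "write_vcf",
    "bundled_path", "load_bundled_rates", "load_bundled_gail_params",
    "load_bundled_panel",
]

_PER_100K = 1e-5

_COHORT_BOOL_COLUMNS = ("fh_breast", "fh_ovarian", "ptv_carrier")


def bundled_path(name: str) -> Path:
    """Path of a data file shipped with the package."""
    return Path(resources.files("riskstrat.data") / name)


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

def load_rates(path, population: str | None = None) -> RatesTable:
    """Load an age-interval rates CSV (rates given per 100,000 person-years).

    If the file holds several populations, ``population`` selects one;
    with a single population the argument may be omitted.
    """
    df = pd.read_csv(path, comment="#")
    required = {"age_low", "age_high", "incidence_per_100k_py",
                "mortality_per_100k_py"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if "population" not in df.columns:
        df["population"] = "overall"
    pops = df["population"].unique()
    if population is None:
        if len(pops) > 1:
            raise ValueError(f"{path}: multiple populations {list(pops)}; pick one")
        population = pops[0]
    sub = df[df["population"] == population]
    if sub.empty:
        raise ValueError(f"{path}: no rows for population {population!r}")
    sub = sub.sort_values("age_low")
    try:
        return RatesTable(
            age_low=sub["age_low"].to_numpy(float),
            age_high=sub["age_high"].to_numpy(float),
            incidence=sub["incidence_per_100k_py"].to_numpy(float) * _PER_100K,
            mortality=sub["mortality_per_100k_py"].to_numpy(float) * _PER_100K,
            population=str(population))
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_rates(rates: RatesTable, path) -> None:
    pd.DataFrame({
        "age_low": rates.age_low.astype(int),
        "age_high": rates.age_high.astype(int),
        "incidence_per_100k_py": rates.incidence / _PER_100K,
        "mortality_per_100k_py": rates.mortality / _PER_100K,
        "population": rates.population,
    }).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PRS weights
# ---------------------------------------------------------------------------

def load_weights(path) -> PRSWeights:
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "effect_allele", "other_allele", "weight"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dup = df["id"][df["id"].duplicated()]
    if not dup.empty:
        lines = (dup.index + 2).tolist()  # header is line 1
        raise ValueError(f"{path}: duplicated variant ids {dup.tolist()[:5]} "
                         f"at lines {lines[:5]}")
    try:
        return PRSWeights.from_frame(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_weights(weights: PRSWeights, path) -> None:
    weights.to_frame().to_csv(path, sep="\t", index=False)


def load_panel_freqs(path) -> np.ndarray:
    """Allele-frequency column of a panel TSV (for simulation)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "freq" not in df.columns:
        raise ValueError(f"{path}: no 'freq' column")
    return df["freq"].to_numpy(float)


# ---------------------------------------------------------------------------
# Gail parameters
# ---------------------------------------------------------------------------

def load_gail_params(path) -> GailParams:
    """Parse a key/value Gail parameter file.

    Recognised keys: ``population``, ``coef.<factor>.<lt50|ge50>`` and
    ``ar.<lt50|ge50>``; ``#`` starts a comment.
    """
    coef: dict = {"lt50": {}, "ge50": {}}
    ar: dict = {}
    population = ""
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        try:
            key, value = line.split(maxsplit=1)
        except ValueError:
            raise ValueError(f"{path}:{lineno}: expected 'key value'") from None
        if key == "population":
            population = value
        elif key.startswith("coef."):
            _, factor, seg = key.split(".")
            coef[seg][factor] = float(value)
        elif key.startswith("ar."):
            _, seg = key.split(".")
            ar[seg] = float(value)
        elif key == "format_version":
            continue
        else:
            raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
    try:
        return GailParams(coef=coef, ar=ar, population=population)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_gail_params(params: GailParams, path) -> None:
    lines = ["format_version 1"]
    if params.population:
        lines.append(f"population {params.population}")
    for seg in ("lt50", "ge50"):
        for factor, value in params.coef[seg].items():
            lines.append(f"coef.{factor}.{seg} {value!r}")
        lines.append(f"ar.{seg} {params.ar[seg]!r}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def load_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "individual_id" not in df.columns:
        raise ValueError(f"{path}: missing individual_id column")
    for col in _COHORT_BOOL_COLUMNS:
        if col in df.columns:
            df[col] = df[col].astype(bool)
    return df


def write_cohort(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def write_dosage_matrix(gm: GenotypeMatrix, path) -> None:
    """Variant x individual dosage TSV (id, alleles, then one column per sample)."""
    df = pd.DataFrame(gm.dosages.T, columns=list(gm.sample_ids))
    df.insert(0, "other_allele", gm.other_allele)
    df.insert(0, "counted_allele", gm.counted_allele)
    df.insert(0, "id", gm.variant_ids)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def load_dosage_matrix(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    meta = ["id", "counted_allele", "other_allele"]
    missing = set(meta) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    samples = [c for c in df.columns if c not in meta]
    return GenotypeMatrix(
        sample_ids=samples,
        variant_ids=df["id"].tolist(),
        counted_allele=df["counted_allele"].tolist(),
        other_allele=df["other_allele"].tolist(),
        dosages=df[samples].to_numpy(float).T)


def write_vcf(gm: GenotypeMatrix, path) -> None:
    """Write dosages as an uncompressed VCF with a per-sample DS field.

    Variants are laid out on a single synthetic contig in column order;
    the ALT allele is the counted allele, so DS follows the usual
    ALT-dosage convention.
    """
    header = pysam.VariantHeader()
    header.add_line('##contig=<ID=chrSYN,length=100000000>')
    header.add_line('##FORMAT=<ID=DS,Number=1,Type=Float,'
                    'Description="Dosage of the ALT (counted) allele">')
    for s in gm.sample_ids:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for j, vid in enumerate(gm.variant_ids):
            rec = vcf.new_record(
                contig="chrSYN", start=j * 100, stop=j * 100 + 1,
                alleles=(gm.other_allele[j], gm.counted_allele[j]), id=vid)
            for i, s in enumerate(gm.sample_ids):
                d = gm.dosages[i, j]
                rec.samples[s]["DS"] = None if np.isnan(d) else float(d)
            vcf.write(rec)


def load_vcf(path) -> GenotypeMatrix:
    """Read a DS-dosage VCF back into a genotype matrix."""
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        variant_ids, counted, other, rows = [], [], [], []
        for rec in vcf:
            variant_ids.append(rec.id)
            counted.append(rec.alts[0])
            other.append(rec.ref)
            row = np.full(len(samples), np.nan)
            for i, s in enumerate(samples):
                ds = rec.samples[s].get("DS")
                if ds is not None:
                    row[i] = float(ds)
            rows.append(row)
    dosages = (np.vstack(rows).T if rows
               else np.empty((len(samples), 0)))
    return GenotypeMatrix(sample_ids=samples, variant_ids=variant_ids,
                          counted_allele=counted, other_allele=other,
                          dosages=dosages)


# ---------------------------------------------------------------------------
# Bundled fixtures
# ---------------------------------------------------------------------------

def load_bundled_rates(name: str = "singapore_rates_synthetic.csv",
                       population: str | None = None) -> RatesTable:
    path = bundled_path(name)
    if population is None:
        pops = pd.read_csv(path, comment="#")["population"].unique()
        if len(pops) > 1 and "overall" in pops:
            population = "overall"
    return load_rates(path, population=population)


def load_bundled_gail_params(name: str = "gail_params_aabcs.txt") -> GailParams:
    return load_gail_params(bundled_path(name))


def load_bundled_panel(name: str = "prs_panel_synthetic.tsv"):
    """Bundled synthetic 313-variant panel: (PRSWeights, allele freqs)."""
    path = bundled_path(name)
    return load_weights(path), load_panel_freqs(path)


def load_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(obj: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)
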