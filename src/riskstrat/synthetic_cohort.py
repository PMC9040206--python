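"""Synthetic case-cohort generator.

Emulates the statistical structure of an Asian breast-cancer case series:
genotypes at a 313-variant PRS panel under Hardy-Weinberg equilibrium,
questionnaire risk factors and family history drawn from configurable
marginal frequencies, protein-truncating-variant (PTV) carriership over a
nine-gene panel, ages at diagnosis from a truncated normal, and a
case-sampling operation that enriches for high polygenic scores under the
rare-disease log-linear risk model (selection probability proportional to
``exp(beta * z)``).

Risk factors are simulated independently of each other and of the PRS;
only the marginal frequencies of the emulated cohort are targeted.  Joint
structure (e.g. a family-history/PTV correlation) can be introduced by
passing explicit per-individual overrides to :func:`simulate_cohort`
callers, but the default is independence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .prs import GenotypeMatrix
from .absolute_risk import (BIOPSY_CATEGORIES, FIRST_BIRTH_CATEGORIES,
                            MENARCHE_CATEGORIES)

logger = logging.getLogger("riskstrat")

__all__ = [
    "SimulationConfig",
    "DEFAULT_RISKFACTOR_FREQS",
    "DEFAULT_PRS_BETA",
    "simulate_genotypes",
    "simulate_cohort",
    "sample_cases_by_risk",
    "simulate_variant_records",
]

#: Default per-SD log relative risk of the PRS (odds ratio ~1.61 per SD,
#: the scale reported for 313-variant overall-breast-cancer scores).
DEFAULT_PRS_BETA = float(np.log(1.61))

# Marginal category frequencies of the emulated 7600-patient case series
# (exact fractions of the published counts; unknowns kept explicit so that
# downstream unknown-handling is exercised).
DEFAULT_RISKFACTOR_FREQS: dict = {
    "menarche": {">=14": 2212 / 7600, "12-13": 3968 / 7600,
                 "<12": 803 / 7600, "unknown": 617 / 7600},
    "first_birth": {"<20": 335 / 7600, "20-25": 1479 / 7600,
                    "25-30": 2289 / 7600, ">=30": 1792 / 7600,
                    "nulliparous": 1294 / 7600, "unknown": 411 / 7600},
    "biopsy": {"no": 0.88, "yes": 0.07, "unknown": 0.05},
    "fh_breast": {False: 0.85, True: 0.15},
    "fh_ovarian": {False: 0.98, True: 0.02},
    "ptv_carrier": {False: 0.95, True: 0.05},
    "ethnicity": {"Chinese": 5724 / 7600, "Malay": 1145 / 7600,
                  "Indian": 645 / 7600, "Other": 86 / 7600},
    "case_type": {"incident": 4513 / 7600, "prevalent": 3087 / 7600},
}

_CATEGORY_DOMAINS = {
    "menarche": set(MENARCHE_CATEGORIES),
    "first_birth": set(FIRST_BIRTH_CATEGORIES),
    "biopsy": set(BIOPSY_CATEGORIES),
    "fh_breast": {True, False},
    "fh_ovarian": {True, False},
    "ptv_carrier": {True, False},
}

NINE_GENE_PANEL = frozenset(
    {"ATM", "BRCA1", "BRCA2", "CHEK2", "PALB2", "BARD1", "RAD51C", "RAD51D", "TP53"}
)

PTV_CONSEQUENCES = ("nonsense_snv", "frameshift_indel", "splice_disrupting_snv")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Ages at diagnosis follow a normal distribution (default median 52,
    SD matched to an interquartile range of 45-59) truncated to
    ``age_range``.
    """

    n_individuals: int
    allele_freqs: np.ndarray
    prs_log_or_per_sd: float = DEFAULT_PRS_BETA
    riskfactor_freqs: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_RISKFACTOR_FREQS.items()})
    age_range: tuple = (30.0, 75.0)
    age_mean: float = 52.0
    age_sd: float = (59.0 - 45.0) / 1.349
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 0:
            raise ValueError("n_individuals must be >= 0")
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        _check_freqs(self.allele_freqs)
        if not np.isfinite(self.prs_log_or_per_sd):
            raise ValueError("prs_log_or_per_sd must be finite")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must be increasing")
        for name, freqs in self.riskfactor_freqs.items():
            total = float(sum(freqs.values()))
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"category frequencies for {name!r} sum to {total!r}, not 1")
            if any(p < 0 for p in freqs.values()):
                raise ValueError(f"negative category frequency in {name!r}")
            domain = _CATEGORY_DOMAINS.get(name)
            if domain is not None and not set(freqs) <= domain:
                raise ValueError(
                    f"unknown categories {set(freqs) - domain} for {name!r}")


def _check_freqs(freqs: np.ndarray) -> None:
    bad = ~(np.isfinite(freqs) & (freqs > 0.0) & (freqs < 1.0))
    if bad.any():
        idx = int(np.argmax(bad))
        raise ValueError(
            f"allele frequency at variant index {idx} is {freqs[idx]!r}; "
            "frequencies must be strictly inside (0, 1)")


def simulate_genotypes(freqs: Sequence[float] | np.ndarray, n: int,
                       missing_rate: float = 0.0, seed: int = 0,
                       variant_ids: Sequence[str] | None = None,
                       effect_allele: Sequence[str] | None = None,
                       other_allele: Sequence[str] | None = None,
                       ) -> GenotypeMatrix:
    """Hardy-Weinberg genotype dosages: two Bernoulli(freq) draws summed.

    The counted allele of each column is the panel's effect allele.
    Missing entries (NaN) are introduced independently at ``missing_rate``.
    """
    freqs = np.asarray(freqs, dtype=float)
    _check_freqs(freqs)
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    m = len(freqs)
    rng = np.random.default_rng(seed)
    dosages = rng.binomial(2, freqs, size=(n, m)).astype(float)
    if missing_rate > 0.0 and n > 0:
        dosages[rng.random((n, m)) < missing_rate] = np.nan
    if variant_ids is None:
        variant_ids = [f"var{j + 1:04d}" for j in range(m)]
    if effect_allele is None:
        effect_allele = ["A"] * m
    if other_allele is None:
        other_allele = ["G"] * m
    return GenotypeMatrix(
        sample_ids=[f"S{i + 1:06d}" for i in range(n)],
        variant_ids=variant_ids, counted_allele=effect_allele,
        other_allele=other_allele, dosages=dosages)


def simulate_cohort(config: SimulationConfig) -> tuple[pd.DataFrame, GenotypeMatrix]:
    """Draw a cohort table and matching genotype matrix.

    Each categorical field is drawn independently from its configured
    marginal map; ages come from the truncated normal.  Output is fully
    reproducible under ``config.seed``.
    """
    n = config.n_individuals
    ss = np.random.SeedSequence(config.seed)
    geno_seed, field_seed, age_seed = ss.spawn(3)
    rng = np.random.default_rng(field_seed)

    cohort = pd.DataFrame({"individual_id": [f"S{i + 1:06d}" for i in range(n)]})
    lo, hi = config.age_range
    a, b = (lo - config.age_mean) / config.age_sd, (hi - config.age_mean) / config.age_sd
    ages = stats.truncnorm.rvs(a, b, loc=config.age_mean, scale=config.age_sd,
                               size=n, random_state=np.random.default_rng(age_seed))
    cohort["age"] = ages
    for name, freqs in config.riskfactor_freqs.items():
        cats = list(freqs)
        p = np.array([freqs[c] for c in cats], dtype=float)
        p = p / p.sum()  # guard rounding at 1e-9 scale
        draws = rng.choice(len(cats), size=n, p=p)
        vals = [cats[i] for i in draws]
        cohort[name] = pd.array(vals, dtype="boolean") if set(cats) <= {True, False} \
            else vals
    genotypes = simulate_genotypes(config.allele_freqs, n,
                                   missing_rate=config.missing_rate,
                                   seed=geno_seed)
    return cohort, genotypes


def sample_cases_by_risk(standardized_prs: Sequence[float] | np.ndarray,
                         beta: float, n_cases: int, seed: int = 0) -> np.ndarray:
    """Select cases without replacement with probability ~ exp(beta * z).

    Implemented as Gumbel top-k (equivalent to sequential weighted
    sampling without replacement).  Under rare sampling from a standard
    normal population the selected z are approximately N(beta, 1).
    Returns a boolean indicator vector over the population.
    """
    z = np.asarray(standardized_prs, dtype=float)
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if n_cases > z.size:
        raise ValueError(f"n_cases={n_cases} exceeds population size {z.size}")
    rng = np.random.default_rng(seed)
    keys = beta * z + rng.gumbel(size=z.size)
    cases = np.zeros(z.size, dtype=bool)
    if n_cases > 0:
        cases[np.argpartition(-keys, n_cases - 1)[:n_cases]] = True
    return cases


def simulate_variant_records(cohort: pd.DataFrame, seed: int = 0,
                             decoy_rate: float = 0.05,
                             genes: Sequence[str] | None = None) -> pd.DataFrame:
    """Emit an annotated variant table consistent with the cohort's carriers.

    Every individual flagged ``ptv_carrier`` receives one qualifying PTV
    (random panel gene, random truncating consequence class, not in the
    last exon).  A fraction ``decoy_rate`` of all individuals additionally
    receive a non-qualifying record (a missense variant or a last-exon
    PTV) so that downstream filtering is exercised.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(genes if genes is not None else NINE_GENE_PANEL)
    rows = []
    carriers = cohort.loc[cohort["ptv_carrier"].astype(bool), "individual_id"]
    for iid in carriers:
        rows.append((iid, genes[rng.integers(len(genes))],
                     PTV_CONSEQUENCES[rng.integers(3)], False))
    decoys = cohort.loc[rng.random(len(cohort)) < decoy_rate, "individual_id"]
    for iid in decoys:
        if rng.random() < 0.5:
            rows.append((iid, genes[rng.integers(len(genes))], "other", False))
        else:
            rows.append((iid, genes[rng.integers(len(genes))],
                         PTV_CONSEQUENCES[rng.integers(3)], True))
    return pd.DataFrame(rows, columns=["individual_id", "gene", "consequence",
                                       "in_last_exon"])
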