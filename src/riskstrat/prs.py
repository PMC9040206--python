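"""Polygenic risk score computation and standardization.

The raw score is a weighted sum of effect-allele dosages over a fixed
variant panel (plink ``--score ... sum`` semantics: a total, not a mean).
Scores are standardized against a reference (control) population's mean
and standard deviation, optionally per population label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("riskstrat")

__all__ = [
    "PRSWeights",
    "GenotypeMatrix",
    "ReferenceStats",
    "compute_raw_prs",
    "compute_reference_stats",
    "standardize_prs",
    "standardize_by_population",
]

_AMBIGUOUS_PAIRS = {frozenset(("A", "T")), frozenset(("C", "G"))}


@dataclass(frozen=True)
class PRSWeights:
    """Per-variant effect allele, other allele and log-odds weight."""

    ids: tuple
    effect_allele: tuple
    other_allele: tuple
    weight: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "ids", tuple(self.ids))
        object.__setattr__(self, "effect_allele", tuple(a.upper() for a in self.effect_allele))
        object.__setattr__(self, "other_allele", tuple(a.upper() for a in self.other_allele))
        object.__setattr__(self, "weight", np.asarray(self.weight, dtype=float))
        n = len(self.ids)
        if not (len(self.effect_allele) == len(self.other_allele) == len(self.weight) == n):
            raise ValueError("weights columns have unequal lengths")
        if len(set(self.ids)) != n:
            dup = pd.Index(self.ids)
            raise ValueError(f"duplicate variant ids: {sorted(dup[dup.duplicated()])[:5]}")
        same = [i for i, (e, o) in enumerate(zip(self.effect_allele, self.other_allele)) if e == o]
        if same:
            raise ValueError(f"effect_allele equals other_allele at rows {same[:5]}")
        if not np.all(np.isfinite(self.weight)):
            raise ValueError("weights must be finite")

    def __len__(self) -> int:
        return len(self.ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PRSWeights":
        return cls(ids=df["id"].tolist(), effect_allele=df["effect_allele"].tolist(),
                   other_allele=df["other_allele"].tolist(),
                   weight=df["weight"].to_numpy())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "effect_allele": self.effect_allele,
                             "other_allele": self.other_allele, "weight": self.weight})


@dataclass
class GenotypeMatrix:
    """Individuals x variants dosages of a *counted* allele.

    ``dosages[i, j]`` is the count (0, 1 or 2) of ``counted_allele[j]``
    carried by individual i, or NaN when missing.  The counted allele need
    not be the PRS effect allele; scoring resolves orientation.
    """

    sample_ids: tuple
    variant_ids: tuple
    counted_allele: tuple
    other_allele: tuple
    dosages: np.ndarray  # float array, NaN = missing

    def __post_init__(self) -> None:
        self.sample_ids = tuple(self.sample_ids)
        self.variant_ids = tuple(self.variant_ids)
        self.counted_allele = tuple(a.upper() for a in self.counted_allele)
        self.other_allele = tuple(a.upper() for a in self.other_allele)
        self.dosages = np.asarray(self.dosages, dtype=float)
        n, m = self.dosages.shape
        if n != len(self.sample_ids) or m != len(self.variant_ids):
            raise ValueError("dosage matrix shape does not match id lists")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = np.unique(vals[~np.isin(vals, (0.0, 1.0, 2.0))])
            raise ValueError(f"dosages must be 0, 1, 2 or missing; found {bad[:5]}")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]


@dataclass(frozen=True)
class ReferenceStats:
    """Control-population mean and SD used to standardize raw scores."""

    mean: float
    sd: float
    population: str = "pooled"

    def __post_init__(self) -> None:
        if not (np.isfinite(self.sd) and self.sd > 0):
            raise ValueError("reference sd must be finite and > 0")


def _orient_dosages(gm: GenotypeMatrix, weights: PRSWeights):
    """Align genotype columns to the weights' effect alleles.

    Returns (effect_dosages, weight_vector, n_ambiguous).  Variants absent
    from the genotype matrix or with unmatchable alleles are dropped with
    a warning; an error is raised if nothing remains.
    """
    col_of = {vid: j for j, vid in enumerate(gm.variant_ids)}
    cols, w, flips = [], [], []
    n_absent = n_mismatch = n_ambiguous = 0
    for i, vid in enumerate(weights.ids):
        j = col_of.get(vid)
        if j is None:
            n_absent += 1
            continue
        ea, oa = weights.effect_allele[i], weights.other_allele[i]
        ca, cb = gm.counted_allele[j], gm.other_allele[j]
        if (ca, cb) == (ea, oa):
            flip = False
        elif (ca, cb) == (oa, ea):
            flip = True
        else:
            n_mismatch += 1
            continue
        if frozenset((ea, oa)) in _AMBIGUOUS_PAIRS:
            n_ambiguous += 1
        cols.append(j)
        w.append(weights.weight[i])
        flips.append(flip)
    if n_absent or n_mismatch:
        logger.warning("PRS scoring excluded %d absent and %d allele-mismatched variants",
                       n_absent, n_mismatch)
    if n_ambiguous:
        logger.warning("%d strand-ambiguous (A/T or C/G) variants matched as reported",
                       n_ambiguous)
    if not cols:
        raise ValueError("no weights variant could be matched to the genotype matrix")
    d = gm.dosages[:, cols].copy()
    flips = np.asarray(flips)
    d[:, flips] = 2.0 - d[:, flips]  # NaN stays NaN
    return d, np.asarray(w), n_ambiguous


def compute_raw_prs(genotypes: GenotypeMatrix, weights: PRSWeights,
                    missing_policy: str = "mean_impute") -> np.ndarray:
    """Weighted sum of effect-allele dosages (scoresum-style total).

    ``missing_policy``:

    * ``"mean_impute"`` — a missing dosage contributes ``w * 2 * freq``
      with the effect-allele frequency estimated from non-missing
      individuals at that variant (the plink default behaviour);
    * ``"omit"`` — missing dosages contribute nothing.
    """
    if missing_policy not in ("mean_impute", "omit"):
        raise ValueError(f"unknown missing policy {missing_policy!r}")
    d, w, _ = _orient_dosages(genotypes, weights)
    if d.shape[0] == 0:
        return np.zeros(0)
    miss = np.isnan(d)
    if missing_policy == "mean_impute" and miss.any():
        col_mean = np.nanmean(np.where(miss, np.nan, d), axis=0)
        all_missing = np.isnan(col_mean)
        if all_missing.any():
            logger.warning("%d variants missing in every individual contribute 0",
                           int(all_missing.sum()))
            col_mean = np.where(all_missing, 0.0, col_mean)
        d = np.where(miss, col_mean[None, :], d)
    else:
        d = np.where(miss, 0.0, d)
    return d @ w


def compute_reference_stats(raw_scores: Sequence[float] | np.ndarray,
                            population: str = "pooled") -> ReferenceStats:
    """Mean and sample SD (n-1 denominator) of control raw scores."""
    x = np.asarray(raw_scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 2:
        raise ValueError("need at least 2 finite control scores")
    sd = float(np.std(x, ddof=1))
    if sd == 0.0:
        raise ValueError("control scores have zero variance; standardization undefined")
    return ReferenceStats(mean=float(np.mean(x)), sd=sd, population=population)


def standardize_prs(raw: Sequence[float] | np.ndarray, ref: ReferenceStats) -> np.ndarray:
    """z = (raw - ref.mean) / ref.sd."""
    return (np.asarray(raw, dtype=float) - ref.mean) / ref.sd


def standardize_by_population(raw: np.ndarray, labels: Sequence[str],
                              refs: Mapping[str, ReferenceStats],
                              pooled: ReferenceStats) -> np.ndarray:
    """Standardize each individual against its population's reference.

    Individuals whose label has no entry in ``refs`` fall back to the
    pooled reference with a warning.
    """
    raw = np.asarray(raw, dtype=float)
    labels = np.asarray(labels, dtype=object)
    z = np.empty_like(raw)
    missing = set()
    for lab in np.unique(labels):
        mask = labels == lab
        ref = refs.get(lab)
        if ref is None:
            ref = pooled
            missing.add(str(lab))
        z[mask] = standardize_prs(raw[mask], ref)
    if missing:
        logger.warning("no reference stats for populations %s; pooled reference used",
                       sorted(missing))
    return z
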