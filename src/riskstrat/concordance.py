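"""Agreement and overlap between high-risk criteria.

Pairwise Cohen's kappa between binary classifications, Spearman rank
correlation and the Wilcoxon signed-rank paired test between the two
absolute-risk scales, exhaustive Venn-region decomposition of up to six
criteria, and the incremental proportion of a cohort identified as the
criteria are added sequentially within 5-year age groups.

Degenerate inputs (constant vectors, no nonzero paired differences,
identical constant raters) are reported with an explicit status rather
than a numeric value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.inter_rater import cohens_kappa as _sm_kappa

logger = logging.getLogger("riskstrat")

__all__ = [
    "KappaResult", "CorrelationResult", "SignedRankResult", "OverlapSummary",
    "cohens_kappa", "rank_correlation", "paired_signed_rank", "venn_counts",
    "incremental_by_age", "DEFAULT_AGE_BINS",
]

#: 5-year age bins [30,35) ... [70,75]; the last bin is closed at 75.
DEFAULT_AGE_BINS = tuple(range(30, 75, 5))


@dataclass(frozen=True)
class KappaResult:
    kappa: float | None
    p_value: float | None
    status: str = "ok"  # "ok" or "degenerate"


@dataclass(frozen=True)
class CorrelationResult:
    rho: float | None
    status: str = "ok"


@dataclass(frozen=True)
class SignedRankResult:
    statistic: float | None
    p_value: float | None
    method: str = ""
    status: str = "ok"


@dataclass(frozen=True)
class OverlapSummary:
    """Disjoint Venn regions of k binary criteria.

    ``region_counts`` is keyed by membership pattern strings like "1010"
    (one character per criterion, in ``names`` order).
    """

    names: tuple
    region_counts: dict
    marginals: dict
    union: int
    n: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pattern": list(self.region_counts),
             "count": list(self.region_counts.values())})


def cohens_kappa(a: Sequence[bool], b: Sequence[bool]) -> KappaResult:
    """Chance-corrected agreement between two binary classifications.

    kappa = (p_o - p_e) / (1 - p_e); the p-value is two-sided from the
    large-sample normal approximation of kappa's null standard error.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    table = np.array([[np.sum(~a & ~b), np.sum(~a & b)],
                      [np.sum(a & ~b), np.sum(a & b)]], dtype=float)
    p_row = table.sum(axis=1) / n
    p_col = table.sum(axis=0) / n
    p_e = float(p_row @ p_col)
    if 1.0 - p_e < 1e-15:
        return KappaResult(kappa=None, p_value=None, status="degenerate")
    res = _sm_kappa(table, return_results=True)
    return KappaResult(kappa=float(res.kappa),
                       p_value=float(res.pvalue_two_sided), status="ok")


def rank_correlation(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman's rho with average ranks on ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        return CorrelationResult(rho=None, status="degenerate")
    rho = stats.spearmanr(x, y).statistic
    return CorrelationResult(rho=float(rho), status="ok")


def paired_signed_rank(x: Sequence[float], y: Sequence[float]) -> SignedRankResult:
    """Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking.  The exact null
    distribution is used for n <= 25 without ties in |d|; otherwise the
    normal approximation with tie correction.  The statistic is the sum
    of ranks of positive differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must have equal length")
    d = x - y
    d = d[d != 0.0]
    if d.size == 0:
        return SignedRankResult(statistic=None, p_value=None, status="degenerate")
    ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not ties) else "approx"
    res = stats.wilcoxon(d, alternative="two-sided", method=method,
                         correction=False)
    w_plus = float(stats.rankdata(np.abs(d))[d > 0].sum())
    return SignedRankResult(statistic=w_plus, p_value=float(res.pvalue),
                            method=method)


def venn_counts(flags: Mapping[str, Sequence[bool]]) -> OverlapSummary:
    """Exhaustive disjoint-region counts for up to six binary criteria."""
    names = tuple(flags)
    if not 1 <= len(names) <= 6:
        raise ValueError("venn_counts supports 1 to 6 criteria")
    arrays = [np.asarray(flags[name], dtype=bool) for name in names]
    n = arrays[0].size
    if any(a.size != n for a in arrays):
        raise ValueError("criterion vectors must have equal length")
    codes = np.zeros(n, dtype=int)
    for a in arrays:  # first name -> most significant bit
        codes = (codes << 1) | a.astype(int)
    counts = np.bincount(codes, minlength=2 ** len(names))
    region_counts = {
        format(code, f"0{len(names)}b"): int(c)
        for code, c in enumerate(counts)
    }
    marginals = {name: int(a.sum()) for name, a in zip(names, arrays)}
    union = int(n - counts[0])
    return OverlapSummary(names=names, region_counts=region_counts,
                          marginals=marginals, union=union, n=n)


def incremental_by_age(flags: Mapping[str, Sequence[bool]] | pd.DataFrame,
                       ages: Sequence[float],
                       sequence: Sequence[str],
                       bins: Sequence[int] = DEFAULT_AGE_BINS) -> pd.DataFrame:
    """Proportion flagged by growing unions of criteria, per 5-year age bin.

    For each bin and each prefix of ``sequence``, the fraction of the
    bin's individuals flagged by at least one criterion in the prefix.
    Ages outside the bins land in an "outside" overflow row (with a
    warning).  The output has one row per bin and one proportion column
    per prefix (named "+<criterion>" cumulatively), plus an n column.
    """
    if isinstance(flags, pd.DataFrame):
        flags = {c: flags[c].to_numpy() for c in flags.columns}
    missing = [s for s in sequence if s not in flags]
    if missing:
        raise ValueError(f"criteria {missing} not present in flags")
    ages = np.asarray(ages, dtype=float)
    n = ages.size
    arrays = {k: np.asarray(v, dtype=bool) for k, v in flags.items()}
    if any(v.size != n for v in arrays.values()):
        raise ValueError("flag vectors not aligned with ages")

    bins = list(bins)
    edges = bins + [bins[-1] + 5]
    labels = [f"{lo}-{lo + 4}" for lo in bins]
    # last bin closed on the right (e.g. age exactly 75 belongs to 70-74)
    idx = np.searchsorted(edges, ages, side="right") - 1
    idx[ages == edges[-1]] = len(bins) - 1
    outside = (idx < 0) | (idx >= len(bins))
    if outside.any():
        logger.warning("%d ages outside configured bins assigned to overflow",
                       int(outside.sum()))
    rows = []
    for b, label in enumerate(labels + (["outside"] if outside.any() else [])):
        mask = outside if label == "outside" else (idx == b) & ~outside
        row = {"age_group": label, "n": int(mask.sum())}
        running = np.zeros(n, dtype=bool)
        for crit in sequence:
            running = running | arrays[crit]
            prop = float(running[mask].mean()) if mask.any() else np.nan
            row[f"+{crit}"] = prop
        rows.append(row)
    return pd.DataFrame(rows)
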