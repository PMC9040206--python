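"""The four high-risk criteria.

An individual is high risk if any of the following hold:

1. family history — at least one first-degree relative with breast or
   ovarian cancer;
2. PRS — 5-year absolute risk by the polygenic score at or above the
   screening threshold (default 1.3%, the 5-year risk of an average
   50-year-old woman);
3. Gail — 5-year absolute risk by the Gail model at or above the same
   threshold;
4. PTV — carriership of a protein-truncating variant (nonsense SNV,
   frameshift indel or splice-disrupting SNV, outside the gene's last
   exon, where truncation escapes nonsense-mediated decay) in one of nine
   breast-cancer predisposition genes.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic_cohort import NINE_GENE_PANEL, PTV_CONSEQUENCES

logger = logging.getLogger("riskstrat")

__all__ = ["NINE_GENE_PANEL", "DEFAULT_THRESHOLD", "classify_ptv",
           "classify_high_risk", "CRITERIA"]

#: 5-year absolute risk of an average 50-year-old woman (screening threshold).
DEFAULT_THRESHOLD = 0.013

#: Canonical criterion order used in reports (family history first, then
#: Gail, PRS, PTV — the sequential-addition order of the age-group figure).
CRITERIA = ("fh_high", "gail_high", "prs_high", "ptv_carrier")

_VALID_CONSEQUENCES = set(PTV_CONSEQUENCES) | {"other"}


def classify_ptv(variants: pd.DataFrame, individual_ids: Sequence[str],
                 panel: Iterable[str] = NINE_GENE_PANEL) -> np.ndarray:
    """Carrier flag per individual from annotated variant records.

    ``variants`` needs columns individual_id, gene, consequence,
    in_last_exon.  A carrier has at least one truncating variant
    (nonsense SNV, frameshift indel, splice-disrupting SNV) in a panel
    gene outside its last exon; last-exon truncating variants are excluded
    because they are expected to escape nonsense-mediated decay.
    """
    panel = set(panel)
    required = {"individual_id", "gene", "consequence", "in_last_exon"}
    missing = required - set(variants.columns)
    if missing:
        raise ValueError(f"variant table missing columns {sorted(missing)}")
    bad = ~variants["consequence"].isin(_VALID_CONSEQUENCES)
    if bad.any():
        offending = variants.loc[bad].head(5).to_dict("records")
        raise ValueError(f"unknown consequence class in records: {offending}")
    qualifying = variants[
        variants["consequence"].isin(PTV_CONSEQUENCES)
        & variants["gene"].isin(panel)
        & ~variants["in_last_exon"].astype(bool)
    ]
    carriers = set(qualifying["individual_id"])
    return np.fromiter((iid in carriers for iid in individual_ids),
                       dtype=bool, count=len(individual_ids))


def classify_high_risk(cohort: pd.DataFrame, prs_risk: Sequence[float],
                       gail_risk: Sequence[float],
                       threshold: float = DEFAULT_THRESHOLD,
                       strict: bool = False) -> pd.DataFrame:
    """Apply the four criteria; returns one row per individual.

    ``cohort`` needs boolean columns fh_breast, fh_ovarian, ptv_carrier.
    Risk flags use an inclusive boundary (risk >= threshold counts as
    high) unless ``strict`` is set, in which case the comparison is >.
    """
    prs_risk = np.asarray(prs_risk, dtype=float)
    gail_risk = np.asarray(gail_risk, dtype=float)
    n = len(cohort)
    if prs_risk.shape != (n,) or gail_risk.shape != (n,):
        raise ValueError(
            f"risk vectors ({prs_risk.shape[0]}, {gail_risk.shape[0]}) "
            f"not aligned with cohort of size {n}")
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    cmp = np.greater if strict else np.greater_equal
    out = pd.DataFrame({
        "individual_id": cohort["individual_id"].to_numpy(),
        "fh_high": (cohort["fh_breast"].astype(bool)
                    | cohort["fh_ovarian"].astype(bool)).to_numpy(),
        "prs_risk_5y": prs_risk,
        "gail_risk_5y": gail_risk,
        "prs_high": cmp(prs_risk, threshold),
        "gail_high": cmp(gail_risk, threshold),
        "ptv_carrier": cohort["ptv_carrier"].astype(bool).to_numpy(),
    })
    out["any_high"] = (out["fh_high"] | out["prs_high"] | out["gail_high"]
                       | out["ptv_carrier"])
    return out
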