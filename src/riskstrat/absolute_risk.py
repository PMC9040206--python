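"""Five-year absolute breast-cancer risk under competing mortality.

Converts relative risks (polygenic or questionnaire-based) into absolute
risks using piecewise-constant age-interval incidence and competing
(non-breast-cancer) mortality hazards.

Two relative-risk engines are supported:

* A polygenic risk score (PRS) engine: the per-individual relative risk is
  ``exp(beta * z)`` where ``z`` is the standardized PRS and ``beta`` the
  per-SD log relative risk.  Because the population incidence already
  averages over the PRS distribution, the baseline hazard applicable at
  ``z = 0`` must be *calibrated*: interval by interval, the baseline is
  solved so that the incidence averaged over the PRS distribution of
  still-unaffected women reproduces the registry incidence, and the
  survivor distribution is then depleted by the PRS-dependent hazard
  (higher-PRS women are removed faster, shifting survivors downward).

* A Gail-model engine: the relative risk is a log-linear function of
  questionnaire risk factors (age at menarche, biopsy history, age at
  first live birth, first-degree relatives with breast cancer), with an
  age-segment split at 50 years, and the baseline hazard is the composite
  incidence scaled by one minus the attributable-risk proportion.

Absolute risk over a 5-year window is evaluated in closed form on each
piecewise-constant sub-interval:

    risk = sum_j  rh_j / (rh_j + m_j) * (1 - exp(-(rh_j + m_j) dt_j)) * S_j

where ``rh_j`` is the cause-specific breast-cancer hazard, ``m_j`` the
competing mortality and ``S_j`` survival (both causes) to the start of
sub-interval ``j``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

logger = logging.getLogger("riskstrat")

__all__ = [
    "RatesTable",
    "CalibratedHazards",
    "GailParams",
    "RiskFactorProfile",
    "MENARCHE_CATEGORIES",
    "FIRST_BIRTH_CATEGORIES",
    "BIOPSY_CATEGORIES",
    "calibrate_baseline_hazard",
    "five_year_absolute_risk",
    "population_five_year_risk",
    "prs_five_year_risk",
    "gail_relative_risk",
    "gail_absolute_risk",
]

# Closed category sets for the questionnaire risk factors.
MENARCHE_CATEGORIES = (">=14", "12-13", "<12", "unknown")
FIRST_BIRTH_CATEGORIES = ("<20", "20-25", "25-30", ">=30", "nulliparous", "unknown")
BIOPSY_CATEGORIES = ("no", "yes", "unknown")

# Gail-model category scores (units of the per-unit log relative risks).
# Unknowns map to the reference (lowest-risk) category, the convention of
# the BCRAT-style tools; nulliparous scores with the 25-29 first-birth class.
_MENARCHE_SCORE = {">=14": 0, "12-13": 1, "<12": 2, "unknown": 0}
_FIRST_BIRTH_SCORE = {"<20": 0, "20-25": 1, "25-30": 2, ">=30": 3,
                      "nulliparous": 2, "unknown": 0}
_BIOPSY_SCORE = {"no": 0, "yes": 1, "unknown": 0}


# ---------------------------------------------------------------------------
# Rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatesTable:
    """Age-interval incidence and competing-mortality rates.

    Rates are hazards in events per person-year; intervals ``[age_low,
    age_high)`` must be contiguous, non-overlapping and ascending.
    """

    age_low: np.ndarray
    age_high: np.ndarray
    incidence: np.ndarray
    mortality: np.ndarray
    population: str = "overall"

    def __post_init__(self) -> None:
        for name in ("age_low", "age_high", "incidence", "mortality"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.age_low)
        if not (len(self.age_high) == len(self.incidence) == len(self.mortality) == n):
            raise ValueError("rates columns have unequal lengths")
        if n == 0:
            raise ValueError("empty rates table")
        if np.any(self.age_high <= self.age_low):
            raise ValueError("age_high must exceed age_low in every interval")
        gaps = self.age_low[1:] != self.age_high[:-1]
        if np.any(gaps):
            i = int(np.argmax(gaps))
            raise ValueError(
                f"rates intervals not contiguous: gap/overlap between "
                f"{self.age_high[i]:g} and {self.age_low[i + 1]:g}"
            )
        for name in ("incidence", "mortality"):
            v = getattr(self, name)
            if not np.all(np.isfinite(v)) or np.any(v < 0):
                raise ValueError(f"{name} rates must be finite and >= 0")

    @property
    def n_intervals(self) -> int:
        return len(self.age_low)

    @property
    def edges(self) -> np.ndarray:
        return np.append(self.age_low, self.age_high[-1])

    def interval_index(self, age: float) -> int:
        """Index of the interval containing ``age`` (right-open)."""
        if age < self.age_low[0] or age >= self.age_high[-1]:
            raise ValueError(
                f"age {age:g} outside rates coverage "
                f"[{self.age_low[0]:g}, {self.age_high[-1]:g})"
            )
        return int(np.searchsorted(self.age_high, age, side="right"))

    def covers_window(self, age: float, horizon: float = 5.0) -> bool:
        return self.age_low[0] <= age and age + horizon <= self.age_high[-1]


# ---------------------------------------------------------------------------
# PRS baseline-hazard calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibratedHazards:
    """PRS-calibrated baseline hazards plus survivor-distribution bookkeeping.

    ``h0[k]`` is the breast-cancer hazard at standardized PRS z = 0 during
    interval k.  ``start_weights[k]`` are the (normalized) quadrature
    weights of the PRS distribution among women still unaffected at the
    start of interval k; row 0 is the discretized standard normal.
    """

    rates: RatesTable
    beta: float
    h0: np.ndarray
    nodes: np.ndarray
    start_weights: np.ndarray  # (n_intervals, n_nodes)

    def mean_rr_at_start(self, k: int) -> float:
        """Survivor-averaged relative risk E[exp(beta z)] entering interval k."""
        return float(self.start_weights[k] @ np.exp(self.beta * self.nodes))


def _gauss_hermite_normal(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Probabilists' Gauss-Hermite nodes/weights for a standard normal."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n)
    return nodes, weights / weights.sum()


def calibrate_baseline_hazard(
    rates: RatesTable,
    beta: float,
    quadrature_size: int = 64,
    max_iter: int = 200,
    rtol: float = 1e-10,
) -> CalibratedHazards:
    """Solve per-interval baseline hazards consistent with population incidence.

    Proceeding from the youngest interval: with the current survivor PRS
    distribution, ``h0`` is solved from the fixed point

        h0 * E_surv[exp(beta z)] = population incidence,

    where the survivor expectation is taken at the interval start; the
    distribution is then depleted over the interval by the PRS-specific
    hazard ``h0 * exp(beta z)`` (competing mortality is PRS-independent, so
    it cancels from the normalized distribution).  The within-interval
    fixed point is iterated to relative tolerance ``rtol``.
    """
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if quadrature_size < 2:
        raise ValueError("quadrature_size must be >= 2")
    nodes, w0 = _gauss_hermite_normal(quadrature_size)
    rr = np.exp(beta * nodes)

    n = rates.n_intervals
    widths = rates.age_high - rates.age_low
    h0 = np.empty(n)
    start_weights = np.empty((n, quadrature_size))

    w = w0.copy()
    for k in range(n):
        start_weights[k] = w
        lam = rates.incidence[k]
        mean_rr = float(w @ rr)
        h = lam / mean_rr
        for _ in range(max_iter):
            h_new = lam / mean_rr
            if abs(h_new - h) <= rtol * max(abs(h), 1e-300):
                h = h_new
                break
            h = h_new
        else:  # pragma: no cover - fixed point is closed-form, cannot stall
            raise RuntimeError(f"calibration did not converge in interval {k}")
        if h < 0 or not np.isfinite(h):
            raise RuntimeError(f"negative or non-finite baseline hazard in interval {k}")
        h0[k] = h
        # deplete survivors by the interval's breast-cancer hazard
        w = w * np.exp(-h * rr * widths[k])
        w /= w.sum()

    return CalibratedHazards(rates=rates, beta=beta, h0=h0, nodes=nodes,
                             start_weights=start_weights)


# ---------------------------------------------------------------------------
# Absolute-risk projection
# ---------------------------------------------------------------------------

def _window_breaks(rates: RatesTable, age: float, horizon: float,
                   extra_breaks: Sequence[float]) -> np.ndarray:
    end = age + horizon
    pts = [age, end]
    pts.extend(e for e in rates.edges if age < e < end)
    pts.extend(b for b in extra_breaks if age < b < end)
    return np.unique(np.asarray(pts, dtype=float))


def five_year_absolute_risk(
    relative_risk: float | Callable[[float], float],
    age: float,
    baseline: np.ndarray | Sequence[float],
    rates: RatesTable,
    horizon: float = 5.0,
    extra_breaks: Sequence[float] = (),
) -> float:
    """Absolute risk of breast cancer in ``[age, age + horizon)``.

    ``baseline`` is the per-interval breast-cancer baseline hazard aligned
    with ``rates`` (per person-year); the cause-specific hazard on each
    sub-interval is ``relative_risk * baseline``, competing mortality is
    ``rates.mortality``.  ``relative_risk`` may be a positive scalar or a
    callable of attained age (evaluated at the sub-interval start), in
    which case ``extra_breaks`` should list any ages where it jumps.
    """
    baseline = np.asarray(baseline, dtype=float)
    if baseline.shape != (rates.n_intervals,):
        raise ValueError("baseline hazards not aligned with rates intervals")
    if not rates.covers_window(age, horizon):
        raise ValueError(
            f"projection window [{age:g}, {age + horizon:g}) not covered by rates "
            f"[{rates.age_low[0]:g}, {rates.age_high[-1]:g})"
        )
    rr_fn = relative_risk if callable(relative_risk) else (lambda _a: float(relative_risk))

    breaks = _window_breaks(rates, age, horizon, extra_breaks)
    risk = 0.0
    log_surv = 0.0
    for lo, hi in zip(breaks[:-1], breaks[1:]):
        k = rates.interval_index(lo)
        r = rr_fn(lo)
        if r < 0:
            raise ValueError("relative risk must be positive")
        h = r * baseline[k]
        m = rates.mortality[k]
        dt = hi - lo
        tot = h + m
        surv = np.exp(log_surv)
        if tot > 0.0:
            risk += (h / tot) * (1.0 - np.exp(-tot * dt)) * surv
        log_surv -= tot * dt
    if not 0.0 <= risk <= 1.0:  # pragma: no cover - impossible under the formula
        raise AssertionError(f"absolute risk {risk} outside [0, 1]")
    return float(risk)


def population_five_year_risk(age: float, rates: RatesTable,
                              horizon: float = 5.0) -> float:
    """5-year risk of an average woman: composite incidence projected as-is.

    This is the quantity behind the 1.3% screening threshold (the 5-year
    absolute risk of an average 50-year-old woman on US white-female
    reference rates).
    """
    return five_year_absolute_risk(1.0, age, rates.incidence, rates, horizon)


def prs_five_year_risk(z: float, age: float, calib: CalibratedHazards,
                       horizon: float = 5.0) -> float:
    """5-year absolute risk for standardized PRS ``z`` at ``age``."""
    rr = float(np.exp(calib.beta * z))
    return five_year_absolute_risk(rr, age, calib.h0, calib.rates, horizon)


# ---------------------------------------------------------------------------
# Gail model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskFactorProfile:
    """Questionnaire risk factors entering the Gail relative risk."""

    menarche: str = ">=14"
    first_birth: str = "<20"
    biopsy: str = "no"
    n_relatives_breast: int = 0
    fh_ovarian: bool = False  # not a Gail factor; used by the FH criterion

    def __post_init__(self) -> None:
        if self.menarche not in MENARCHE_CATEGORIES:
            raise ValueError(f"invalid menarche category {self.menarche!r}")
        if self.first_birth not in FIRST_BIRTH_CATEGORIES:
            raise ValueError(f"invalid first-birth category {self.first_birth!r}")
        if self.biopsy not in BIOPSY_CATEGORIES:
            raise ValueError(f"invalid biopsy category {self.biopsy!r}")
        if self.n_relatives_breast not in (0, 1):
            raise ValueError("n_relatives_breast must be 0 or 1 (binary family history)")


@dataclass(frozen=True)
class GailParams:
    """Gail-model log relative risks and attributable risks, per age segment.

    ``coef[segment]`` maps factor names {menarche, biopsy, first_birth,
    relatives, fb_rel_interaction} to per-unit log relative risks; segments
    are "lt50" (age < 50) and "ge50".  ``ar[segment]`` is the
    attributable-risk proportion used to deflate composite incidence into
    the baseline-category hazard.
    """

    coef: dict = field(default_factory=dict)
    ar: dict = field(default_factory=dict)
    population: str = ""

    _FACTORS = ("menarche", "biopsy", "first_birth", "relatives", "fb_rel_interaction")

    def __post_init__(self) -> None:
        for seg in ("lt50", "ge50"):
            if seg not in self.coef:
                raise ValueError(f"missing coefficient segment {seg!r}")
            missing = [f for f in self._FACTORS if f not in self.coef[seg]]
            if missing:
                raise ValueError(f"segment {seg!r} missing coefficients {missing}")
            if seg not in self.ar:
                raise ValueError(f"missing attributable risk for segment {seg!r}")
            if not 0.0 <= self.ar[seg] < 1.0:
                raise ValueError("attributable risk must be in [0, 1)")

    def segment(self, age: float) -> str:
        return "lt50" if age < 50 else "ge50"


def gail_relative_risk(profile: RiskFactorProfile, age: float,
                       params: GailParams) -> float:
    """Relative risk versus the all-reference category profile.

    RR = exp(c_men*M + c_bio*B + c_fb*F + c_rel*R + c_int*F*R) with the
    category scores of the BCRAT coding and the coefficient set of the age
    segment (<50 vs >=50) containing ``age``.
    """
    if age < 20:
        raise ValueError("Gail model is undefined below age 20")
    c = params.coef[params.segment(age)]
    m = _MENARCHE_SCORE[profile.menarche]
    b = _BIOPSY_SCORE[profile.biopsy]
    f = _FIRST_BIRTH_SCORE[profile.first_birth]
    r = profile.n_relatives_breast
    lp = (c["menarche"] * m + c["biopsy"] * b + c["first_birth"] * f
          + c["relatives"] * r + c["fb_rel_interaction"] * f * r)
    return float(np.exp(lp))


def gail_absolute_risk(profile: RiskFactorProfile, age: float,
                       rates: RatesTable, params: GailParams,
                       horizon: float = 5.0) -> float:
    """Gail 5-year absolute risk with competing mortality.

    Baseline hazard per age interval is the composite incidence times
    (1 - AR) of the segment the interval falls in; the relative risk is
    re-evaluated per sub-interval so the age-50 segment change inside the
    projection window is honoured.
    """
    seg_of = params.segment
    one_minus_ar = np.array([1.0 - params.ar[seg_of(a)] for a in rates.age_low])
    baseline = rates.incidence * one_minus_ar
    rr_fn = lambda a: gail_relative_risk(profile, a, params)
    return five_year_absolute_risk(rr_fn, age, baseline, rates, horizon,
                                   extra_breaks=(50.0,))
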