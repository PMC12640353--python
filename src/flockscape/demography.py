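"""Census-based demographic statistics and FAO-style risk classification.

For each breed the herd book provides yearly counts of registered animals,
breeding males and females, and farms.  From these the module computes:

* percent change between two census years, 100 * (last - first) / first
  (``inf`` when the breed did not exist at the first census);
* the yearly growth rate r = (N2 / N1)^(1/t) for consecutive positive
  censuses (antilog of the log-count difference per year), with
  zero-registration years excluded, and its mean;
* Wright's effective population size for unequal sex ratios,
  Ne = 4 * Nm * Nf / (Nm + Nf), and the expected per-generation increase in
  inbreeding dF = 1 / (2 * Ne), reported in percent (undefined at Ne = 0);
* a risk category (NR / Vulnerable / Endangered / Critical / Extinct)
  assigned by the *least favourable* parameter: each available parameter is
  mapped to the worst category whose threshold it violates and the final
  category is the worst over parameters, with Extinct overriding everything
  when the latest census is zero.

Default thresholds follow FAO's in-vivo conservation guidance tiers but are
configuration, not published constants; swap in your own
:class:`RiskThresholds` to match a national programme.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["RiskThresholds", "RiskAssessment", "percent_change",
           "growth_rate", "wright_ne_delta_f", "classify_risk",
           "assess_breed", "CATEGORIES", "UNDEFINED"]

#: ordered worst-last; classification picks the maximum index
CATEGORIES = ("NR", "V", "E", "C", "Ex")

#: sentinel for quantities the data cannot define (e.g. dF at Ne = 0)
UNDEFINED = float("nan")


@dataclass
class RiskThresholds:
    """Per-category cutoffs; a parameter at or below (or for growth, below)
    the cutoff puts the breed in at least that category.  Monotone across
    categories: Critical strictest."""

    females_max: dict = field(default_factory=lambda: {
        "C": 100, "E": 1000, "V": 2000})
    males_max: dict = field(default_factory=lambda: {
        "C": 5, "E": 20, "V": 35})
    total_max: dict = field(default_factory=lambda: {
        "C": 120, "E": 1200, "V": 2400})
    growth_below: dict = field(default_factory=lambda: {
        "C": 0.90, "E": 0.95, "V": 1.00})
    delta_f_pct_min: dict = field(default_factory=lambda: {
        "C": 2.0, "E": 1.0, "V": 0.5})

    def __post_init__(self) -> None:
        for name in ("females_max", "males_max", "total_max", "growth_below"):
            t = getattr(self, name)
            if not t["C"] <= t["E"] <= t["V"]:
                raise ValueError(f"{name} thresholds not monotone (C<=E<=V)")
        t = self.delta_f_pct_min
        if not t["C"] >= t["E"] >= t["V"]:
            raise ValueError("delta_f thresholds not monotone (C>=E>=V)")


@dataclass
class RiskAssessment:
    breed: str
    mean_growth_rate: float
    ne: float
    delta_f_pct: float
    category: str
    triggering_parameter: str


def percent_change(first: float, last: float) -> float:
    """100 * (last - first) / first; ``inf`` when first = 0 and last > 0,
    0 when both are 0."""
    if first < 0 or last < 0:
        raise ValueError("counts must be non-negative")
    if first == 0:
        return 0.0 if last == 0 else math.inf
    return 100.0 * (last - first) / first


def growth_rate(years: np.ndarray, counts: np.ndarray
                ) -> tuple[pd.DataFrame, float]:
    """Per-interval growth rates r = (N2/N1)^(1/t) over consecutive
    positive-count censuses, and their arithmetic mean.

    Zero-registration years are excluded before pairing, so an interval
    spans the gap between the surrounding positive censuses.
    """
    years = np.asarray(years, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(years) != len(counts):
        raise ValueError("years and counts differ in length")
    pos = counts > 0
    y, n = years[pos], counts[pos]
    if len(n) < 2:
        raise ValueError("need at least 2 censuses with positive counts")
    t = np.diff(y)
    r = (n[1:] / n[:-1]) ** (1.0 / t)
    intervals = pd.DataFrame({"year1": y[:-1], "year2": y[1:],
                              "n1": n[:-1], "n2": n[1:], "rate": r})
    return intervals, float(r.mean())


def wright_ne_delta_f(n_males: float, n_females: float) -> tuple[float, float]:
    """Wright's Ne for unequal sex ratios and dF% = 100 / (2 Ne)
    (undefined when Ne = 0)."""
    if n_males < 0 or n_females < 0:
        raise ValueError("breeding counts must be non-negative")
    total = n_males + n_females
    ne = 0.0 if total == 0 else 4.0 * n_males * n_females / total
    delta_f_pct = UNDEFINED if ne == 0 else 100.0 / (2.0 * ne)
    return ne, delta_f_pct


def _tier(value: float, cutoffs: dict, *, below: bool = False,
          at_least: bool = False) -> int:
    """Index into CATEGORIES of the worst category whose cutoff is violated."""
    for cat in ("C", "E", "V"):
        cut = cutoffs[cat]
        if at_least:
            hit = value >= cut
        elif below:
            hit = value < cut
        else:
            hit = value <= cut
        if hit:
            return CATEGORIES.index(cat)
    return 0  # NR


def classify_risk(breed: str, *, latest_animals: float = None,
                  n_females: float = None, n_males: float = None,
                  mean_growth: float = None, ne: float = None,
                  delta_f_pct: float = None,
                  thresholds: RiskThresholds | None = None) -> RiskAssessment:
    """Least-favourable-parameter FAO classification.

    Any subset of parameters may be supplied; at least one is required.
    ``latest_animals == 0`` forces Extinct regardless of the rest.
    """
    th = thresholds or RiskThresholds()
    scores: dict[str, int] = {}
    if latest_animals is not None and latest_animals == 0:
        return RiskAssessment(breed, mean_growth if mean_growth is not None
                              else UNDEFINED,
                              ne if ne is not None else UNDEFINED,
                              delta_f_pct if delta_f_pct is not None
                              else UNDEFINED, "Ex", "latest_animals")
    if n_females is not None:
        scores["breeding_females"] = _tier(n_females, th.females_max)
    if n_males is not None:
        scores["breeding_males"] = _tier(n_males, th.males_max)
    if latest_animals is not None:
        scores["total_size"] = _tier(latest_animals, th.total_max)
    if mean_growth is not None:
        scores["growth_rate"] = _tier(mean_growth, th.growth_below, below=True)
    if delta_f_pct is not None and not math.isnan(delta_f_pct):
        scores["delta_f"] = _tier(delta_f_pct, th.delta_f_pct_min,
                                  at_least=True)
    if not scores:
        raise ValueError(f"{breed}: no parameters available for classification")
    trigger = max(scores, key=lambda k: (scores[k], k))
    return RiskAssessment(
        breed,
        mean_growth if mean_growth is not None else UNDEFINED,
        ne if ne is not None else UNDEFINED,
        delta_f_pct if delta_f_pct is not None else UNDEFINED,
        CATEGORIES[scores[trigger]], trigger)


def assess_breed(census: pd.DataFrame, breed: str,
                 thresholds: RiskThresholds | None = None) -> RiskAssessment:
    """Full assessment of one breed from a long-format census table."""
    sub = census[census["breed"] == breed].sort_values("year")
    if sub.empty:
        raise ValueError(f"no census rows for breed {breed}")
    latest = sub.iloc[-1]
    try:
        _, mean_r = growth_rate(sub["year"].to_numpy(),
                                sub["n_animals"].to_numpy())
    except ValueError:
        mean_r = None
    ne, dfp = wright_ne_delta_f(latest["n_males"], latest["n_females"])
    return classify_risk(breed, latest_animals=float(latest["n_animals"]),
                         n_females=float(latest["n_females"]),
                         n_males=float(latest["n_males"]),
                         mean_growth=mean_r, ne=ne, delta_f_pct=dfp,
                         thresholds=thresholds)


def demography_report(census: pd.DataFrame,
                      thresholds: RiskThresholds | None = None
                      ) -> pd.DataFrame:
    """Per-breed summary table: counts, changes, growth, Ne, dF%, category."""
    rows = []
    for breed, sub in census.groupby("breed", sort=True):
        sub = sub.sort_values("year")
        first, latest = sub.iloc[0], sub.iloc[-1]
        a = assess_breed(census, breed, thresholds)
        rows.append({
            "breed": breed,
            "n_farms": latest["n_farms"],
            "pct_change_farms": round(percent_change(first["n_farms"],
                                                     latest["n_farms"]), 1),
            "n_animals": latest["n_animals"],
            "pct_change_animals": round(percent_change(first["n_animals"],
                                                       latest["n_animals"]), 1),
            "mean_growth_rate": round(a.mean_growth_rate, 2),
            "ne": round(a.ne),
            "delta_f_pct": round(a.delta_f_pct, 2),
            "risk": a.category,
            "trigger": a.triggering_parameter,
        })
    return pd.DataFrame(rows)
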