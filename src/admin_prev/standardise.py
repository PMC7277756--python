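"""Crude and age-standardised rates, SMRs, and Byar's approximation CIs.

Rates are computed on (age band, sex) strata with 5-year bands 0-4 ... 85+.
Direct standardisation weights the stratum-specific rates by a fixed
standard age structure; the shipped default is the 2013 European Standard
Population (with 85+ as the terminal band).  Indirect standardisation
applies reference stratum rates to a target population to get the expected
count, and the standardised morbidity ratio (SMR) is observed / expected.

All Poisson-count confidence intervals use Byar's cube-root normal
approximation, which tracks the exact chi-square-quantile limits to well
under 1% relative error for counts above ~10.  The CI of a directly
standardised rate uses the stratified-Poisson approximation: the weighted
sum of independent Poisson counts is treated as a scaled Poisson with
matching mean and variance, and Byar limits are applied to the equivalent
count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

AGE_BANDS = tuple(f"{5 * i}-{5 * i + 4}" for i in range(17)) + ("85+",)

#: 2013 European Standard Population, per 100,000, 85+ terminal band.
ESP2013 = {
    "0-4": 5000, "5-9": 5500, "10-14": 5500, "15-19": 5500,
    "20-24": 6000, "25-29": 6000, "30-34": 6500, "35-39": 7000,
    "40-44": 7000, "45-49": 7000, "50-54": 7000, "55-59": 6500,
    "60-64": 6000, "65-69": 5500, "70-74": 5000, "75-79": 4000,
    "80-84": 2500, "85+": 2500,
}
ESP2013_WEIGHTS = {band: v / 100_000 for band, v in ESP2013.items()}


@dataclass(frozen=True)
class RateResult:
    rate: float        # per 100,000
    ci_low: float
    ci_high: float
    cases: float
    population: float
    level: float = 0.95

    def as_dict(self) -> dict:
        return {
            "rate": self.rate, "ci": [self.ci_low, self.ci_high],
            "cases": self.cases, "population": self.population,
            "level": self.level,
        }


def byar_ci(d: float, level: float = 0.95) -> tuple[float, float]:
    """Byar's approximation to the exact Poisson CI for an observed count.

    lower = d (1 - 1/(9d) - z/(3 sqrt(d)))^3, 0 when d = 0;
    upper = (d+1) (1 - 1/(9(d+1)) + z/(3 sqrt(d+1)))^3.

    ``d`` may be non-integer (pooled or effective counts are real-valued).
    """
    if d < 0:
        raise ValueError("count must be >= 0")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = float(norm.ppf(1 - (1 - level) / 2))
    if d == 0:
        lower = 0.0
    else:
        lower = d * (1 - 1 / (9 * d) - z / (3 * np.sqrt(d))) ** 3
    dp = d + 1
    upper = dp * (1 - 1 / (9 * dp) + z / (3 * np.sqrt(dp))) ** 3
    return max(lower, 0.0), upper


def age_band(age: int) -> str:
    """5-year band label for an age in completed years."""
    if age < 0:
        raise ValueError("age must be >= 0")
    if age >= 85:
        return "85+"
    return AGE_BANDS[age // 5]


def age_from_birth_year(birth_year, prevalence_year: int = 2018):
    """Age in completed years on 1 January of ``prevalence_year`` (year
    arithmetic: only birth years are retained in the data)."""
    return prevalence_year - birth_year - 1


def _check_strata(strata: pd.DataFrame) -> pd.DataFrame:
    for col in ("age_band", "cases", "population"):
        if col not in strata.columns:
            raise ValueError(f"strata table lacks column {col!r}")
    if (strata["population"] < 0).any() or (strata["cases"] < 0).any():
        raise ValueError("cases and population must be >= 0")
    return strata


def crude_rate(strata: pd.DataFrame, level: float = 0.95) -> RateResult:
    """Total cases over total population, per 100,000, with Byar CI."""
    _check_strata(strata)
    cases = float(strata["cases"].sum())
    pop = float(strata["population"].sum())
    if pop <= 0:
        raise ValueError("total population must be positive")
    lo, hi = byar_ci(cases, level)
    scale = 1e5 / pop
    return RateResult(cases * scale, lo * scale, hi * scale, cases, pop, level)


def direct_standardised_rate(strata: pd.DataFrame,
                             weights: Mapping[str, float],
                             level: float = 0.95) -> RateResult:
    """Directly standardised rate per 100,000 with a stratified-Poisson CI.

    ``strata`` must have one row per age band (pre-aggregate over sex or
    area first); ``weights`` maps every band with non-zero weight to its
    standard-population share (normalised internally).  A band with zero
    population is allowed only if its weight is zero.
    """
    _check_strata(strata)
    s = strata.set_index("age_band")
    if s.index.duplicated().any():
        raise ValueError("strata must have one row per age band")
    w = pd.Series(weights, dtype=float)
    w = w / w.sum()
    missing = [b for b in w.index[w > 0] if b not in s.index]
    if missing:
        raise ValueError(f"strata missing bands required by weights: {missing}")
    s = s.reindex(w.index).fillna({"cases": 0.0, "population": 0.0})
    zero_pop = (s["population"] <= 0) & (w > 0)
    if zero_pop.any():
        raise ValueError(
            f"zero population in weighted bands: {list(s.index[zero_pop])}"
        )
    use = w > 0
    coeff = 1e5 * w[use] / s.loc[use, "population"]
    dsr = float((coeff * s.loc[use, "cases"]).sum())
    var = float((coeff**2 * s.loc[use, "cases"]).sum())
    if var <= 0 or dsr <= 0:
        # no cases: conservative upper bound from the largest stratum scale
        hi_c = byar_ci(0.0, level)[1] * (float(coeff.max()) if len(coeff) else 0.0)
        return RateResult(dsr, 0.0, hi_c,
                          float(s["cases"].sum()),
                          float(s["population"].sum()), level)
    d_eff = dsr**2 / var    # equivalent Poisson count with matching CV
    lo, hi = byar_ci(d_eff, level)
    scale = dsr / d_eff
    return RateResult(dsr, lo * scale, hi * scale,
                      float(s["cases"].sum()),
                      float(s["population"].sum()), level)


def expected_counts(reference_rates: Mapping[str, float],
                    target_strata: pd.DataFrame) -> float:
    """Indirect standardisation: sum of reference stratum rates (per person)
    times target stratum populations."""
    _check_strata(target_strata)
    missing = [
        b for b in target_strata["age_band"] if b not in reference_rates
    ]
    if missing:
        raise ValueError(f"reference rates missing bands: {sorted(set(missing))}")
    rates = target_strata["age_band"].map(reference_rates).astype(float)
    return float((rates * target_strata["population"]).sum())


def smr(observed: float, expected: float, level: float = 0.95
        ) -> tuple[float, tuple[float, float]]:
    """Standardised morbidity ratio observed/expected with Byar CI."""
    if expected <= 0:
        raise ValueError("expected count must be positive")
    if observed < 0:
        raise ValueError("observed count must be >= 0")
    lo, hi = byar_ci(observed, level)
    return observed / expected, (lo / expected, hi / expected)


def strata_rates(strata: pd.DataFrame) -> Mapping[str, float]:
    """Per-person stratum rates keyed by age band (for expected_counts)."""
    _check_strata(strata)
    s = strata.set_index("age_band")
    return (s["cases"] / s["population"]).to_dict()
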