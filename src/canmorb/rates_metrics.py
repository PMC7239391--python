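"""ESP-2013 age-standardisation and regional inequality statistics.

Direct standardisation: an age-standardised rate is the weighted mean of
age-specific rates under the European Standard Population 2013 weights,
restricted to the modelled age range and renormalised.  Regional
inequality in a year t is summarised by the absolute gap AD_t = HR_t - LR_t
and the relative gap RD_t = (HR_t - LR_t) / LR_t between the
highest-incidence and lowest-incidence regions; temporal change per region
by the percentage change RC_r = 100 (R_{t1,r} - R_{t0,r}) / R_{t0,r}.
When posterior draws are available, every statistic is computed per draw
(so the region attaining the extreme may vary across draws) and summarised
by its posterior mean, median and equal-tailed 95% interval.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .mcmc_inference import PosteriorDraws
from .registry_data import RegistrationTable

__all__ = [
    "ESP2013",
    "StandardisationWeights",
    "StandardisedRateSeries",
    "IntervalEstimate",
    "age_standardise",
    "absolute_difference",
    "relative_difference",
    "relative_change",
    "regional_differential",
    "inequality_summary",
    "published_rates_2016",
    "round_half_away",
]

#: European Standard Population 2013 (Eurostat), per 100,000, keyed by the
#: canonical five-year band labels; the open 85+ band pools ESP's 85-89,
#: 90-94 and 95+ groups (1500 + 800 + 200).
ESP2013_WEIGHTS: Mapping[str, float] = {
    "0": 1000,
    "1-4": 4000,
    "5-9": 5500,
    "10-14": 5500,
    "15-19": 5500,
    "20-24": 6000,
    "25-29": 6000,
    "30-34": 6500,
    "35-39": 7000,
    "40-44": 7000,
    "45-49": 7000,
    "50-54": 7000,
    "55-59": 6500,
    "60-64": 6000,
    "65-69": 5500,
    "70-74": 5000,
    "75-79": 4000,
    "80-84": 2500,
    "85+": 2500,
}


class StandardisationWeights:
    """Standard-population weights with restriction to a band subset."""

    def __init__(self, weights: Mapping[str, float]):
        if any(w < 0 for w in weights.values()):
            raise ValueError("weights must be non-negative")
        self.weights = dict(weights)

    def subtotal(self, bands: Sequence[str]) -> float:
        """Raw (pre-normalisation) weight total over a band subset."""
        self._check(bands)
        return float(sum(self.weights[b] for b in bands))

    def restricted(self, bands: Sequence[str]) -> np.ndarray:
        """Weights over ``bands`` renormalised to sum to 1."""
        self._check(bands)
        w = np.array([self.weights[b] for b in bands], dtype=float)
        return w / w.sum()

    def _check(self, bands: Sequence[str]) -> None:
        missing = [b for b in bands if b not in self.weights]
        if missing:
            raise KeyError(f"no standard-population weight for bands {missing}")


ESP2013 = StandardisationWeights(ESP2013_WEIGHTS)


def age_standardise(
    age_specific_rates: Mapping[str, float] | Sequence[float],
    weights: StandardisationWeights = ESP2013,
    bands: Sequence[str] | None = None,
) -> float:
    """Directly standardised rate: restricted-weight mean of per-band rates.

    Rates are taken on whatever scale they come in (conventionally per
    100,000) and the result stays on that scale.
    """
    if isinstance(age_specific_rates, Mapping):
        bands = list(age_specific_rates)
        r = np.array([age_specific_rates[b] for b in bands], dtype=float)
    else:
        if bands is None:
            raise ValueError("bands must accompany a rate sequence")
        r = np.asarray(age_specific_rates, dtype=float)
    w = weights.restricted(bands)
    return float(w @ r)


@dataclass(frozen=True)
class IntervalEstimate:
    """Point estimate with equal-tailed 95% credible interval (mean and
    median are both reported; the interval is None for point-only input)."""

    point: float
    lower: float | None = None
    upper: float | None = None
    median: float | None = None

    @classmethod
    def from_draws(cls, x: np.ndarray) -> "IntervalEstimate":
        lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
        return cls(point=float(np.mean(x)), lower=float(lo), upper=float(hi), median=float(med))


class StandardisedRateSeries:
    """Age-standardised rates per 100,000 by (region, gender, year).

    ``frame`` has one row per group with point/lower/upper; when built from
    posterior draws, ``draws`` holds the per-draw standardised rates column-
    aligned with ``frame`` rows, and all inequality statistics are computed
    draw-wise.
    """

    def __init__(self, frame: pd.DataFrame, draws: np.ndarray | None = None):
        self.frame = frame.reset_index(drop=True)
        self.draws = draws
        if draws is not None and draws.shape[1] != len(self.frame):
            raise ValueError("draw columns must align with frame rows")
        bad = self.frame["lower"].notna() & (
            (self.frame["lower"] > self.frame["point"])
            | (self.frame["point"] > self.frame["upper"])
        )
        if bad.any():
            raise ValueError("interval must bracket the point estimate")

    # -- constructors ---------------------------------------------------
    @classmethod
    def from_draws(
        cls,
        draws: PosteriorDraws,
        table: RegistrationTable,
        weights: StandardisationWeights = ESP2013,
        per: float = 1.0e5,
    ) -> "StandardisedRateSeries":
        """Standardise the latent rate draws of a fitted model.

        For each (region, gender, year) and each retained draw the age-
        specific latent rates theta are combined with the restricted,
        renormalised weights and scaled to per-100,000.
        """
        df = table.df
        rows = []
        cols = []
        for (region, gender, year), g in df.groupby(
            ["region", "gender", "year"], sort=True
        ):
            g = g.sort_values("age_mid")
            w = weights.restricted(list(g["age_band"]))
            asr = np.exp(draws.log_theta[:, g.index.to_numpy()]) @ w * per
            lo, med, hi = np.percentile(asr, [2.5, 50.0, 97.5])
            rows.append(
                {
                    "region": region,
                    "gender": gender,
                    "year": int(year),
                    "point": float(asr.mean()),
                    "lower": float(lo),
                    "upper": float(hi),
                }
            )
            cols.append(asr)
        return cls(pd.DataFrame(rows), np.column_stack(cols))

    @classmethod
    def from_point_rates(cls, rates: pd.DataFrame) -> "StandardisedRateSeries":
        """Wrap a table of point rates (columns region, year, rate and
        optionally gender) with no uncertainty attached."""
        df = rates.copy()
        if "gender" not in df.columns:
            df["gender"] = "all"
        if "year" not in df.columns:
            df["year"] = 0
        frame = pd.DataFrame(
            {
                "region": df["region"],
                "gender": df["gender"],
                "year": df["year"].astype(int),
                "point": df["rate"].astype(float),
                "lower": np.nan,
                "upper": np.nan,
            }
        )
        return cls(frame)

    # -- access ---------------------------------------------------------
    def _select(self, gender: str | None, year: int | None, region: str | None = None):
        mask = np.ones(len(self.frame), dtype=bool)
        if gender is not None:
            mask &= (self.frame["gender"] == gender).to_numpy()
        if year is not None:
            mask &= (self.frame["year"] == year).to_numpy()
        if region is not None:
            mask &= (self.frame["region"] == region).to_numpy()
        return np.nonzero(mask)[0]

    def rate_matrix(self, gender: str | None, year: int) -> tuple[list, np.ndarray]:
        """(regions, values) at a year: draw matrix (n_draws, n_regions) when
        draws exist, else the 1 x n_regions point row."""
        idx = self._select(gender, year)
        regions = list(self.frame.loc[idx, "region"])
        if len(set(regions)) != len(regions):
            raise ValueError("ambiguous selection: pass gender explicitly")
        if self.draws is not None:
            return regions, self.draws[:, idx]
        return regions, self.frame.loc[idx, "point"].to_numpy()[None, :]

    @property
    def years(self) -> list[int]:
        return sorted(self.frame["year"].unique())


def absolute_difference(
    series: StandardisedRateSeries, year: int, gender: str | None = None
) -> IntervalEstimate:
    """AD_t: gap between the highest- and lowest-incidence region in a year,
    computed per posterior draw (the extreme regions may differ by draw)."""
    regions, m = series.rate_matrix(gender, year)
    if len(regions) < 2:
        raise ValueError("absolute difference needs at least 2 regions")
    gaps = m.max(axis=1) - m.min(axis=1)
    return IntervalEstimate.from_draws(gaps) if gaps.size > 1 else IntervalEstimate(float(gaps[0]))


def relative_difference(
    series: StandardisedRateSeries, year: int, gender: str | None = None
) -> IntervalEstimate:
    """RD_t = (HR_t - LR_t) / LR_t, computed per draw."""
    regions, m = series.rate_matrix(gender, year)
    if len(regions) < 2:
        raise ValueError("relative difference needs at least 2 regions")
    lo = m.min(axis=1)
    if np.any(lo <= 0):
        raise ValueError("lowest regional rate must be positive")
    rel = (m.max(axis=1) - lo) / lo
    return IntervalEstimate.from_draws(rel) if rel.size > 1 else IntervalEstimate(float(rel[0]))


def relative_change(
    series: StandardisedRateSeries,
    region: str,
    gender: str | None = None,
    year0: int = 1981,
    year1: int = 2016,
) -> IntervalEstimate:
    """RC_r = 100 (R_{year1,r} - R_{year0,r}) / R_{year0,r}, per draw."""
    i0 = series._select(gender, year0, region)
    i1 = series._select(gender, year1, region)
    if len(i0) != 1 or len(i1) != 1:
        raise ValueError(f"need exactly one entry per year for {region}")
    if series.draws is not None:
        r0 = series.draws[:, i0[0]]
        r1 = series.draws[:, i1[0]]
    else:
        r0 = series.frame.loc[i0, "point"].to_numpy()
        r1 = series.frame.loc[i1, "point"].to_numpy()
    if np.any(r0 <= 0):
        raise ValueError("baseline rate must be positive")
    rc = 100.0 * (r1 - r0) / r0
    return IntervalEstimate.from_draws(rc) if rc.size > 1 else IntervalEstimate(float(rc[0]))


def regional_differential(
    draws: PosteriorDraws,
    table: RegistrationTable,
    age_mid: float,
    year: int,
    gender: str,
) -> pd.DataFrame:
    """Proportional differential of each region against the all-region
    average effect at a given age band, year and gender.

    Per draw: theta_r / geometric-mean over regions of theta - 1.  Under
    sum-to-zero region coding the average regional effect is exactly zero
    on the log scale, so a value of 0.05 reads as a region 5% above the
    average-region rate.  Returns one row per region with point estimate
    and 95% interval.
    """
    df = table.df
    mask = (
        (df["age_mid"] == age_mid) & (df["year"] == year) & (df["gender"] == gender)
    )
    sel = df[mask].sort_values("region")
    if sel.empty:
        raise ValueError(f"no cells at age {age_mid}, year {year}, {gender}")
    u = draws.log_theta[:, sel.index.to_numpy()]  # (n_draws, n_regions)
    diff = np.exp(u - u.mean(axis=1, keepdims=True)) - 1.0
    rows = []
    for k, region in enumerate(sel["region"]):
        est = IntervalEstimate.from_draws(diff[:, k])
        rows.append(
            {
                "region": region,
                "point": est.point,
                "lower": est.lower,
                "upper": est.upper,
            }
        )
    return pd.DataFrame(rows)


def inequality_summary(
    series: StandardisedRateSeries,
    gender: str | None = None,
    year0: int | None = None,
    year1: int | None = None,
) -> dict[str, pd.DataFrame]:
    """AD_t and RD_t for every year plus RC_r for every region.

    Returns ``{"by_year": ..., "by_region": ...}`` DataFrames with point
    estimates and 95% intervals (interval columns are NaN for point-only
    series).  RC uses the first and last observed years unless overridden.
    """
    years = series.years
    year0 = years[0] if year0 is None else year0
    year1 = years[-1] if year1 is None else year1
    by_year = []
    for t in years:
        ad = absolute_difference(series, t, gender)
        rd = relative_difference(series, t, gender)
        by_year.append(
            {
                "year": t,
                "AD": ad.point,
                "AD_lower": ad.lower,
                "AD_upper": ad.upper,
                "RD": rd.point,
                "RD_lower": rd.lower,
                "RD_upper": rd.upper,
            }
        )
    regions = sorted(series.frame["region"].unique())
    by_region = []
    if year0 != year1:
        for r in regions:
            rc = relative_change(series, r, gender, year0, year1)
            by_region.append(
                {
                    "region": r,
                    "RC": rc.point,
                    "RC_lower": rc.lower,
                    "RC_upper": rc.upper,
                }
            )
    return {"by_year": pd.DataFrame(by_year), "by_region": pd.DataFrame(by_region)}


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (the convention used for reported rates)."""
    factor = 10.0**ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def published_rates_2016() -> pd.DataFrame:
    """Published 2016 age-standardised incidence point rates per 100,000 for
    the nine English regions, by cancer type and gender (point estimates of
    a Bayesian registry analysis; bundled as plain CSV)."""
    ref = importlib.resources.files("canmorb.data").joinpath("england_asr_2016.csv")
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p)
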