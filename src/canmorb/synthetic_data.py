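"""Synthetic ONS-style registry generator with known ground truth.

Generates long-format registration tables over the 9 English regions x
1981-2016 x five-year age bands x genders, by simulating the same
hierarchy the fitting code assumes:

    log theta ~ Normal(X beta_true, sigma2_true),  C ~ Poisson(theta E)

so that every pipeline stage (design, MCMC, standardisation, metrics,
changepoint detection) can be exercised against recorded truth.  Default
effect sizes are chosen so age-standardised rates land in the few-hundred
per 100,000 range typical of site-specific cancer incidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .design_matrix import DesignMatrix, ModelSpec, SpecError, build_design
from .registry_data import (
    CANONICAL_REGIONS,
    MODELLING_AGE_START,
    SINGLE_GENDER_TYPES,
    RegistrationTable,
    canonical_bands,
)

__all__ = [
    "ExposureProfile",
    "GeneratorTruth",
    "default_truth",
    "generate_exposures",
    "simulate_registrations",
    "inject_break",
]

#: Mid-2010s mid-year population of the nine regions, millions (rounded;
#: used only as smooth relative scales for plausible exposures).
_REGION_POP_M: Mapping[str, float] = {
    "East": 6.1,
    "East Midlands": 4.7,
    "London": 8.8,
    "North East": 2.6,
    "North West": 7.2,
    "South East": 9.0,
    "South West": 5.5,
    "West Midlands": 5.8,
    "Yorkshire and the Humber": 5.4,
}

YEARS = tuple(range(1981, 2017))


@dataclass(frozen=True)
class ExposureProfile:
    """Smooth person-years model: region scale x age pyramid x annual growth
    x small lognormal jitter.  Bounds document the plausible cell range."""

    scale: float = 1.0
    annual_growth: float = 1.004
    jitter_sd: float = 0.02
    bounds: tuple[float, float] = (1.0e4, 1.5e6)

    def __post_init__(self):
        if self.scale <= 0:
            raise ValueError("exposure scale must be positive")


def _age_fraction(midpoint: float) -> float:
    """Fraction of a region's population in one five-year band (smooth,
    tapering after age 70 like a real pyramid)."""
    if midpoint < 70:
        return 0.062
    return 0.055 * float(np.exp(-(midpoint - 70.0) / 18.0))


def generate_exposures(
    profile: ExposureProfile,
    seed: int,
    *,
    regions=CANONICAL_REGIONS,
    years=YEARS,
    bands=None,
    genders=("male", "female"),
) -> pd.DataFrame:
    """Deterministic (given seed) grid of person-years exposures."""
    if bands is None:
        bands = canonical_bands()
    rng = np.random.default_rng(seed)
    rows = []
    for region in regions:
        base = _REGION_POP_M[region] * 1.0e6 * profile.scale
        for band in bands:
            frac = _age_fraction(band.midpoint)
            for gender in genders:
                gfrac = 0.49 if gender == "male" else 0.51
                for year in years:
                    growth = profile.annual_growth ** (year - 1998)
                    rows.append(
                        {
                            "age_band": band.label,
                            "age_mid": band.midpoint,
                            "year": year,
                            "gender": gender,
                            "region": region,
                            "exposure": base * frac * gfrac * growth,
                        }
                    )
    df = pd.DataFrame(rows)
    jitter = np.exp(rng.normal(0.0, profile.jitter_sd, size=len(df)))
    df["exposure"] = df["exposure"] * jitter
    return df


@dataclass(frozen=True)
class GeneratorTruth:
    """Everything needed to regenerate a synthetic table bit-for-bit.

    ``beta`` maps design-column labels to true coefficients; labels absent
    from the design are ignored and design columns absent from the map get
    coefficient zero, so one truth can serve nested model specs.
    """

    spec: ModelSpec
    beta: Mapping[str, float]
    sigma2: float
    seed: int
    profile: ExposureProfile = field(default_factory=ExposureProfile)
    years: tuple[int, ...] = YEARS
    full_age_ladder: bool = False

    def beta_vector(self, design: DesignMatrix) -> np.ndarray:
        return np.array([self.beta.get(c, 0.0) for c in design.columns])


#: Region deviations (sum-to-zero over the 9 regions is enforced by the
#: contrast coding: the 9th effect is minus the sum of these 8).
_DEFAULT_REGION_EFFECTS = {
    "region[East]": -0.10,
    "region[East Midlands]": -0.03,
    "region[London]": -0.08,
    "region[North East]": 0.18,
    "region[North West]": 0.12,
    "region[South East]": -0.09,
    "region[South West]": -0.05,
    "region[West Midlands]": 0.02,
}


def default_truth(cancer_type: str = "lung", seed: int = 20160101) -> GeneratorTruth:
    """Packaged default truth: a lung-like quadratic age/year surface with
    gender and fixed region effects and modest overdispersion."""
    spec = ModelSpec(
        cancer_type=cancer_type,
        max_age_power=2,
        max_year_power=1,
        interactions=("age:year",),
    )
    beta = {
        "intercept": np.log(150e-5),
        "age^1": 0.85,
        "age^2": -0.22,
        "year^1": 0.15,
        "gender[male]": 0.22,
        "age^1:year^1": 0.06,
        **_DEFAULT_REGION_EFFECTS,
    }
    return GeneratorTruth(spec=spec, beta=beta, sigma2=0.02, seed=seed)


def _grid_table(truth: GeneratorTruth) -> RegistrationTable:
    start = MODELLING_AGE_START[truth.spec.cancer_type]
    bands = canonical_bands()
    if not truth.full_age_ladder:
        bands = [b for b in bands if b.midpoint >= start]
    single = SINGLE_GENDER_TYPES.get(truth.spec.cancer_type)
    genders = (single,) if single else ("male", "female")
    df = generate_exposures(
        truth.profile, truth.seed, years=truth.years, bands=bands, genders=genders
    )
    lo, hi = truth.profile.bounds
    if df["exposure"].min() < lo or df["exposure"].max() > hi:
        raise ValueError("generated exposures fall outside the configured bounds")
    df["count"] = 0
    return RegistrationTable(df, cancer_type=truth.spec.cancer_type, validate=False)


def simulate_registrations(
    truth: GeneratorTruth,
) -> tuple[RegistrationTable, DesignMatrix, np.ndarray]:
    """Draw a registration table from the truth.

    Returns (table, design, true_log_theta); the design is the one implied
    by truth.spec on the generated grid, so recovery tests can compare
    fitted coefficients directly against ``truth.beta_vector(design)``.
    """
    table = _grid_table(truth)
    design = build_design(truth.spec, table)
    beta = truth.beta_vector(design)
    mu = design.X @ beta
    rng = np.random.default_rng(truth.seed + 1)
    log_theta = mu + np.sqrt(truth.sigma2) * rng.standard_normal(mu.size) if truth.sigma2 > 0 else mu.copy()
    lam = np.exp(log_theta) * table.exposures
    if np.any(lam > 1e12):
        raise ValueError("true rates imply astronomically large Poisson means")
    counts = rng.poisson(lam)
    df = table.df.copy()
    df["count"] = counts
    out = RegistrationTable(df, cancer_type=truth.spec.cancer_type, validate=False)
    return out, design, log_theta


def inject_break(
    truth: GeneratorTruth,
    variable: str,
    threshold: float,
    log_step: float,
    log_slope: float = 0.0,
) -> GeneratorTruth:
    """Add a level shift and/or trend change at ``threshold`` to the truth.

    ``log_step`` is the jump of log theta at the threshold (exp(log_step) is
    the multiplicative level shift); ``log_slope`` is the extra slope per
    standardised unit of the variable beyond the threshold.
    """
    if variable == "year":
        vmin, vmax = min(truth.years), max(truth.years)
    elif variable == "age":
        vmin, vmax = 0.0, 90.0
    else:
        raise SpecError(f"changepoint variable must be age or year: {variable}")
    if not (vmin <= threshold <= vmax):
        raise SpecError(f"threshold {threshold} outside range [{vmin}, {vmax}]")
    cps = truth.spec.changepoints
    if (variable, threshold) not in cps:
        cps = cps + ((variable, threshold),)
    spec = replace(truth.spec, changepoints=cps)
    beta = dict(truth.beta)
    beta[f"{variable}>={threshold:g}"] = beta.get(f"{variable}>={threshold:g}", 0.0) + log_step
    beta[f"{variable}_hinge_{threshold:g}"] = (
        beta.get(f"{variable}_hinge_{threshold:g}", 0.0) + log_slope
    )
    return replace(truth, spec=spec, beta=beta)
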