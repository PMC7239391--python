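"""Covariate coding: standardisation, sum-to-zero contrasts, polynomial and
changepoint terms, and the per-cancer-type model catalogue.

The linear predictor is mu = X beta where X holds an intercept, polynomial
terms in standardised age and year (or 14 sum-to-zero age contrasts for
all-cancer, where age is categorical with 15 levels), gender and region
contrasts, the catalogued interactions, and step + hinge changepoint terms.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np

from .registry_data import RegistrationTable, SINGLE_GENDER_TYPES

__all__ = [
    "ModelSpec",
    "DesignMatrix",
    "SpecError",
    "standardise_numeric",
    "sum_to_zero_contrasts",
    "changepoint_terms",
    "build_design",
    "spec_catalogue",
    "default_spec",
]

VALID_INTERACTIONS = (
    "age:year",
    "age:gender",
    "age:region",
    "gender:year",
    "gender:region",
    "region:year",
)


class SpecError(ValueError):
    """Model specification inconsistent with the data or with itself."""


@dataclass(frozen=True)
class ModelSpec:
    """Covariate/interaction/changepoint configuration for one cancer type.

    ``changepoints`` is a list of (variable, threshold) pairs, e.g.
    ``("year", 2006)`` or ``("age", 50)``; each adds a step indicator
    I(v >= threshold) and a hinge (v - threshold) * I(v >= threshold).
    ``interaction_power`` raises the numeric terms used inside interaction
    products (1 = linear, the default).
    """

    cancer_type: str = "all"
    age_mode: str = "numeric"  # "numeric" | "categorical"
    max_age_power: int = 1
    max_year_power: int = 1
    interactions: tuple[str, ...] = ()
    changepoints: tuple[tuple[str, float], ...] = ()
    interaction_power: int = 1

    def __post_init__(self):
        bad = [i for i in self.interactions if i not in VALID_INTERACTIONS]
        if bad:
            raise SpecError(f"unknown interactions: {bad}")
        single = SINGLE_GENDER_TYPES.get(self.cancer_type)
        if single is not None:
            with_gender = [i for i in self.interactions if "gender" in i]
            if with_gender:
                raise SpecError(
                    f"{self.cancer_type} is single-gender; drop {with_gender}"
                )
        for var, _ in self.changepoints:
            if var not in ("age", "year"):
                raise SpecError(f"changepoint variable must be age or year: {var}")

    def without(self, *interactions: str) -> "ModelSpec":
        return replace(
            self,
            interactions=tuple(i for i in self.interactions if i not in interactions),
        )


_ALL_INTERACTIONS = VALID_INTERACTIONS


def spec_catalogue() -> dict[str, ModelSpec]:
    """Best-fit model structure per cancer type.

    All main effects always enter; the table records the highest age/year
    powers, which pairwise interactions are included, and the screening-era
    changepoints (bowel 2006; breast 1989 and age 50).
    """
    return {
        "all": ModelSpec(
            cancer_type="all",
            age_mode="categorical",
            max_age_power=1,
            max_year_power=1,
            interactions=_ALL_INTERACTIONS,
        ),
        "lung": ModelSpec(
            cancer_type="lung",
            max_age_power=2,
            max_year_power=2,
            interactions=_ALL_INTERACTIONS,
        ),
        "bowel": ModelSpec(
            cancer_type="bowel",
            max_age_power=2,
            max_year_power=2,
            interactions=_ALL_INTERACTIONS,
            changepoints=(("year", 2006),),
        ),
        "prostate": ModelSpec(
            cancer_type="prostate",
            max_age_power=3,
            max_year_power=3,
            interactions=("age:year", "age:region", "region:year"),
        ),
        "breast": ModelSpec(
            cancer_type="breast",
            max_age_power=3,
            max_year_power=2,
            interactions=("age:year", "age:region"),
            changepoints=(("year", 1989), ("age", 50)),
        ),
    }


def default_spec(cancer_type: str) -> ModelSpec:
    return spec_catalogue()[cancer_type]


def standardise_numeric(values: Sequence[float]) -> tuple[np.ndarray, float, float]:
    """Centre and scale to zero mean, unit variance; returns (scaled, mean, sd).

    The sd uses ddof=0 so the output variance is exactly 1.  The constants
    are retained on the design so new grids can be coded identically.
    """
    v = np.asarray(values, dtype=float)
    mean = float(v.mean())
    sd = float(v.std(ddof=0))
    if sd == 0.0:
        raise SpecError("cannot standardise a constant covariate")
    return (v - mean) / sd, mean, sd


def sum_to_zero_contrasts(levels: Sequence) -> np.ndarray:
    """Sum-coding contrast matrix: L levels -> (L, L-1).

    Row i < L-1 is the indicator of level i; the last row is all -1, so the
    implied full-level effects C @ gamma always sum to zero and the implicit
    reference is the average level.
    """
    L = len(levels)
    if L < 2:
        raise SpecError("need at least 2 levels for contrasts")
    C = np.vstack([np.eye(L - 1), -np.ones(L - 1)])
    return C


def changepoint_terms(
    values: np.ndarray, threshold: float, sd: float = 1.0
) -> tuple[np.ndarray, np.ndarray]:
    """Step and hinge columns for a break at ``threshold``.

    The indicator is I(v >= threshold) on the raw scale; the hinge
    (v - threshold) * I(...) is expressed in standardised units so its
    coefficient is commensurate with the polynomial terms.  The hinge is 0
    at the threshold, making the fitted curve continuous there unless the
    step coefficient is nonzero.
    """
    v = np.asarray(values, dtype=float)
    if not (v.min() <= threshold <= v.max()):
        raise SpecError(
            f"changepoint threshold {threshold} outside observed range "
            f"[{v.min()}, {v.max()}]"
        )
    step = (v >= threshold).astype(float)
    hinge = (v - threshold) / sd * step
    return step, hinge


@dataclass
class DesignMatrix:
    """Design matrix aligned row-for-row with a RegistrationTable.

    ``scalers`` holds (mean, sd) per numeric covariate and ``contrasts`` the
    (levels, contrast matrix) per categorical covariate, so effects on the
    original level scale can be reconstructed and new data coded identically.
    """

    X: np.ndarray
    columns: list[str]
    scalers: dict[str, tuple[float, float]]
    contrasts: dict[str, tuple[list, np.ndarray]]
    spec: ModelSpec

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def column_index(self, label: str) -> int:
        return self.columns.index(label)

    def block(self, prefix: str) -> list[int]:
        """Indices of the main-effect block for a categorical covariate."""
        return [
            j
            for j, c in enumerate(self.columns)
            if c.startswith(prefix + "[") and ":" not in c
        ]

    def categorical_effects(self, beta: np.ndarray, covariate: str) -> np.ndarray:
        """Full-level effects (length L, summing to zero) of a categorical block."""
        if covariate not in self.contrasts:
            raise SpecError(f"no categorical block for {covariate!r}")
        _, C = self.contrasts[covariate]
        idx = self.block(covariate)
        gamma = np.asarray(beta)[..., idx]
        return gamma @ C.T

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.X, columns=self.columns)


def _main_effect_columns(
    spec: ModelSpec, table: RegistrationTable
) -> tuple[dict[str, list[tuple[str, np.ndarray]]], dict, dict]:
    """Build per-covariate column lists plus scaler/contrast records."""
    df = table.df
    scalers: dict[str, tuple[float, float]] = {}
    contrasts: dict[str, tuple[list, np.ndarray]] = {}
    blocks: dict[str, list[tuple[str, np.ndarray]]] = {}

    # age
    if spec.age_mode == "categorical":
        levels = sorted(df["age_mid"].unique())
        C = sum_to_zero_contrasts(levels)
        codes = np.searchsorted(levels, df["age_mid"].to_numpy())
        cols = C[codes]
        blocks["age"] = [
            (f"age[{levels[k]:g}]", cols[:, k]) for k in range(len(levels) - 1)
        ]
        contrasts["age"] = (levels, C)
    else:
        z, m, s = standardise_numeric(df["age_mid"].to_numpy())
        scalers["age"] = (m, s)
        blocks["age"] = [(f"age^{p}", z**p) for p in range(1, spec.max_age_power + 1)]

    # year
    zy, my, sy = standardise_numeric(df["year"].to_numpy())
    scalers["year"] = (my, sy)
    blocks["year"] = [(f"year^{p}", zy**p) for p in range(1, spec.max_year_power + 1)]

    # gender (absent for single-gender types)
    genders = table.genders
    if SINGLE_GENDER_TYPES.get(spec.cancer_type) is None:
        if len(genders) < 2:
            raise SpecError(
                f"{spec.cancer_type} model expects both genders; table has {genders}"
            )
        C = sum_to_zero_contrasts(genders)
        codes = np.array([genders.index(g) for g in df["gender"]])
        cols = C[codes]
        blocks["gender"] = [(f"gender[{genders[0]}]", cols[:, 0])]
        contrasts["gender"] = (genders, C)

    # region
    regions = table.regions
    C = sum_to_zero_contrasts(regions)
    codes = np.array([regions.index(r) for r in df["region"]])
    cols = C[codes]
    blocks["region"] = [
        (f"region[{regions[k]}]", cols[:, k]) for k in range(len(regions) - 1)
    ]
    contrasts["region"] = (regions, C)

    return blocks, scalers, contrasts


def _interaction_basis(
    name: str,
    blocks: Mapping[str, list[tuple[str, np.ndarray]]],
    spec: ModelSpec,
) -> list[tuple[str, np.ndarray]]:
    """Columns entering an interaction for one covariate.

    Numeric covariates contribute standardised powers up to
    ``spec.interaction_power``; categorical covariates contribute their full
    contrast block.
    """
    cols = blocks[name]
    if cols and cols[0][0].endswith("^1"):  # numeric block
        return cols[: spec.interaction_power]
    return cols


def build_design(spec: ModelSpec, table: RegistrationTable) -> DesignMatrix:
    """Assemble the design matrix for ``table`` under ``spec``.

    Column order: intercept, age block, year block, gender, region,
    changepoint terms, then interactions in catalogue order.  The
    construction is deterministic: identical (spec, table) inputs give
    byte-identical columns.
    """
    df = table.df
    blocks, scalers, contrasts = _main_effect_columns(spec, table)

    named: list[tuple[str, np.ndarray]] = [("intercept", np.ones(len(df)))]
    for key in ("age", "year", "gender", "region"):
        named.extend(blocks.get(key, []))

    for var, thr in spec.changepoints:
        raw = df["age_mid"].to_numpy() if var == "age" else df["year"].to_numpy(float)
        if var in scalers:
            _, sd = scalers[var]
        else:
            sd = float(raw.std(ddof=0)) or 1.0
        step, hinge = changepoint_terms(raw, thr, sd)
        named.append((f"{var}>={thr:g}", step))
        named.append((f"{var}_hinge_{thr:g}", hinge))

    for inter in VALID_INTERACTIONS:
        if inter not in spec.interactions:
            continue
        a, b = inter.split(":")
        for part in (a, b):
            if part not in blocks:
                raise SpecError(
                    f"interaction {inter!r} references covariate {part!r} "
                    f"absent from the {spec.cancer_type} model"
                )
        for la, ca in _interaction_basis(a, blocks, spec):
            for lb, cb in _interaction_basis(b, blocks, spec):
                named.append((f"{la}:{lb}", ca * cb))

    labels = [n for n, _ in named]
    if len(set(labels)) != len(labels):  # defensive; labels are deterministic
        raise SpecError("duplicate design column labels")
    X = np.column_stack([c for _, c in named])
    return DesignMatrix(X=X, columns=labels, scalers=scalers, contrasts=contrasts, spec=spec)
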