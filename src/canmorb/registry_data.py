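"""Data model and I/O for ONS-style cancer registration tables.

Registration counts and mid-year population exposures are held in long
format, one row per (age band, calendar year, gender, region) cell.  Age
enters all downstream modelling as the midpoint of its five-year band,
with the open 85+ band assigned midpoint 90.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AgeBand",
    "RegistrationTable",
    "CANONICAL_REGIONS",
    "CANCER_TYPES",
    "GENDERS",
    "canonical_bands",
    "band_midpoint",
    "parse_age_band",
    "load_registrations",
    "write_registrations",
    "filter_age_range",
    "SchemaError",
    "ValidationError",
]

#: The nine NUTS-1 English regions, alphabetical so contrast coding is stable.
CANONICAL_REGIONS: tuple[str, ...] = (
    "East",
    "East Midlands",
    "London",
    "North East",
    "North West",
    "South East",
    "South West",
    "West Midlands",
    "Yorkshire and the Humber",
)

GENDERS: tuple[str, ...] = ("male", "female")

#: Supported cancer groupings; prostate is male-only, breast female-only.
CANCER_TYPES: tuple[str, ...] = ("all", "lung", "bowel", "prostate", "breast")

#: Minimum band midpoint retained for modelling, by cancer type.  All-cancer
#: and breast are modelled from the 15-19 band (midpoint 17); lung, bowel and
#: prostate from the 45-49 band (midpoint 47).
MODELLING_AGE_START: Mapping[str, float] = {
    "all": 17.0,
    "breast": 17.0,
    "lung": 47.0,
    "bowel": 47.0,
    "prostate": 47.0,
}

SINGLE_GENDER_TYPES: Mapping[str, str] = {"prostate": "male", "breast": "female"}

#: Column names of the canonical long-format table.
COLUMNS = ("age_band", "year", "gender", "region", "count", "exposure")


class SchemaError(ValueError):
    """A required column is missing or an unknown label was encountered."""


class ValidationError(ValueError):
    """A cell violates a table invariant; the message names the cell key."""


@dataclass(frozen=True, order=True)
class AgeBand:
    """A five-year age band, or the open 85+ band.

    ``upper`` is ``None`` for the open band.  The midpoint of a closed
    five-year band [lower, lower+4] is lower + 2; the bands 0 and 1-4 get
    their arithmetic midpoints 0.5 and 2.5 (they only occur before the
    modelling-age filter); the open 85+ band is assigned midpoint 90.
    """

    lower: int
    upper: int | None = None

    @property
    def midpoint(self) -> float:
        if self.upper is None:
            return 90.0
        if self.lower == 0 and self.upper == 0:
            return 0.5
        if self.lower == 1 and self.upper == 4:
            return 2.5
        return float(self.lower + 2)

    @property
    def label(self) -> str:
        if self.upper is None:
            return f"{self.lower}+"
        if self.lower == self.upper:
            return str(self.lower)
        return f"{self.lower}-{self.upper}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


_BAND_RE = re.compile(r"^\s*(\d+)\s*(?:[-–]\s*(\d+)|\+)?\s*$")


def canonical_bands() -> list[AgeBand]:
    """The canonical band ladder 0, 1-4, 5-9, ..., 80-84, 85+."""
    bands = [AgeBand(0, 0), AgeBand(1, 4)]
    bands += [AgeBand(lo, lo + 4) for lo in range(5, 85, 5)]
    bands.append(AgeBand(85, None))
    return bands


_CANONICAL_LABELS = {b.label: b for b in canonical_bands()}


def parse_age_band(label: str) -> AgeBand:
    """Parse an age-band label such as ``"15-19"``, ``"85+"`` or ``"0"``."""
    m = _BAND_RE.match(str(label))
    if not m:
        raise SchemaError(f"unparseable age band label: {label!r}")
    lower = int(m.group(1))
    if m.group(2) is not None:
        band = AgeBand(lower, int(m.group(2)))
    elif str(label).strip().endswith("+"):
        band = AgeBand(lower, None)
    else:
        band = AgeBand(lower, lower)
    if band.label not in _CANONICAL_LABELS:
        raise SchemaError(f"non-canonical age band: {label!r}")
    return band


def band_midpoint(band: AgeBand | str) -> float:
    """Midpoint in years of a canonical band (``"15-19"`` -> 17, ``"85+"`` -> 90)."""
    if isinstance(band, str):
        band = parse_age_band(band)
    return band.midpoint


class RegistrationTable:
    """Long-format registration/population table for one cancer grouping.

    Wraps a :class:`pandas.DataFrame` with columns ``age_band`` (label),
    ``age_mid``, ``year``, ``gender``, ``region``, ``count``, ``exposure``;
    the tuple (age_band, year, gender, region) is a unique key.
    """

    def __init__(self, df: pd.DataFrame, cancer_type: str = "all", *, validate: bool = True):
        if cancer_type not in CANCER_TYPES:
            raise SchemaError(f"unknown cancer type: {cancer_type!r}")
        df = df.copy()
        if "age_mid" not in df.columns:
            df["age_mid"] = [band_midpoint(b) for b in df["age_band"]]
        df["year"] = df["year"].astype(int)
        df["count"] = df["count"].astype(int)
        df["exposure"] = df["exposure"].astype(float)
        self.df = df.reset_index(drop=True)
        self.cancer_type = cancer_type
        if validate:
            self.validate()

    # -- invariants -----------------------------------------------------
    def validate(self) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise SchemaError(f"missing columns: {missing}")
        bad_gender = set(df["gender"]) - set(GENDERS)
        if bad_gender:
            raise ValidationError(f"unknown gender labels: {sorted(bad_gender)}")
        bad_region = set(df["region"]) - set(CANONICAL_REGIONS)
        if bad_region:
            raise ValidationError(f"unknown regions: {sorted(bad_region)}")
        only = SINGLE_GENDER_TYPES.get(self.cancer_type)
        if only is not None and (df["gender"] != only).any():
            raise ValidationError(
                f"{self.cancer_type} tables must be {only}-only"
            )
        neg = df[df["count"] < 0]
        if len(neg):
            raise ValidationError(f"negative count at {self._key(neg.iloc[0])}")
        nonpos = df[df["exposure"] <= 0]
        if len(nonpos):
            raise ValidationError(f"non-positive exposure at {self._key(nonpos.iloc[0])}")
        dup = df.duplicated(subset=["age_band", "year", "gender", "region"])
        if dup.any():
            raise ValidationError(f"duplicate cell key {self._key(df[dup].iloc[0])}")

    @staticmethod
    def _key(row: pd.Series) -> tuple:
        return (row["age_band"], int(row["year"]), row["gender"], row["region"])

    # -- conveniences ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def counts(self):
        return self.df["count"].to_numpy()

    @property
    def exposures(self):
        return self.df["exposure"].to_numpy(dtype=float)

    @property
    def years(self) -> list[int]:
        return sorted(self.df["year"].unique())

    @property
    def midpoints(self) -> list[float]:
        return sorted(self.df["age_mid"].unique())

    @property
    def regions(self) -> list[str]:
        return [r for r in CANONICAL_REGIONS if r in set(self.df["region"])]

    @property
    def genders(self) -> list[str]:
        return [g for g in GENDERS if g in set(self.df["gender"])]

    def total_count(self) -> int:
        return int(self.df["count"].sum())


DEFAULT_SCHEMA: Mapping[str, str] = {c: c for c in COLUMNS}


def load_registrations(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
    cancer_type: str = "all",
) -> RegistrationTable:
    """Load a UTF-8 CSV of registration cells.

    ``schema`` maps canonical column names (``age_band``, ``year``, ``gender``,
    ``region``, ``count``, ``exposure``) to the column names used in the file;
    omitted entries default to the canonical name.
    """
    mapping = dict(DEFAULT_SCHEMA)
    if schema:
        mapping.update(schema)
    raw = pd.read_csv(path, dtype={mapping["age_band"]: str})
    missing = [src for src in mapping.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"missing columns in {path}: {missing}")
    df = pd.DataFrame({canon: raw[src] for canon, src in mapping.items()})
    df["gender"] = df["gender"].map(_normalise_gender)
    # parse bands up-front so bad labels fail loudly with the offending label
    df["age_mid"] = [band_midpoint(b) for b in df["age_band"]]
    df["age_band"] = [parse_age_band(b).label for b in df["age_band"]]
    return RegistrationTable(df, cancer_type=cancer_type)


def _normalise_gender(g: str) -> str:
    g = str(g).strip().lower()
    if g in ("m", "male"):
        return "male"
    if g in ("f", "female"):
        return "female"
    return g  # caught by validate()


def write_registrations(table: RegistrationTable, path: str | Path) -> None:
    """Write the canonical long-format CSV (round-trips bit-exactly)."""
    table.df[list(COLUMNS)].to_csv(path, index=False)


def filter_age_range(table: RegistrationTable) -> RegistrationTable:
    """Restrict to the modelling age range for the table's cancer type.

    Bands below the start age are dropped (not aggregated): all-cancer and
    breast keep midpoints >= 17, the other site-specific types >= 47.
    """
    start = MODELLING_AGE_START[table.cancer_type]
    kept = table.df[table.df["age_mid"] >= start]
    if kept.empty:
        raise ValidationError(
            f"no modellable cells: all bands below midpoint {start}"
        )
    return RegistrationTable(kept, cancer_type=table.cancer_type, validate=False)


def from_cells(
    cells: Iterable[Mapping], cancer_type: str = "all"
) -> RegistrationTable:
    """Build a table from an iterable of dict-like cells (mainly for tests)."""
    return RegistrationTable(pd.DataFrame(list(cells)), cancer_type=cancer_type)
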