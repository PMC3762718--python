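"""Camera-trap tables to detection matrices.

Raw inputs are three CSV tables: detection events (``species_id, site_id,
date``), camera deployments (``site_id, start_date, end_date``, inclusive)
and per-site covariates.  They are condensed, per species and per year, into
a sites × days presence/absence matrix whose cells are 1 (photographed),
0 (sampled, not photographed) or NA (camera not active that day), and then
collapsed into a small number of equal-as-possible contiguous time periods
(15 by default, roughly a week each for a 30-day deployment) that the
occupancy models consume as repeat visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DailyDetectionMatrix",
    "PeriodDetectionMatrix",
    "StandardizedCovariates",
    "read_events",
    "read_deployments",
    "read_covariates",
    "read_species_attributes",
    "build_daily_matrix",
    "collapse_to_periods",
    "pool_species",
    "standardize_covariates",
    "events_from_daily",
    "detection_stack",
]

#: integer codes used in the dense int8 representation
NA = -1

GUILDS = ("carnivore", "large_herbivore", "small_herbivore", "omnivore", "insectivore")

#: body-mass threshold (kg) separating large from small herbivores
HERBIVORE_MASS_SPLIT_KG = 20.0


@dataclass
class _DetectionMatrix:
    """Sites × columns ternary matrix; values is float with NaN = not sampled."""

    species_id: str
    year: int
    values: pd.DataFrame  # index: site_id; cells in {0.0, 1.0, NaN}

    @property
    def site_ids(self) -> list[str]:
        return list(self.values.index)

    def to_array(self) -> np.ndarray:
        """Dense int8 with -1 for NA."""
        arr = self.values.to_numpy(dtype=float)
        out = np.where(np.isnan(arr), NA, arr).astype(np.int8)
        return out

    def n_sampled(self) -> int:
        return int(self.values.notna().to_numpy().sum())

    def to_csv(self, path) -> None:
        self.values.to_csv(path, na_rep="NA", index_label="site_id")

    @classmethod
    def from_csv(cls, path, species_id: str, year: int):
        df = pd.read_csv(path, index_col="site_id", na_values=["NA"], comment="#")
        df.index = df.index.astype(str)
        return cls(species_id=species_id, year=year, values=df)

    def __eq__(self, other) -> bool:  # cell-exact, NA-aware
        if not isinstance(other, _DetectionMatrix):
            return NotImplemented
        if self.values.shape != other.values.shape:
            return False
        a, b = self.values.to_numpy(float), other.values.to_numpy(float)
        return bool(np.array_equal(a, b, equal_nan=True))


class DailyDetectionMatrix(_DetectionMatrix):
    """One row per sampling point, one column per calendar day of the season."""


class PeriodDetectionMatrix(_DetectionMatrix):
    """Daily matrix collapsed to ``n_periods`` contiguous blocks of days."""

    @property
    def n_periods(self) -> int:
        return self.values.shape[1]


@dataclass
class StandardizedCovariates:
    """Numeric covariates scaled to mean 0 / sd 1, categoricals one-hot expanded.

    ``means``/``sds`` keep the scaling constants so coefficients can be
    back-transformed to natural units; ``reference_levels`` names the dropped
    (first alphabetical) level of each categorical column.
    """

    values: pd.DataFrame
    means: pd.Series
    sds: pd.Series
    reference_levels: dict[str, str] = field(default_factory=dict)

    def design_matrix(self, columns: tuple[str, ...]) -> np.ndarray:
        """Intercept + the named standardized columns, one row per site."""
        n = len(self.values)
        cols = [np.ones(n)]
        for c in columns:
            if c not in self.values.columns:
                raise KeyError(f"unknown covariate {c!r}")
            cols.append(self.values[c].to_numpy(float))
        return np.column_stack(cols)


# ---------------------------------------------------------------------------
# readers

def read_events(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"species_id": str, "site_id": str})
    df["date"] = pd.to_datetime(df["date"]).dt.normalize()
    return df[["species_id", "site_id", "date"]]


def read_deployments(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"site_id": str})
    for c in ("start_date", "end_date"):
        df[c] = pd.to_datetime(df[c]).dt.normalize()
    _validate_deployments(df)
    return df[["site_id", "start_date", "end_date"]]


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"site_id": str}).set_index("site_id")
    num = df.select_dtypes(include="number")
    if not np.isfinite(num.to_numpy(float)).all():
        raise ValueError("covariate table contains non-finite numeric values")
    return df


def read_species_attributes(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"species_id": str}).set_index("species_id")
    bad = set(df["guild"]) - set(GUILDS)
    if bad:
        raise ValueError(f"unknown guild(s): {sorted(bad)}")
    if df["hunted"].dtype != bool:
        df["hunted"] = df["hunted"].astype(str).str.lower().isin(("true", "1", "yes"))
    return df


def _validate_deployments(dep: pd.DataFrame) -> None:
    if (dep["start_date"] > dep["end_date"]).any():
        bad = dep.loc[dep["start_date"] > dep["end_date"], "site_id"].iloc[0]
        raise ValueError(f"deployment for site {bad!r} has start after end")
    # overlapping intervals at the same site within a year are a data error
    for (site, _), grp in dep.groupby([dep["site_id"], dep["start_date"].dt.year]):
        g = grp.sort_values("start_date")
        if (g["start_date"].iloc[1:].to_numpy() <= g["end_date"].iloc[:-1].to_numpy()).any():
            raise ValueError(f"overlapping deployment intervals for site {site!r}")


# ---------------------------------------------------------------------------
# matrix construction

def build_daily_matrix(
    events: pd.DataFrame,
    deployments: pd.DataFrame,
    species_id: str,
    year: int,
) -> DailyDetectionMatrix:
    """Sites × days ternary matrix for one species and one annual season.

    The day axis spans the earliest to the latest active deployment day of
    the year; a cell is NA iff the site's camera was not active that day,
    1 iff at least one event for the species fell on an active (site, day),
    else 0.  Events at inactive site-days or unknown sites are rejected.
    """
    _validate_deployments(deployments)
    dep = deployments[deployments["start_date"].dt.year == year]
    if dep.empty:
        raise ValueError(f"no deployments start in year {year}")
    sites = sorted(dep["site_id"].unique())
    day0, day1 = dep["start_date"].min(), dep["end_date"].max()
    days = pd.date_range(day0, day1, freq="D")
    active = pd.DataFrame(False, index=pd.Index(sites, name="site_id"), columns=days)
    for row in dep.itertuples(index=False):
        active.loc[row.site_id, row.start_date : row.end_date] = True

    values = pd.DataFrame(
        np.where(active.to_numpy(), 0.0, np.nan), index=active.index, columns=days
    )
    ev = events[events["species_id"] == species_id]
    ev = ev[ev["date"].dt.year == year]
    for row in ev.itertuples(index=False):
        if row.site_id not in active.index:
            raise ValueError(
                f"event for species {species_id!r} at unknown site {row.site_id!r}"
            )
        d = row.date
        if d not in active.columns or not active.at[row.site_id, d]:
            raise ValueError(
                f"event for species {species_id!r} at site {row.site_id!r} on "
                f"{d.date()} falls outside any active deployment"
            )
        values.at[row.site_id, d] = 1.0
    values.columns = [d.date().isoformat() for d in days]
    return DailyDetectionMatrix(species_id=species_id, year=year, values=values)


def collapse_to_periods(daily: DailyDetectionMatrix, n_periods: int = 15) -> PeriodDetectionMatrix:
    """Group the day columns into ``n_periods`` contiguous, near-equal blocks.

    Remainder days go one-per-block to the earliest blocks.  A period is 1 if
    any day in the block is 1; 0 if no day is 1 but at least one day was
    sampled; NA only when every day in the block is NA.
    """
    if n_periods < 1:
        raise ValueError("n_periods must be >= 1")
    n_days = daily.values.shape[1]
    if n_days < n_periods:
        raise ValueError(f"cannot collapse {n_days} days into {n_periods} periods")
    blocks = np.array_split(np.arange(n_days), n_periods)
    arr = daily.values.to_numpy(float)
    out = np.full((arr.shape[0], n_periods), np.nan)
    for k, idx in enumerate(blocks):
        block = arr[:, idx]
        sampled = ~np.isnan(block)
        any_det = np.nansum(np.where(sampled, block, 0.0), axis=1) > 0
        out[:, k] = np.where(any_det, 1.0, np.where(sampled.any(axis=1), 0.0, np.nan))
    values = pd.DataFrame(
        out, index=daily.values.index, columns=[f"p{k + 1}" for k in range(n_periods)]
    )
    return PeriodDetectionMatrix(species_id=daily.species_id, year=daily.year, values=values)


def pool_species(matrices: list, pooled_id: str = "pooled"):
    """Cell-wise union of detection matrices (e.g. all cat species together).

    A pooled cell is 1 if any input is 1, NA if every input is NA, else 0.
    """
    if not matrices:
        raise ValueError("nothing to pool")
    first = matrices[0]
    for m in matrices[1:]:
        if m.values.shape != first.values.shape or list(m.values.index) != list(first.values.index):
            raise ValueError("pooled matrices must share sites and columns")
        if m.year != first.year:
            raise ValueError("pooled matrices must share the year")
    stack = np.stack([m.values.to_numpy(float) for m in matrices])
    sampled = ~np.isnan(stack)
    any_det = np.nansum(np.where(sampled, stack, 0.0), axis=0) > 0
    out = np.where(any_det, 1.0, np.where(sampled.any(axis=0), 0.0, np.nan))
    values = pd.DataFrame(out, index=first.values.index, columns=first.values.columns)
    return type(first)(species_id=pooled_id, year=first.year, values=values)


def standardize_covariates(cov: pd.DataFrame) -> StandardizedCovariates:
    """Center/scale numeric columns (sample sd, ddof=1); one-hot categoricals.

    Zero-variance numeric columns are rejected by name.  The first level in
    alphabetical order of each categorical column is the reference and is
    dropped from the expansion.
    """
    num = cov.select_dtypes(include="number")
    cat = cov.select_dtypes(exclude="number")
    means = num.mean()
    sds = num.std(ddof=1)
    zero = sds[(sds == 0) | sds.isna()]
    if len(zero):
        raise ValueError(f"zero-variance covariate column(s): {list(zero.index)}")
    z = (num - means) / sds
    refs: dict[str, str] = {}
    pieces = [z]
    for c in cat.columns:
        levels = sorted(cat[c].astype(str).unique())
        refs[c] = levels[0]
        for lev in levels[1:]:
            pieces.append((cat[c].astype(str) == lev).astype(float).rename(f"{c}_{lev}"))
    values = pd.concat(pieces, axis=1)
    return StandardizedCovariates(values=values, means=means, sds=sds, reference_levels=refs)


# ---------------------------------------------------------------------------
# round trips with the simulator / export

def events_from_daily(matrices: list) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Invert daily matrices into (events, deployments) CSV-shaped tables.

    Contiguous sampled runs become deployment intervals; 1-cells become one
    event each, so ``build_daily_matrix`` on the output reproduces the input.
    """
    ev_rows, dep_rows = [], []
    seen_dep = set()
    for m in matrices:
        days = pd.to_datetime(m.values.columns)
        arr = m.values.to_numpy(float)
        for i, site in enumerate(m.values.index):
            sampled = ~np.isnan(arr[i])
            if (m.year, site) not in seen_dep:
                seen_dep.add((m.year, site))
                j = 0
                while j < len(sampled):
                    if sampled[j]:
                        k = j
                        while k + 1 < len(sampled) and sampled[k + 1]:
                            k += 1
                        dep_rows.append((site, days[j], days[k]))
                        j = k + 1
                    else:
                        j += 1
            for j in np.flatnonzero(arr[i] == 1.0):
                ev_rows.append((m.species_id, site, days[j]))
    events = pd.DataFrame(ev_rows, columns=["species_id", "site_id", "date"])
    deployments = pd.DataFrame(dep_rows, columns=["site_id", "start_date", "end_date"])
    return events, deployments


def detection_stack(per_year: dict[int, PeriodDetectionMatrix]) -> np.ndarray:
    """Stack one species' per-year period matrices into (sites, years, periods) int8."""
    years = sorted(per_year)
    mats = [per_year[y] for y in years]
    sites = mats[0].values.index
    for m in mats:
        if not m.values.index.equals(sites):
            raise ValueError("years disagree on the site set")
    return np.stack([m.to_array() for m in mats], axis=1)
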