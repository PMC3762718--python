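"""Posterior-derived community indicators.

The Wildlife Picture Index (WPI) for a set of species is the geometric mean
of their occupancies scaled by their first-year (baseline) occupancies,
computed at every retained posterior draw so the index itself carries a
posterior distribution.  Change between years is tested through the ratio
lambda_n = psi(t+n)/psi(t): a decline is declared when the 95% HPDI of
lambda lies entirely below 1, an increase when it lies entirely above 1,
otherwise no change; the same rule applies to WPI ratios.

Point estimates use the median or the half-sample mode, whichever is lower,
because occupancy posteriors for sparsely detected species are strongly
skewed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "hpdi",
    "posterior_mode",
    "OccupancyPosterior",
    "WPISeries",
    "LambdaMatrix",
    "relative_occupancy",
    "wpi_series",
    "group_wpi",
    "lambda_matrix",
    "naive_occupancy",
]

#: floor applied to occupancy draws before forming ratios
RATIO_EPS = 1e-6

DECLINE, INCREASE, NO_CHANGE = "decline", "increase", "no_change"


def hpdi(draws, level: float = 0.95) -> tuple[float, float]:
    """Shortest contiguous interval containing ceil(level * n) sorted draws."""
    x = np.sort(np.asarray(draws, dtype=float))
    n = x.size
    if n < 20:
        raise ValueError("need at least 20 draws for an HPDI")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    m = int(np.ceil(level * n))
    widths = x[m - 1 :] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


def posterior_mode(draws) -> float:
    """Half-sample mode: recursively narrow to the shortest half of the sample.

    Deterministic given the draws; robust for skewed posteriors and needs no
    bandwidth choice.
    """
    x = np.sort(np.asarray(draws, dtype=float))
    if x.size < 100:
        raise ValueError("need at least 100 draws for the half-sample mode")
    while x.size > 3:
        h = (x.size + 1) // 2
        widths = x[h - 1 :] - x[: x.size - h + 1]
        i = int(np.argmin(widths))
        x = x[i : i + h]
    if x.size == 3:
        # keep the closer pair
        x = x[:2] if (x[1] - x[0]) <= (x[2] - x[1]) else x[1:]
    return float(x.mean())


def _central_low(draws: np.ndarray) -> float:
    """min(median, half-sample mode); median alone when draws are few."""
    med = float(np.median(draws))
    if draws.size >= 100:
        return min(med, posterior_mode(draws))
    return med


@dataclass
class OccupancyPosterior:
    """Aligned annual-occupancy draws for several independently fitted species.

    occ: (n_species, n_years, n_draws); the m-th draw of each species is
    paired across species (species are fitted independently, so any pairing
    is valid; pairing by retained-draw index is the convention here).
    """

    occ: np.ndarray
    species: list[str]
    attributes: pd.DataFrame | None = None
    flagged_species: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.occ = np.asarray(self.occ, dtype=float)
        if self.occ.ndim != 3 or self.occ.shape[0] != len(self.species):
            raise ValueError("occ must be (n_species, n_years, n_draws)")
        if ((self.occ < 0) | (self.occ > 1)).any():
            raise ValueError("occupancy draws must lie in [0, 1]")

    @property
    def n_years(self) -> int:
        return self.occ.shape[1]

    def subset(self, species: list[str]) -> "OccupancyPosterior":
        idx = [self.species.index(s) for s in species]
        return OccupancyPosterior(
            occ=self.occ[idx], species=list(species), attributes=self.attributes,
            flagged_species=[s for s in self.flagged_species if s in species],
        )


@dataclass
class WPISeries:
    years: np.ndarray
    draws: np.ndarray          # (n_years, n_draws); year 0 is the baseline
    point: np.ndarray          # per-year min(median, mode)
    hpdi_lo: np.ndarray
    hpdi_hi: np.ndarray
    species: list[str]
    baseline_year: int = 0


@dataclass
class LambdaMatrix:
    """Posterior change ratios lambda = psi(t2)/psi(t1) for all t1 < t2."""

    years: np.ndarray
    draws: dict[tuple[int, int], np.ndarray]
    hpdi_lo: np.ndarray        # (T, T), NaN off the upper triangle
    hpdi_hi: np.ndarray
    trend: dict[tuple[int, int], str]

    def classify(self, t1: int, t2: int) -> str:
        return self.trend[(t1, t2)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "from_year": t1, "to_year": t2,
                "lambda_median": float(np.median(d)),
                "hpdi_lo": self.hpdi_lo[t1, t2], "hpdi_hi": self.hpdi_hi[t1, t2],
                "trend": self.trend[(t1, t2)],
            }
            for (t1, t2), d in sorted(self.draws.items())
        ]
        return pd.DataFrame(rows)


def relative_occupancy(occ: OccupancyPosterior) -> OccupancyPosterior:
    """Scale every draw trajectory by its own baseline-year value.

    Zero baseline draws are floored at RATIO_EPS and the species flagged.
    """
    base = occ.occ[:, :1, :]
    flagged = [occ.species[i] for i in np.flatnonzero((base <= 0).any(axis=(1, 2)))]
    rel = occ.occ / np.maximum(base, RATIO_EPS)
    out = OccupancyPosterior.__new__(OccupancyPosterior)
    out.occ = rel  # relative values may exceed 1; skip the [0,1] check
    out.species = list(occ.species)
    out.attributes = occ.attributes
    out.flagged_species = sorted(set(occ.flagged_species) | set(flagged))
    return out


def wpi_series(occ: OccupancyPosterior, subset: list[str] | None = None,
               level: float = 0.95) -> WPISeries:
    """WPI draws: per-draw geometric mean of relative occupancies.

    The baseline year is identically 1 in every draw.  Point estimate per
    year is min(median, half-sample mode) of the draws; a 95% HPDI is
    attached.
    """
    if subset is not None:
        if len(subset) == 0:
            raise ValueError("species subset must be nonempty")
        occ = occ.subset(list(subset))
    rel = relative_occupancy(occ)
    logs = np.log(np.maximum(rel.occ, RATIO_EPS))
    draws = np.exp(logs.mean(axis=0))          # (n_years, n_draws)
    draws[0, :] = 1.0
    T = draws.shape[0]
    point = np.array([_central_low(draws[t]) for t in range(T)])
    lo = np.empty(T)
    hi = np.empty(T)
    lo[0] = hi[0] = 1.0
    for t in range(1, T):
        if np.ptp(draws[t]) == 0:
            lo[t] = hi[t] = draws[t, 0]
        else:
            lo[t], hi[t] = hpdi(draws[t], level)
    return WPISeries(
        years=np.arange(T), draws=draws, point=point,
        hpdi_lo=lo, hpdi_hi=hi, species=list(occ.species),
    )


_SCHEMES = ("hunted", "guild", "iucn")


def group_wpi(occ: OccupancyPosterior, attributes: pd.DataFrame,
              scheme: str) -> dict[str, WPISeries]:
    """WPI disaggregated by hunted status, functional guild or IUCN status.

    The iucn scheme splits least-concern species from the rest (near
    threatened / endangered / data deficient).  Single-species groups are
    allowed: the WPI then equals that species' relative occupancy.
    """
    if scheme not in _SCHEMES:
        raise ValueError(f"unknown grouping scheme {scheme!r}; pick from {_SCHEMES}")
    missing = [s for s in occ.species if s not in attributes.index]
    if missing:
        raise ValueError(f"species without attributes: {missing}")
    if scheme == "hunted":
        labels = {
            s: ("hunted" if bool(attributes.loc[s, "hunted"]) else "not_hunted")
            for s in occ.species
        }
    elif scheme == "guild":
        labels = {s: str(attributes.loc[s, "guild"]) for s in occ.species}
    else:
        labels = {
            s: ("least_concern" if attributes.loc[s, "iucn_status"] == "LC" else "other")
            for s in occ.species
        }
    out = {}
    for g in sorted(set(labels.values())):
        members = [s for s in occ.species if labels[s] == g]
        out[g] = wpi_series(occ, subset=members)
    return out


def lambda_matrix(draws: np.ndarray, level: float = 0.95) -> LambdaMatrix:
    """Change ratios for an annual posterior series (occupancy or WPI).

    draws: (n_years, n_draws).  For every ordered pair t1 < t2 the ratio
    draws[t2]/draws[t1] is classified against 1 by the HPDI rule.
    """
    draws = np.asarray(draws, dtype=float)
    T = draws.shape[0]
    if T < 2:
        raise ValueError("need at least 2 years")
    lam: dict[tuple[int, int], np.ndarray] = {}
    trend: dict[tuple[int, int], str] = {}
    lo = np.full((T, T), np.nan)
    hi = np.full((T, T), np.nan)
    for t1 in range(T - 1):
        denom = np.maximum(draws[t1], RATIO_EPS)
        for t2 in range(t1 + 1, T):
            r = draws[t2] / denom
            lam[(t1, t2)] = r
            if np.ptp(r) == 0:
                a = b = float(r[0])
            else:
                a, b = hpdi(r, level)
            lo[t1, t2], hi[t1, t2] = a, b
            trend[(t1, t2)] = DECLINE if b < 1.0 else INCREASE if a > 1.0 else NO_CHANGE
    return LambdaMatrix(years=np.arange(T), draws=lam, hpdi_lo=lo, hpdi_hi=hi, trend=trend)


def naive_occupancy(matrix) -> float:
    """Fraction of sampled sites with at least one detection.

    Accepts a PeriodDetectionMatrix or a (sites, periods) array with -1/NaN
    for not-sampled; all-NA sites are excluded from the denominator.
    """
    arr = matrix.values.to_numpy(float) if hasattr(matrix, "values") and hasattr(matrix, "species_id") else np.asarray(matrix, dtype=float)
    arr = np.where(arr == -1, np.nan, arr)
    sampled = ~np.isnan(arr)
    site_sampled = sampled.any(axis=1)
    if not site_sampled.any():
        raise ValueError("no sampled sites")
    det = np.nansum(np.where(sampled, arr, 0.0), axis=1) > 0
    return float(det[site_sampled].mean())
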