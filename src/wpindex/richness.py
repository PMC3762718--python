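"""Detection-corrected species richness from a species-by-point matrix.

Relative richness psi_S is the probability that a species from a known
regional pool is present in a given year, estimated with the same dynamic
occupancy machinery used for single species but transposed: the modelled
"unit" is a species from the pool (never-detected pool members enter as
all-zero rows), and the repeat visits within a year are the sampling
points.  Detection is modelled on the logit scale with standardized body
mass, trophic group and year effects.  Scaled richness is psi_S times the
pool size; uncertainty comes from a nonparametric bootstrap over sampling
points (500 iterations by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .likelihood import forward_loglik

__all__ = ["RichnessEstimate", "richness_fit", "build_richness_stack"]

NA = -1

TROPHIC_GROUPS = ("carnivore", "herbivore", "insectivore", "omnivore")

_GUILD_TO_TROPHIC = {
    "carnivore": "carnivore",
    "large_herbivore": "herbivore",
    "small_herbivore": "herbivore",
    "omnivore": "omnivore",
    "insectivore": "insectivore",
}


@dataclass
class RichnessEstimate:
    years: np.ndarray
    psi_rel: np.ndarray            # relative richness per year, in [0, 1]
    scaled: np.ndarray             # psi_rel * pool_size
    pool_size: int
    ci_lo: np.ndarray | None = None   # bootstrap percentile CI on scaled richness
    ci_hi: np.ndarray | None = None
    se: np.ndarray | None = None      # bootstrap SE on scaled richness
    detection_coefs: dict = field(default_factory=dict)
    n_boot: int = 0
    converged: bool = True

    def __post_init__(self):
        if (self.scaled > self.pool_size + 1e-9).any():
            raise ValueError("scaled richness cannot exceed the pool size")

    def to_frame(self) -> pd.DataFrame:
        d = {"year": self.years, "psi_rel": self.psi_rel, "richness": self.scaled}
        if self.ci_lo is not None:
            d["ci_lo"], d["ci_hi"], d["se"] = self.ci_lo, self.ci_hi, self.se
        return pd.DataFrame(d)


def build_richness_stack(
    detections: dict[str, np.ndarray],
    pool_attributes: pd.DataFrame,
    pool_size: int,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Species-by-point yearly detection stack for the whole regional pool.

    ``detections``: per detected species a (sites, years, periods) int8
    array.  Each species-year is collapsed to detected/not per point (NA
    when the point was never sampled that year).  Pool members never
    detected become all-zero rows, which are informative under the model.
    Returns ((pool, years, points) int8, attribute frame aligned to rows).
    """
    if not detections:
        raise ValueError("no detections supplied")
    ids = list(detections)
    missing = [s for s in ids if s not in pool_attributes.index]
    if missing:
        raise ValueError(f"species without attributes: {missing}")
    if pool_size < len(pool_attributes):
        raise ValueError("pool_size smaller than the attribute table")
    first = detections[ids[0]]
    S, T, _ = first.shape
    # a point counts as sampled in a year if any period was sampled for any species
    sampled = np.zeros((S, T), dtype=bool)
    for arr in detections.values():
        sampled |= (arr != NA).any(axis=2)

    rows = []
    order = [s for s in pool_attributes.index]  # detected + undetected pool members
    for sp in order:
        row = np.where(sampled, 0, NA).astype(np.int8)  # (S, T)
        if sp in detections:
            row = np.where((detections[sp] == 1).any(axis=2), 1, row).astype(np.int8)
        rows.append(row.T)  # (T, S): replicates are points
    data = np.stack(rows)   # (pool, T, S)
    return data, pool_attributes.loc[order]


def _detection_design(attributes: pd.DataFrame, n_years: int):
    """Columns: intercept, standardized log mass, trophic dummies, year dummies."""
    mass = np.log(attributes["body_mass_kg"].to_numpy(float))
    mass = (mass - mass.mean()) / mass.std(ddof=1)
    trophic = attributes["guild"].map(_GUILD_TO_TROPHIC)
    if trophic.isna().any():
        bad = attributes.index[trophic.isna()][0]
        raise ValueError(f"species {bad!r} has no recognised guild")
    levels = sorted(set(trophic))
    names = ["intercept", "log_mass"]
    cols = [np.ones(len(attributes)), mass]
    for lev in levels[1:]:
        cols.append((trophic == lev).to_numpy(float))
        names.append(f"trophic_{lev}")
    Xs = np.column_stack(cols)                      # per-species part
    year_names = [f"year_{t + 1}" for t in range(1, n_years)]
    return Xs, names, year_names, levels[0]


def richness_fit(
    detections: dict[str, np.ndarray],
    pool_attributes: pd.DataFrame,
    pool_size: int,
    n_boot: int = 500,
    seed: int = 0,
    conf_level: float = 0.95,
) -> RichnessEstimate:
    """Fit the species-level dynamic occupancy model and scale to the pool.

    Occupancy: year-1 intercept, year-specific survival/colonization.
    Detection: logit-linear in standardized log body mass, trophic group and
    year.  psi_S per year follows the fitted recursion; bootstrap CIs (and
    SE) resample sampling points with replacement.
    """
    data, attrs = build_richness_stack(detections, pool_attributes, pool_size)
    n_pool, T, n_points = data.shape
    Xs, coef_names, year_names, ref_trophic = _detection_design(attrs, T)

    def fit_once(dat):
        nd = Xs.shape[1]
        n_theta = 1 + 2 * max(T - 1, 0) + nd + (T - 1)

        def unpack(theta):
            psi1 = expit(theta[0])
            i = 1
            phi = expit(theta[i : i + T - 1]); i += T - 1
            gam = expit(theta[i : i + T - 1]); i += T - 1
            b = theta[i : i + nd]; i += nd
            yr = np.r_[0.0, theta[i : i + T - 1]]
            # p[(species, year)] = invlogit(Xs b + year effect)
            p = expit(Xs @ b[:, None] + yr[None, :])    # (n_pool, T)
            return psi1, phi, gam, p

        def nll(theta):
            psi1, phi, gam, p = unpack(theta)
            ll = forward_loglik(dat, np.full(n_pool, psi1), phi, gam, p)
            if not np.isfinite(ll).all():
                return 1e12
            return -float(ll.sum())

        naive = float(((dat[:, 0, :] == 1).any(axis=1)).mean())
        x0 = np.zeros(n_theta)
        x0[0] = logit(np.clip(naive, 0.05, 0.95))
        x0[1 : 1 + 2 * (T - 1)] = logit(np.r_[np.full(T - 1, 0.8), np.full(T - 1, 0.2)])
        bounds = [(-15.0, 15.0)] * n_theta
        res = minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 800, "ftol": 1e-10})
        psi1, phi, gam, p = unpack(res.x)
        traj = np.empty(T)
        traj[0] = psi1
        for t in range(1, T):
            traj[t] = traj[t - 1] * phi[t - 1] + (1 - traj[t - 1]) * gam[t - 1]
        return traj, res

    traj, res = fit_once(data)
    i0 = 1 + 2 * (T - 1)
    coefs = dict(zip(coef_names, res.x[i0 : i0 + Xs.shape[1]]))
    coefs.update(dict(zip(year_names, res.x[i0 + Xs.shape[1] :])))
    coefs["reference_trophic"] = ref_trophic

    ci_lo = ci_hi = se = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boot = np.empty((n_boot, T))
        for b in range(n_boot):
            cols = rng.integers(0, n_points, size=n_points)
            boot[b], _ = fit_once(data[:, :, cols])
        boot_scaled = boot * pool_size
        a = (1 - conf_level) / 2
        ci_lo = np.quantile(boot_scaled, a, axis=0)
        ci_hi = np.quantile(boot_scaled, 1 - a, axis=0)
        se = boot_scaled.std(axis=0, ddof=1)

    return RichnessEstimate(
        years=np.arange(T), psi_rel=traj, scaled=traj * pool_size,
        pool_size=pool_size, ci_lo=ci_lo, ci_hi=ci_hi, se=se,
        detection_coefs=coefs, n_boot=n_boot, converged=bool(res.success),
    )
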