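"""Synthetic camera-trap communities with known truth.

The generator draws data from exactly the statistical model the analysis
assumes: year-1 occupancy Bernoulli(inv-logit(beta . x)), between-year
transitions via apparent survival phi and colonization gamma, and
period-level detections Bernoulli(Z * p) under within-year closure.  Its
default community emulates the study design this package was built around:
60 sampling points along a 30-3000 m elevational gradient, 5 annual
seasons of 15 sampling periods, and a 13-species tropical-forest mammal
assemblage (3 of them locally hunted).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from scipy.special import expit, logit
from scipy.stats import norm

from .ingest import PeriodDetectionMatrix, StandardizedCovariates, standardize_covariates

__all__ = [
    "SpeciesSimParams",
    "CommunityScenario",
    "CommunityBundle",
    "simulate_site_covariates",
    "simulate_species",
    "simulate_community",
    "apply_missingness",
    "stable_scenario",
    "hunted_decline_scenario",
]

NA = -1


@dataclass
class SpeciesSimParams:
    """Generative parameters for one species.

    beta_psi: logit-scale year-1 occupancy coefficients (intercept first,
    then one per name in psi1_covariates); phi/gamma: per-transition
    survival/colonization; p: per-year per-period detection probability.
    """

    species_id: str
    beta_psi: np.ndarray
    phi: np.ndarray
    gamma: np.ndarray
    p: np.ndarray
    psi1_covariates: tuple[str, ...] = ()

    def __post_init__(self):
        self.beta_psi = np.atleast_1d(np.asarray(self.beta_psi, float))
        self.phi = np.atleast_1d(np.asarray(self.phi, float))
        self.gamma = np.atleast_1d(np.asarray(self.gamma, float))
        self.p = np.atleast_1d(np.asarray(self.p, float))
        if not np.isfinite(self.beta_psi).all():
            raise ValueError("beta_psi must be finite")
        for name, v in (("phi", self.phi), ("gamma", self.gamma), ("p", self.p)):
            if ((v < 0) | (v > 1)).any():
                raise ValueError(f"{name} must lie in [0, 1]")
        if len(self.beta_psi) != 1 + len(self.psi1_covariates):
            raise ValueError("beta_psi length must be 1 + len(psi1_covariates)")


@dataclass
class CommunityScenario:
    n_sites: int = 60
    n_years: int = 5
    n_periods: int = 15
    species: list[SpeciesSimParams] = field(default_factory=list)
    attributes: pd.DataFrame | None = None  # index species_id
    miss_prob: float = 0.0
    miss_mode: str = "iid"
    seed: int = 0
    covariate_seed: int | None = None
    name: str = "custom"

    def __post_init__(self):
        if min(self.n_sites, self.n_years, self.n_periods) < 1:
            raise ValueError("scenario dimensions must be >= 1")
        if not 0.0 <= self.miss_prob < 1.0:
            raise ValueError("miss_prob must lie in [0, 1)")

    def to_yaml(self, path) -> None:
        d = {
            "name": self.name,
            "n_sites": self.n_sites,
            "n_years": self.n_years,
            "n_periods": self.n_periods,
            "miss_prob": self.miss_prob,
            "miss_mode": self.miss_mode,
            "seed": self.seed,
            "species": [
                {
                    "species_id": s.species_id,
                    "beta_psi": s.beta_psi.tolist(),
                    "phi": s.phi.tolist(),
                    "gamma": s.gamma.tolist(),
                    "p": s.p.tolist(),
                    "psi1_covariates": list(s.psi1_covariates),
                }
                for s in self.species
            ],
            "attributes": (
                self.attributes.reset_index().to_dict(orient="records")
                if self.attributes is not None
                else None
            ),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CommunityScenario":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        species = [
            SpeciesSimParams(
                species_id=s["species_id"],
                beta_psi=np.asarray(s["beta_psi"], float),
                phi=np.asarray(s["phi"], float),
                gamma=np.asarray(s["gamma"], float),
                p=np.asarray(s["p"], float),
                psi1_covariates=tuple(s.get("psi1_covariates", ())),
            )
            for s in d.get("species", [])
        ]
        attrs = d.get("attributes")
        attributes = (
            pd.DataFrame(attrs).set_index("species_id") if attrs else None
        )
        return cls(
            n_sites=d["n_sites"], n_years=d["n_years"], n_periods=d["n_periods"],
            species=species, attributes=attributes,
            miss_prob=d.get("miss_prob", 0.0), miss_mode=d.get("miss_mode", "iid"),
            seed=d.get("seed", 0), name=d.get("name", "custom"),
        )


def simulate_site_covariates(
    n_sites: int,
    seed: int = 0,
    elevation_range: tuple[float, float] = (30.0, 3000.0),
    canopy_corr: float = -0.4,
    edge_corr: float = 0.3,
) -> pd.DataFrame:
    """Per-site covariates along an elevational gradient.

    Elevation is uniform over ``elevation_range``; canopy height and
    distance-to-edge are Gaussian-copula correlated with elevation at the
    given correlations.  Forest type is banded by elevation with a
    secondary-forest class near the low end.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    z_elev = rng.normal(size=n_sites)
    u = norm.cdf(z_elev)
    lo, hi = elevation_range
    elevation = lo + (hi - lo) * u

    def correlated(r, loc, scale, floor):
        z = r * z_elev + np.sqrt(max(1 - r**2, 0.0)) * rng.normal(size=n_sites)
        return np.clip(loc + scale * z, floor, None)

    canopy = correlated(canopy_corr, 28.0, 8.0, 2.0)
    edge = correlated(edge_corr, 1500.0, 900.0, 10.0)
    slope = rng.uniform(0.0, 50.0, size=n_sites)
    aspect = rng.uniform(0.0, 360.0, size=n_sites)
    bands = np.select(
        [elevation < 300, elevation < 1200, elevation < 2200],
        ["primary_low", "primary_mid", "primary_high"],
        default="primary_very_high",
    )
    secondary = rng.random(n_sites) < np.where(elevation < 600, 0.3, 0.02)
    forest_type = np.where(secondary, "secondary", bands)
    return pd.DataFrame(
        {
            "elevation": elevation,
            "canopy_height": canopy,
            "edge_distance": edge,
            "slope": slope,
            "aspect": aspect,
            "forest_type": forest_type,
        },
        index=pd.Index([f"VB-{i + 1:02d}" for i in range(n_sites)], name="site_id"),
    )


def simulate_species(
    params: SpeciesSimParams,
    cov: StandardizedCovariates | pd.DataFrame,
    n_years: int,
    n_periods: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one species: latent Z (sites, years) and detections
    (sites, years, periods) int8.

    Year-1 Z ~ Bernoulli(inv-logit(X beta)); transitions via phi (stay) and
    gamma (colonize); detections only where Z=1 (closure within years).
    """
    if isinstance(cov, pd.DataFrame):
        cov = standardize_covariates(cov)
    X = cov.design_matrix(params.psi1_covariates)
    S = X.shape[0]
    T, K = n_years, n_periods
    def per(v, n):  # scalar broadcast, else first n entries
        v = np.atleast_1d(v)
        return np.broadcast_to(v, (n,)) if v.size == 1 else v[:n]

    phi = per(params.phi, max(T - 1, 1))
    gamma = per(params.gamma, max(T - 1, 1))
    p = per(params.p, T)
    rng = np.random.default_rng(seed)
    psi1 = expit(X @ params.beta_psi)
    Z = np.empty((S, T), dtype=np.int8)
    Z[:, 0] = rng.random(S) < psi1
    for t in range(1, T):
        stay = rng.random(S) < phi[t - 1]
        col = rng.random(S) < gamma[t - 1]
        Z[:, t] = np.where(Z[:, t - 1] == 1, stay, col)
    y = (rng.random((S, T, K)) < (Z[:, :, None] * p[None, :, None])).astype(np.int8)
    return Z, y


def apply_missingness(
    matrix: np.ndarray | PeriodDetectionMatrix,
    miss_prob: float,
    seed: int = 0,
    mode: str = "iid",
):
    """Blank cells to NA to emulate camera failures; never invents detections.

    mode "iid": each cell independently NA with ``miss_prob``.
    mode "tail": per site-year, the camera dies before a uniformly chosen
    period with probability ``miss_prob``; all later periods become NA.
    """
    if not 0.0 <= miss_prob < 1.0:
        raise ValueError("miss_prob must lie in [0, 1)")
    wrap = isinstance(matrix, PeriodDetectionMatrix)
    if wrap:
        arr = matrix.to_array()[:, None, :]
    else:
        arr = np.asarray(matrix)
    out = arr.copy()
    if miss_prob > 0:
        rng = np.random.default_rng(seed)
        if mode == "iid":
            out[rng.random(arr.shape) < miss_prob] = NA
        elif mode == "tail":
            S, T, K = arr.shape
            dies = rng.random((S, T)) < miss_prob
            cut = rng.integers(1, K, size=(S, T))
            k_idx = np.arange(K)[None, None, :]
            out[(k_idx >= cut[:, :, None]) & dies[:, :, None]] = NA
        else:
            raise ValueError(f"unknown missingness mode {mode!r}")
    if wrap:
        vals = np.where(out[:, 0, :] == NA, np.nan, out[:, 0, :].astype(float))
        return PeriodDetectionMatrix(
            species_id=matrix.species_id,
            year=matrix.year,
            values=pd.DataFrame(vals, index=matrix.values.index, columns=matrix.values.columns),
        )
    return out


@dataclass
class CommunityBundle:
    """Simulated community plus the generating truth."""

    scenario: CommunityScenario
    covariates: pd.DataFrame
    std_covariates: StandardizedCovariates
    attributes: pd.DataFrame
    detections: dict[str, np.ndarray]   # species -> (S, T, K) int8
    latent: dict[str, np.ndarray]       # species -> (S, T) int8

    @property
    def site_ids(self) -> list[str]:
        return list(self.covariates.index)

    def true_expected_occupancy(self) -> pd.DataFrame:
        """Per-species expected occupancy trajectory from the recursion."""
        rows = {}
        T = self.scenario.n_years
        for sp in self.scenario.species:
            X = self.std_covariates.design_matrix(sp.psi1_covariates)
            psi = np.empty(T)
            psi[0] = expit(X @ sp.beta_psi).mean()
            phi = np.broadcast_to(sp.phi, (max(T - 1, 1),))
            gam = np.broadcast_to(sp.gamma, (max(T - 1, 1),))
            for t in range(1, T):
                psi[t] = psi[t - 1] * phi[t - 1] + (1 - psi[t - 1]) * gam[t - 1]
            rows[sp.species_id] = psi
        return pd.DataFrame(rows, index=pd.RangeIndex(T, name="year")).T

    def true_wpi(self) -> np.ndarray:
        """Geometric mean over species of expected occupancy relative to year 1."""
        occ = self.true_expected_occupancy().to_numpy()
        rel = occ / occ[:, :1]
        return np.exp(np.log(rel).mean(axis=0))

    def period_matrices(self, species_id: str, years: list[int] | None = None):
        arr = self.detections[species_id]
        T = arr.shape[1]
        years = years if years is not None else list(range(T))
        out = {}
        for t in years:
            vals = np.where(arr[:, t, :] == NA, np.nan, arr[:, t, :].astype(float))
            out[t] = PeriodDetectionMatrix(
                species_id=species_id,
                year=t,
                values=pd.DataFrame(
                    vals,
                    index=self.covariates.index,
                    columns=[f"p{k + 1}" for k in range(arr.shape[2])],
                ),
            )
        return out

    def write_csvs(self, outdir) -> None:
        """Emit the same CSV dialects the ingest module reads."""
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.covariates.to_csv(outdir / "covariates.csv", index_label="site_id")
        self.attributes.to_csv(outdir / "species_attributes.csv", index_label="species_id")
        for sp, arr in self.detections.items():
            for t in range(arr.shape[1]):
                self.period_matrices(sp, [t])[t].to_csv(outdir / f"detections_{sp}_year{t}.csv")


def simulate_community(scenario: CommunityScenario) -> CommunityBundle:
    """Draw the full community; byte-identical under a fixed scenario seed."""
    cov_seed = scenario.covariate_seed if scenario.covariate_seed is not None else scenario.seed
    covariates = simulate_site_covariates(scenario.n_sites, seed=cov_seed)
    std = standardize_covariates(covariates)
    seqs = np.random.SeedSequence(scenario.seed).spawn(len(scenario.species) + 1)
    detections, latent = {}, {}
    for i, sp in enumerate(scenario.species):
        Z, y = simulate_species(
            sp, std, scenario.n_years, scenario.n_periods, seed=seqs[i]
        )
        if scenario.miss_prob > 0:
            y = apply_missingness(
                y, scenario.miss_prob,
                seed=np.random.SeedSequence((scenario.seed, 7919, i)),
                mode=scenario.miss_mode,
            )
        detections[sp.species_id] = y
        latent[sp.species_id] = Z
    attributes = scenario.attributes
    if attributes is None:
        attributes = pd.DataFrame(
            {
                "body_mass_kg": 5.0,
                "guild": "omnivore",
                "hunted": False,
                "iucn_status": "LC",
            },
            index=pd.Index([s.species_id for s in scenario.species], name="species_id"),
        )
    return CommunityBundle(
        scenario=scenario, covariates=covariates, std_covariates=std,
        attributes=attributes, detections=detections, latent=latent,
    )


# ---------------------------------------------------------------------------
# preset communities

# 13-species tropical-forest assemblage: (id, mass kg, guild, hunted, iucn,
# equilibrium occupancy, detection probability per period)
_COMMUNITY = [
    ("paca",        8.0,  "small_herbivore", True,  "LC", 0.70, 0.4),
    ("agouti",      4.0,  "small_herbivore", True,  "LC", 0.65, 0.4),
    ("armadillo",   4.5,  "omnivore",        False, "LC", 0.55, 0.4),
    ("tayra",       5.0,  "omnivore",        False, "LC", 0.40, 0.4),
    ("coati",       5.5,  "omnivore",        False, "LC", 0.50, 0.4),
    ("ocelot",     12.0,  "carnivore",       False, "LC", 0.45, 0.4),
    ("margay",      3.5,  "carnivore",       False, "NT", 0.30, 0.4),
    ("jaguarundi",  6.0,  "carnivore",       False, "LC", 0.25, 0.4),
    ("cougar",     60.0,  "carnivore",       False, "LC", 0.35, 0.4),
    ("jaguar",     80.0,  "carnivore",       False, "NT", 0.25, 0.4),
    ("brocket",    25.0,  "large_herbivore", False, "DD", 0.45, 0.4),
    ("peccary",    25.0,  "large_herbivore", True,  "LC", 0.60, 0.4),
    ("tapir",     250.0,  "large_herbivore", False, "EN", 0.40, 0.4),
]

#: stationary apparent survival shared by the stable preset
_PHI_STABLE = 0.8
#: survival of hunted small herbivores in the decline preset: with gamma
#: near zero, occupancy drops by >half over 3 transitions (0.72^3 ~ 0.37)
_PHI_DECLINE = 0.72
_GAMMA_DECLINE = 0.01


def _attributes_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "body_mass_kg": [r[1] for r in rows],
            "guild": [r[2] for r in rows],
            "hunted": [r[3] for r in rows],
            "iucn_status": [r[4] for r in rows],
        },
        index=pd.Index([r[0] for r in rows], name="species_id"),
    )


def _stationary_gamma(psi: float, phi: float) -> float:
    # psi = psi*phi + (1-psi)*gamma  =>  gamma = psi(1-phi)/(1-psi)
    return psi * (1.0 - phi) / (1.0 - psi)


def stable_scenario(
    n_sites: int = 60, n_years: int = 5, n_periods: int = 15,
    seed: int = 0, miss_prob: float = 0.0,
) -> CommunityScenario:
    """All species at their stationary occupancy: true WPI = 1 every year."""
    nt = max(n_years - 1, 1)
    species = []
    for sid, _, _, _, _, psi, p in _COMMUNITY:
        gam = _stationary_gamma(psi, _PHI_STABLE)
        species.append(
            SpeciesSimParams(
                species_id=sid,
                beta_psi=np.array([logit(psi)]),
                phi=np.full(nt, _PHI_STABLE),
                gamma=np.full(nt, gam),
                p=np.full(n_years, p),
            )
        )
    return CommunityScenario(
        n_sites=n_sites, n_years=n_years, n_periods=n_periods,
        species=species, attributes=_attributes_frame(_COMMUNITY),
        miss_prob=miss_prob, seed=seed, name="stable",
    )


def hunted_decline_scenario(
    n_sites: int = 60, n_years: int = 5, n_periods: int = 15,
    seed: int = 0, miss_prob: float = 0.0,
) -> CommunityScenario:
    """Hunted small herbivores decline ~50% over 3-4 years; others stable."""
    base = stable_scenario(n_sites, n_years, n_periods, seed, miss_prob)
    attrs = base.attributes
    for sp in base.species:
        a = attrs.loc[sp.species_id]
        if a["hunted"] and a["guild"] == "small_herbivore":
            sp.phi = np.full_like(sp.phi, _PHI_DECLINE)
            sp.gamma = np.full_like(sp.gamma, _GAMMA_DECLINE)
    base.name = "hunted-decline"
    return base


def declining_species_ids(scenario: CommunityScenario) -> list[str]:
    """Species whose generating parameters are non-stationary (flagged)."""
    out = []
    for sp in scenario.species:
        psi1 = float(expit(sp.beta_psi[0])) if len(sp.beta_psi) == 1 else None
        if psi1 is None:
            continue
        psi = psi1
        for t in range(len(sp.phi)):
            psi = psi * sp.phi[t] + (1 - psi) * sp.gamma[t]
        if abs(psi - psi1) > 0.05:
            out.append(sp.species_id)
    return out
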