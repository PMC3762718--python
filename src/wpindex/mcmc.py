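"""Self-contained Gibbs/Metropolis sampler for the dynamic occupancy model.

The sampler alternates three blocks:

* a Gibbs draw of each latent occupancy state Z_jt from its full
  conditional given the neighbouring years, the detection history and the
  current parameters (years are scanned in order, sites vectorized);
* conjugate Beta(1,1)-posterior draws for the probability parameters:
  detection p from detection counts over occupied site-years, apparent
  survival phi from occupied-to-occupied transitions, colonization gamma
  from empty-to-occupied transitions (pooled across years when constant);
* a random-walk Metropolis update of the logit-scale year-1 occupancy
  coefficients beta under a Normal(0, sd 10) prior, with proposal scale
  adapted only during burn-in.

Each retained draw also records two derived annual occupancy series: the
finite-sample occupancy (mean of Z across sites, the default fed to the
WPI and lambda ratios) and the expected occupancy from the recursion
psi_{t+1} = psi_t phi_t + (1 - psi_t) gamma_t.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .model import ModelSpec, ParameterSet

__all__ = ["MCMCConfig", "PosteriorSamples", "fit_mcmc", "gelman_rubin"]

NA = -1

#: sd of the Normal prior on logit-scale occupancy coefficients
BETA_PRIOR_SD = 10.0


def gelman_rubin(chains) -> float:
    """Classical potential scale reduction factor for one scalar parameter.

    ``chains``: (m, n) array of m chains with n draws each.
    R-hat = sqrt(var+ / W) with W the mean within-chain variance,
    B the between-chain variance and var+ = ((n-1)/n) W + B/n.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2 or chains.shape[1] < 2:
        raise ValueError("need >= 2 chains of >= 2 equal-length draws")
    m, n = chains.shape
    W = chains.var(axis=1, ddof=1).mean()
    if W == 0:
        raise ValueError("degenerate chains: within-chain variance is zero")
    B = n * chains.mean(axis=1).var(ddof=1)
    var_plus = (n - 1) / n * W + B / n
    return float(np.sqrt(var_plus / W))


@dataclass(frozen=True)
class MCMCConfig:
    n_chains: int = 5
    n_iterations: int = 30_000
    burn_in: int = 20_000
    thin: int = 3
    seed: int = 0

    def __post_init__(self):
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be < n_iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def n_retained_per_chain(self) -> int:
        return (self.n_iterations - self.burn_in) // self.thin


#: desk-scale default used by the pipeline; the full survey configuration
#: (5 chains x 30,000, burn-in 20,000, thin 3) is MCMCConfig's default
DESK_MCMC = MCMCConfig(n_chains=3, n_iterations=6_000, burn_in=4_000, thin=2)


@dataclass
class PosteriorSamples:
    """Post-burn-in thinned draws, per chain, plus derived occupancies."""

    spec: ModelSpec
    config: MCMCConfig
    draws: dict[str, np.ndarray]      # name -> (m, d, dim)
    z: np.ndarray | None              # (m, d, S, T) uint8, or None
    rhat: dict[str, float] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        m, d = self.draws["p"].shape[:2]
        return m * d

    def flat(self, name: str) -> np.ndarray:
        """(m*d, dim) draws concatenated over chains."""
        a = self.draws[name]
        return a.reshape(-1, a.shape[-1])

    def psi_draws(self, kind: str = "finite_sample") -> np.ndarray:
        """(n_years, m*d) annual occupancy draws."""
        key = {"finite_sample": "psi_fs", "expected": "psi_exp"}[kind]
        return self.flat(key).T

    def z_flat(self) -> np.ndarray:
        if self.z is None:
            raise ValueError("latent states were not stored (store_z=False)")
        m, d, S, T = self.z.shape
        return self.z.reshape(m * d, S, T)

    def posterior_mean_params(self) -> ParameterSet:
        return ParameterSet(
            beta_psi=self.flat("beta").mean(axis=0),
            phi=self.flat("phi").mean(axis=0),
            gamma=self.flat("gamma").mean(axis=0),
            p=self.flat("p").mean(axis=0),
        )

    def max_rhat(self) -> float:
        vals = [v for v in self.rhat.values() if np.isfinite(v)]
        return max(vals) if vals else np.nan

    def to_frame(self) -> pd.DataFrame:
        """Long format: chain, iteration, parameter, value."""
        rows = []
        for name, arr in self.draws.items():
            m, d, dim = arr.shape
            for c in range(m):
                for j in range(dim):
                    rows.append(
                        pd.DataFrame(
                            {
                                "chain": c,
                                "iteration": np.arange(d),
                                "parameter": f"{name}[{j}]",
                                "value": arr[c, :, j],
                            }
                        )
                    )
        return pd.concat(rows, ignore_index=True)


def _run_chain(data, X, spec, config, rng, store_z):
    S, T, _ = data.shape
    sampled = data != NA
    n_samp = sampled.sum(axis=2).astype(float)
    n_det = (data == 1).sum(axis=2).astype(float)
    any_det = n_det > 0

    nb = spec.n_beta
    beta = rng.normal(0, 1, size=nb)
    phi = rng.uniform(0.3, 0.9, size=spec.n_phi)
    gamma = rng.uniform(0.05, 0.5, size=spec.n_gamma)
    p = rng.uniform(0.2, 0.8, size=spec.n_p)
    Z = any_det.copy().astype(np.int8)
    Z |= (rng.random((S, T)) < 0.5) & ~any_det

    n_ret = config.n_retained_per_chain
    out = {
        "beta": np.empty((n_ret, nb)),
        "phi": np.empty((n_ret, spec.n_phi)),
        "gamma": np.empty((n_ret, spec.n_gamma)),
        "p": np.empty((n_ret, spec.n_p)),
        "psi_fs": np.empty((n_ret, T)),
        "psi_exp": np.empty((n_ret, T)),
    }
    z_out = np.empty((n_ret, S, T), dtype=np.uint8) if store_z else None

    year_of_p = np.zeros(T, int) if spec.n_p == 1 else np.arange(T)
    tr_of_phi = np.zeros(max(T - 1, 1), int) if spec.n_phi == 1 else np.arange(max(T - 1, 1))
    tr_of_gam = np.zeros(max(T - 1, 1), int) if spec.n_gamma == 1 else np.arange(max(T - 1, 1))

    prop_sd = 0.3
    acc = 0
    kept = 0

    def beta_logpost(b):
        psi1 = expit(X @ b)
        psi1 = np.clip(psi1, 1e-12, 1 - 1e-12)
        ll = np.sum(Z[:, 0] * np.log(psi1) + (1 - Z[:, 0]) * np.log(1 - psi1))
        return ll - 0.5 * np.sum(b**2) / BETA_PRIOR_SD**2

    lp_beta = beta_logpost(beta)

    for it in range(1, config.n_iterations + 1):
        # --- conjugate probability updates ---------------------------------
        occ = Z == 1
        for u in range(spec.n_p):
            yrs = np.flatnonzero(year_of_p == u)
            n = n_samp[:, yrs][occ[:, yrs]].sum()
            k = n_det[:, yrs][occ[:, yrs]].sum()
            p[u] = rng.beta(1 + k, 1 + n - k)
        if T > 1:
            for u in range(spec.n_phi):
                trs = np.flatnonzero(tr_of_phi == u)
                at = occ[:, trs]
                n1 = at.sum()
                s = Z[:, trs + 1][at].sum()
                phi[u] = rng.beta(1 + s, 1 + n1 - s)
            for u in range(spec.n_gamma):
                trs = np.flatnonzero(tr_of_gam == u)
                at = ~occ[:, trs]
                n0 = at.sum()
                c = Z[:, trs + 1][at].sum()
                gamma[u] = rng.beta(1 + c, 1 + n0 - c)

        # --- Metropolis on beta -------------------------------------------
        prop = beta + rng.normal(0, prop_sd, size=nb)
        lp_prop = beta_logpost(prop)
        if np.log(rng.random()) < lp_prop - lp_beta:
            beta, lp_beta = prop, lp_prop
            acc += 1
        if it <= config.burn_in and it % 50 == 0:
            rate = acc / 50
            prop_sd *= np.exp(0.5 * (rate - 0.35))
            prop_sd = float(np.clip(prop_sd, 1e-3, 5.0))
            acc = 0

        # --- Gibbs scan of Z ----------------------------------------------
        psi1 = expit(X @ beta)
        phi_t = phi[tr_of_phi] if T > 1 else np.empty(0)
        gam_t = gamma[tr_of_gam] if T > 1 else np.empty(0)
        p_t = p[year_of_p]
        for t in range(T):
            like1 = np.exp(
                n_det[:, t] * np.log(p_t[t]) + (n_samp[:, t] - n_det[:, t]) * np.log1p(-p_t[t])
            )
            like0 = np.where(any_det[:, t], 0.0, 1.0)
            if t == 0:
                pr1, pr0 = psi1, 1.0 - psi1
            else:
                prev = Z[:, t - 1]
                pr1 = np.where(prev == 1, phi_t[t - 1], gam_t[t - 1])
                pr0 = 1.0 - pr1
            w1 = pr1 * like1
            w0 = pr0 * like0
            if t < T - 1:
                nxt = Z[:, t + 1]
                w1 *= np.where(nxt == 1, phi_t[t], 1.0 - phi_t[t])
                w0 *= np.where(nxt == 1, gam_t[t], 1.0 - gam_t[t])
            tot = w1 + w0
            prob1 = np.where(tot > 0, w1 / np.where(tot > 0, tot, 1.0), 1.0)
            Z[:, t] = rng.random(S) < prob1
        lp_beta = beta_logpost(beta)  # Z[:, 0] may have changed

        # --- retain --------------------------------------------------------
        if it > config.burn_in and (it - config.burn_in) % config.thin == 0:
            out["beta"][kept] = beta
            out["phi"][kept] = phi
            out["gamma"][kept] = gamma
            out["p"][kept] = p
            out["psi_fs"][kept] = Z.mean(axis=0)
            traj = np.empty(T)
            traj[0] = psi1.mean()
            for t in range(1, T):
                traj[t] = traj[t - 1] * phi_t[t - 1] + (1 - traj[t - 1]) * gam_t[t - 1]
            out["psi_exp"][kept] = traj
            if store_z:
                z_out[kept] = Z
            kept += 1
    return out, z_out


def fit_mcmc(
    data: np.ndarray,
    X: np.ndarray,
    spec: ModelSpec,
    config: MCMCConfig = MCMCConfig(),
    store_z: bool = True,
) -> PosteriorSamples:
    """Draw from the posterior of a dynamic occupancy model.

    data: (S, T, K) int8 with -1 = NA; X: (S, n_beta) year-1 occupancy
    design matrix.  Fully reproducible given ``config.seed``; chains get
    independent streams.  Any scalar parameter with R-hat > 1.1 attaches a
    convergence warning to the output (never fatal).
    """
    data = np.asarray(data)
    S, T, _ = data.shape
    if T != spec.n_years:
        raise ValueError(f"data has {T} years but spec.n_years={spec.n_years}")
    if X.shape != (S, spec.n_beta):
        raise ValueError(f"design matrix must be {(S, spec.n_beta)}, got {X.shape}")

    seqs = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    chains, z_chains = [], []
    for c in range(config.n_chains):
        out, z_out = _run_chain(data, X, spec, config, np.random.default_rng(seqs[c]), store_z)
        chains.append(out)
        z_chains.append(z_out)

    draws = {k: np.stack([c[k] for c in chains]) for k in chains[0]}
    z = np.stack(z_chains) if store_z else None

    rhat: dict[str, float] = {}
    warnings: list[str] = []
    if config.n_chains >= 2:
        for name in ("beta", "phi", "gamma", "p", "psi_fs"):
            arr = draws[name]
            for j in range(arr.shape[-1]):
                c2 = arr[:, :, j]
                if np.allclose(c2, c2.flat[0]):
                    rhat[f"{name}[{j}]"] = 1.0
                    continue
                try:
                    rhat[f"{name}[{j}]"] = gelman_rubin(c2)
                except ValueError:
                    rhat[f"{name}[{j}]"] = np.nan
        for k, v in rhat.items():
            if np.isfinite(v) and v > 1.1:
                warnings.append(f"R-hat {v:.3f} > 1.1 for {k}")
    return PosteriorSamples(spec=spec, config=config, draws=draws, z=z,
                            rhat=rhat, warnings=warnings)
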