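"""Goodness of fit and model comparison.

Fit is assessed with a chi-square Bayesian posterior predictive check
(BPPC): at each retained posterior draw, expected annual detection
frequencies E_t are computed conditional on that draw's latent occupancy
states and detection probability over the sampled cells; chi2_obs measures
the discrepancy of the real aggregated annual detection counts against E_t,
and chi2_new the discrepancy of a replicate dataset simulated from the same
draw (with the real NA pattern).  The Bayesian p-value is the fraction of
draws with chi2_new > chi2_obs; values near 0 or 1 indicate lack of fit.

Model comparison uses AIC for the likelihood fits and DIC for the Bayesian
refits (deviance is the marginal -2 log L, integrating the latent states).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .likelihood import forward_loglik
from .mcmc import PosteriorSamples
from .model import MLFit, ModelSpec

__all__ = [
    "annual_detection_frequencies",
    "chi2_discrepancy",
    "BPPCResult",
    "bppc",
    "dic",
    "select_model",
]

NA = -1

#: small-count stabilizer added to expected counts in the chi-square
CHI2_STABILIZER = 0.5


def annual_detection_frequencies(data: np.ndarray) -> np.ndarray:
    """Observed detections per year, aggregated over sites and periods.

    data: (S, T, K) int8 with -1 = NA; NA cells are excluded.
    """
    data = np.asarray(data)
    return (data == 1).sum(axis=(0, 2)).astype(int)


def chi2_discrepancy(observed, expected, c: float = CHI2_STABILIZER) -> float:
    """Pearson-type discrepancy sum_t (O_t - E_t)^2 / (E_t + c)."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have equal length")
    if (observed < 0).any():
        raise ValueError("observed counts must be nonnegative")
    if (expected < 0).any():
        raise ValueError("expected counts must be nonnegative")
    return float(((observed - expected) ** 2 / (expected + c)).sum())


@dataclass
class BPPCResult:
    chi2_obs: np.ndarray   # per retained draw
    chi2_new: np.ndarray
    bayesian_p: float

    def __post_init__(self):
        if not 0.0 <= self.bayesian_p <= 1.0:
            raise ValueError("bayesian_p must lie in [0, 1]")


def bppc(samples: PosteriorSamples, data: np.ndarray, seed: int = 0) -> BPPCResult:
    """Chi-square Bayesian posterior predictive check.

    Per draw: E_t = p_t * (number of sampled periods at sites occupied under
    the draw's Z); chi2_obs compares the real annual detection counts to
    E_t; a replicate with the observed NA pattern simulated from (Z, p)
    gives chi2_new against the same E_t.
    """
    data = np.asarray(data)
    S, T, K = data.shape
    z = samples.z_flat()
    if z.shape[1:] != (S, T):
        raise ValueError("posterior latent states do not match the data dimensions")
    n_samp = (data != NA).sum(axis=2).astype(float)       # (S, T)
    obs = annual_detection_frequencies(data).astype(float)

    p = samples.flat("p")                                  # (n, n_p)
    if p.shape[1] == 1:
        p = np.repeat(p, T, axis=1)
    n = z.shape[0]
    occ_effort = np.einsum("nst,st->nt", z.astype(float), n_samp)   # (n, T)
    E = p * occ_effort

    rng = np.random.default_rng(seed)
    chi2_obs = np.empty(n)
    chi2_new = np.empty(n)
    # replicate annual counts: Binomial over the sampled periods of occupied
    # sites (aggregated per year, so the check is invariant to site order)
    rep = rng.binomial(np.rint(occ_effort).astype(int), p)
    for i in range(n):
        chi2_obs[i] = chi2_discrepancy(obs, E[i])
        chi2_new[i] = chi2_discrepancy(rep[i], E[i])
    return BPPCResult(
        chi2_obs=chi2_obs,
        chi2_new=chi2_new,
        bayesian_p=float((chi2_new > chi2_obs).mean()),
    )


def dic(
    samples: PosteriorSamples,
    data: np.ndarray,
    X: np.ndarray,
    spec: ModelSpec,
    max_draws: int = 1000,
) -> float:
    """Deviance information criterion, DIC = Dbar + pD.

    D(theta) = 2 * marginal negative log-likelihood (latent states
    integrated out); Dbar averages over (an evenly strided subset of) the
    retained draws; pD = Dbar - D(theta_bar) at the posterior mean.
    """
    from .model import neg_log_likelihood

    data = np.asarray(data)
    beta = samples.flat("beta")
    phi = samples.flat("phi")
    gamma = samples.flat("gamma")
    p = samples.flat("p")
    n = beta.shape[0]
    idx = np.arange(n) if n <= max_draws else np.linspace(0, n - 1, max_draws).astype(int)

    from .model import ParameterSet

    devs = np.empty(len(idx))
    for j, i in enumerate(idx):
        theta = ParameterSet(beta_psi=beta[i], phi=phi[i], gamma=gamma[i], p=p[i])
        devs[j] = 2.0 * neg_log_likelihood(data, X, spec, theta)
    dbar = float(devs.mean())
    d_at_mean = 2.0 * neg_log_likelihood(data, X, spec, samples.posterior_mean_params())
    if not np.isfinite(d_at_mean):
        raise ValueError("non-finite deviance at the posterior mean")
    pd_ = dbar - d_at_mean
    return dbar + pd_


def select_model(fits, criterion: str = "aic") -> tuple[object, pd.DataFrame]:
    """Rank candidates by AIC (or a provided criterion value), ascending.

    ``fits``: list of MLFit, or of (model_id, criterion_value, n_params)
    tuples.  Ties break toward fewer parameters.  Returns (best, table with
    delta column).
    """
    if not fits:
        raise ValueError("no candidate models to select from")
    rows = []
    for f in fits:
        if isinstance(f, MLFit):
            rows.append((f.spec.name, getattr(f, criterion), f.n_params, f))
        else:
            mid, val, k = f[0], f[1], f[2]
            rows.append((mid, val, k, f))
    df = pd.DataFrame(rows, columns=["model", criterion, "n_params", "_obj"])
    df = df.sort_values([criterion, "n_params"], kind="stable").reset_index(drop=True)
    df[f"delta_{criterion}"] = df[criterion] - df[criterion].iloc[0]
    best = df["_obj"].iloc[0]
    return best, df.drop(columns="_obj")
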