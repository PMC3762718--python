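"""Marginal likelihood of a multi-season (dynamic) occupancy model.

The model: each site j holds a latent Bernoulli occupancy state Z_jt per
year.  Year-1 occupancy follows logit(psi1_j) = beta . x_j; between years an
occupied site stays occupied with apparent-survival probability phi_t and an
empty site is colonized with probability gamma_t; within a year (closure)
the state is fixed and each sampling period yields a detection with
probability p conditional on Z=1, never when Z=0.  The likelihood of a
site's ternary detection history marginalizes the latent chain by a scaled
forward recursion over the two states, which is exact and linear in years.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit, xlogy

__all__ = [
    "within_year_prob",
    "site_likelihood",
    "occupancy_recursion",
    "forward_loglik",
]

NA = -1


def _check_ternary(row: np.ndarray) -> np.ndarray:
    row = np.asarray(row, dtype=float)
    valid = np.isnan(row) | np.isin(row, (0.0, 1.0, float(NA)))
    if not valid.all():
        raise ValueError("detection history entries must be 0, 1 or NA")
    return np.where(np.isnan(row), NA, row).astype(np.int8)


def within_year_prob(history_row, p: float, z: int) -> float:
    """P(one year's detection history | occupancy state z).

    Conditional on occupancy (z=1) each non-NA entry is an independent
    Bernoulli(p); conditional on absence (z=0) a detection is impossible.
    An all-NA row carries no information and has probability 1 for either z.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if z not in (0, 1):
        raise ValueError("z must be 0 or 1")
    row = _check_ternary(np.asarray(history_row))
    obs = row[row != NA]
    if obs.size == 0:
        return 1.0
    if z == 0:
        return 0.0 if (obs == 1).any() else 1.0
    k = int((obs == 1).sum())
    n = obs.size
    return float(np.exp(xlogy(k, p) + xlogy(n - k, 1.0 - p)))


def occupancy_recursion(psi_t: float, phi_t: float, gamma_t: float) -> float:
    """psi_{t+1} = psi_t * phi_t + (1 - psi_t) * gamma_t."""
    for name, v in (("psi_t", psi_t), ("phi_t", phi_t), ("gamma_t", gamma_t)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    return psi_t * phi_t + (1.0 - psi_t) * gamma_t


def _year_log_f(n_samp: np.ndarray, n_det: np.ndarray, p: np.ndarray):
    """Per site-year log P(history | z) for z=1 and z=0.

    n_samp/n_det: (S, T) sampled-cell and detection counts; p: (T,) or (S, T).
    """
    p = np.clip(np.asarray(p, dtype=float), 0.0, 1.0)
    log_f1 = xlogy(n_det, p) + xlogy(n_samp - n_det, 1.0 - p)
    log_f0 = np.where(n_det > 0, -np.inf, 0.0)
    return log_f1, log_f0


def forward_loglik(
    data: np.ndarray,
    psi1: np.ndarray,
    phi: np.ndarray,
    gamma: np.ndarray,
    p: np.ndarray,
) -> np.ndarray:
    """Per-site marginal log-likelihood, vectorized across sites.

    data: (S, T, K) int8 with -1 = NA; psi1: (S,); phi, gamma: (T-1,) or
    scalar-broadcastable; p: (T,) or (S, T).  Returns (S,) log-likelihoods.
    """
    data = np.asarray(data)
    S, T, _ = data.shape
    sampled = data != NA
    n_samp = sampled.sum(axis=2)
    n_det = (data == 1).sum(axis=2)
    if np.ndim(p) == 1:
        p = np.broadcast_to(np.asarray(p, float), (S, T))
    log_f1, log_f0 = _year_log_f(n_samp, n_det, p)
    f1, f0 = np.exp(log_f1), np.exp(log_f0)

    psi1 = np.asarray(psi1, dtype=float)
    phi = np.broadcast_to(np.asarray(phi, float), (T - 1,)) if T > 1 else np.empty(0)
    gamma = np.broadcast_to(np.asarray(gamma, float), (T - 1,)) if T > 1 else np.empty(0)

    a1 = psi1 * f1[:, 0]
    a0 = (1.0 - psi1) * f0[:, 0]
    loglik = np.zeros(S)
    for t in range(1, T):
        b1 = (a1 * phi[t - 1] + a0 * gamma[t - 1]) * f1[:, t]
        b0 = (a1 * (1.0 - phi[t - 1]) + a0 * (1.0 - gamma[t - 1])) * f0[:, t]
        c = b1 + b0
        # scale to dodge underflow; c == 0 means an impossible history
        with np.errstate(divide="ignore", invalid="ignore"):
            a1, a0 = np.where(c > 0, b1 / c, 0.0), np.where(c > 0, b0 / c, 0.0)
        loglik += np.where(c > 0, np.log(np.where(c > 0, c, 1.0)), -np.inf)
    total = a1 + a0
    with np.errstate(divide="ignore"):
        loglik += np.where(total > 0, np.log(np.where(total > 0, total, 1.0)), -np.inf)
    return loglik


def site_likelihood(histories, psi1: float, phi, gamma, p) -> float:
    """Marginal probability of one site's multi-year detection history.

    ``histories``: sequence of per-year ternary rows (NA allowed, possibly
    ragged); ``p`` a scalar or per-year vector; ``phi``/``gamma`` scalars or
    per-transition vectors.
    """
    rows = [_check_ternary(np.asarray(h)) for h in histories]
    T = len(rows)
    K = max(r.size for r in rows)
    data = np.full((1, T, K), NA, dtype=np.int8)
    for t, r in enumerate(rows):
        data[0, t, : r.size] = r
    p_arr = np.broadcast_to(np.asarray(p, float), (T,))
    phi_arr = np.broadcast_to(np.asarray(phi, float), (T - 1,)) if T > 1 else np.empty(0)
    gam_arr = np.broadcast_to(np.asarray(gamma, float), (T - 1,)) if T > 1 else np.empty(0)
    if not 0.0 <= psi1 <= 1.0:
        raise ValueError("psi1 must lie in [0, 1]")
    ll = forward_loglik(data, np.array([psi1]), phi_arr, gam_arr, p_arr)[0]
    return float(np.exp(ll))
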