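"""Model structures and maximum-likelihood fitting.

A ``ModelSpec`` names which pieces of the dynamic occupancy model carry
structure: covariates on year-1 occupancy (logit link), and whether apparent
survival phi, colonization gamma and detection p are constant or
year-specific.  The candidate set used for per-species selection holds the
six structures that describe tropical-forest camera-trap species well:
null-type models with or without year effects, and year-1 occupancy driven
by elevation, elevation+canopy or elevation+edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit
from statsmodels.tools.numdiff import approx_hess

from .likelihood import forward_loglik

__all__ = [
    "ModelSpec",
    "ParameterSet",
    "MLFit",
    "neg_log_likelihood",
    "fit_ml",
    "candidate_specs",
]

_MODES = ("constant", "by_year")


@dataclass(frozen=True)
class ModelSpec:
    psi1_covariates: tuple[str, ...] = ()
    gamma_mode: str = "by_year"
    phi_mode: str = "by_year"
    p_mode: str = "constant"
    n_years: int = 5
    n_periods: int = 15

    def __post_init__(self):
        for m in (self.gamma_mode, self.phi_mode, self.p_mode):
            if m not in _MODES:
                raise ValueError(f"mode must be one of {_MODES}, got {m!r}")
        if self.n_years < 1 or self.n_periods < 1:
            raise ValueError("n_years and n_periods must be >= 1")

    @property
    def n_beta(self) -> int:
        return 1 + len(self.psi1_covariates)

    @property
    def n_phi(self) -> int:
        return max(self.n_years - 1, 0) if self.phi_mode == "by_year" else 1

    @property
    def n_gamma(self) -> int:
        return max(self.n_years - 1, 0) if self.gamma_mode == "by_year" else 1

    @property
    def n_p(self) -> int:
        return self.n_years if self.p_mode == "by_year" else 1

    @property
    def n_params(self) -> int:
        k = self.n_beta + self.n_p
        if self.n_years > 1:
            k += self.n_phi + self.n_gamma
        return k

    @property
    def name(self) -> str:
        cov = "+".join(self.psi1_covariates) if self.psi1_covariates else "."
        tag = lambda m: "year" if m == "by_year" else "."
        return (
            f"psi({cov})gamma({tag(self.gamma_mode)})"
            f"phi({tag(self.phi_mode)})p({tag(self.p_mode)})"
        )


@dataclass
class ParameterSet:
    """Natural-scale parameter values conforming to a ModelSpec."""

    beta_psi: np.ndarray          # logit-scale coefficients, intercept first
    phi: np.ndarray               # (n_years-1,) or (1,)
    gamma: np.ndarray             # (n_years-1,) or (1,)
    p: np.ndarray                 # (n_years,) or (1,)

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

    def expand(self, spec: ModelSpec, X: np.ndarray):
        """Broadcast to per-site psi1, per-transition phi/gamma, per-year p."""
        psi1 = expit(X @ self.beta_psi)
        T = spec.n_years
        phi = np.broadcast_to(self.phi, (max(T - 1, 0),)) if T > 1 else np.empty(0)
        gamma = np.broadcast_to(self.gamma, (max(T - 1, 0),)) if T > 1 else np.empty(0)
        p = np.broadcast_to(self.p, (T,))
        return psi1, phi, gamma, p


def neg_log_likelihood(data: np.ndarray, X: np.ndarray, spec: ModelSpec, theta: ParameterSet) -> float:
    """-sum over sites of the marginal log site likelihood.

    data: (S, T, K) int8 with -1 = NA; X: (S, n_beta) design matrix for
    year-1 occupancy (intercept column included).  All-NA sites contribute 0.
    """
    psi1, phi, gamma, p = theta.expand(spec, X)
    ll = forward_loglik(data, psi1, phi, gamma, p)
    if not np.isfinite(ll).all():
        bad = int(np.flatnonzero(~np.isfinite(ll))[0])
        raise ValueError(f"non-finite site likelihood at site index {bad}")
    return float(-ll.sum())


# ---------------------------------------------------------------------------
# unconstrained packing

_BOUND = 15.0  # |logit| cap: keeps probabilities off the exact boundary


def _unpack(theta: np.ndarray, spec: ModelSpec) -> ParameterSet:
    b = spec.n_beta
    beta = theta[:b]
    i = b
    if spec.n_years > 1:
        phi = expit(theta[i : i + spec.n_phi]); i += spec.n_phi
        gamma = expit(theta[i : i + spec.n_gamma]); i += spec.n_gamma
    else:
        phi = np.array([0.5]); gamma = np.array([0.5])
    p = expit(theta[i : i + spec.n_p])
    return ParameterSet(beta_psi=beta, phi=phi, gamma=gamma, p=p)


def _pack(params: ParameterSet, spec: ModelSpec) -> np.ndarray:
    clip = lambda v: logit(np.clip(v, 1e-6, 1 - 1e-6))
    parts = [params.beta_psi]
    if spec.n_years > 1:
        parts += [clip(params.phi), clip(params.gamma)]
    parts.append(clip(params.p))
    return np.concatenate(parts)


@dataclass
class MLFit:
    spec: ModelSpec
    params: ParameterSet
    se: dict = field(default_factory=dict)   # unconstrained-scale SEs by block
    loglik: float = np.nan
    aic: float = np.nan
    n_params: int = 0
    converged: bool = False
    boundary: bool = False
    theta: np.ndarray | None = None
    theta_cov: np.ndarray | None = None

    def summary(self) -> str:
        flags = ("" if self.converged else " [NOT CONVERGED]") + (
            " [boundary]" if self.boundary else ""
        )
        return (
            f"{self.spec.name}: logL={self.loglik:.3f} AIC={self.aic:.2f} "
            f"k={self.n_params}{flags}"
        )


def fit_ml(
    data: np.ndarray,
    X: np.ndarray,
    spec: ModelSpec,
    n_starts: int = 5,
    seed: int = 0,
) -> MLFit:
    """Maximize the marginal likelihood on the unconstrained scale.

    Quasi-Newton (L-BFGS-B) from a moment-based start plus ``n_starts - 1``
    seeded random restarts; standard errors from the inverse observed
    information at the optimum.  Non-convergence and boundary estimates are
    flagged, never silent.
    """
    data = np.asarray(data)
    sampled = data != -1
    if not sampled.any():
        raise ValueError("no sampled periods in the data")
    S, T, _ = data.shape
    if T != spec.n_years:
        raise ValueError(f"data has {T} years but spec.n_years={spec.n_years}")
    if X.shape != (S, spec.n_beta):
        raise ValueError(f"design matrix must be {(S, spec.n_beta)}, got {X.shape}")

    def objective(theta):
        try:
            return neg_log_likelihood(data, X, spec, _unpack(theta, spec))
        except ValueError:
            return 1e12

    # moment start: naive occupancy and raw detection frequency
    naive1 = float(((data[:, 0, :] == 1).any(axis=1)).mean())
    freq = float((data == 1).sum() / max(sampled.sum(), 1))
    start = _pack(
        ParameterSet(
            beta_psi=np.r_[logit(np.clip(naive1, 0.05, 0.95)), np.zeros(spec.n_beta - 1)],
            phi=np.full(spec.n_phi, 0.7),
            gamma=np.full(spec.n_gamma, 0.2),
            p=np.full(spec.n_p, np.clip(freq * 2, 0.05, 0.95)),
        ),
        spec,
    )
    rng = np.random.default_rng(seed)
    starts = [start] + [start + rng.normal(0, 1.0, size=start.size) for _ in range(n_starts - 1)]
    bounds = [(-25.0, 25.0)] * spec.n_beta + [(-_BOUND, _BOUND)] * (start.size - spec.n_beta)

    best = None
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"maxiter": 500, "ftol": 1e-10, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res

    theta = best.x
    params = _unpack(theta, spec)
    k = spec.n_params
    nll = best.fun
    probs = np.concatenate([params.phi, params.gamma, params.p]) if T > 1 else params.p
    boundary = bool((probs < 1e-3).any() or (probs > 1 - 1e-3).any())

    se: dict[str, np.ndarray] = {}
    theta_cov = None
    try:
        H = approx_hess(theta, objective)
        theta_cov = np.linalg.inv(H)
        d = np.sqrt(np.clip(np.diag(theta_cov), 0, np.inf))
        i = spec.n_beta
        se["beta_psi"] = d[:i]
        if T > 1:
            se["phi"] = d[i : i + spec.n_phi]; i += spec.n_phi
            se["gamma"] = d[i : i + spec.n_gamma]; i += spec.n_gamma
        se["p"] = d[i : i + spec.n_p]
    except np.linalg.LinAlgError:
        pass

    return MLFit(
        spec=spec,
        params=params,
        se=se,
        loglik=-nll,
        aic=2.0 * k + 2.0 * nll,
        n_params=k,
        converged=bool(best.success),
        boundary=boundary,
        theta=theta,
        theta_cov=theta_cov,
    )


def candidate_specs(
    n_years: int,
    n_periods: int,
    elevation: str = "elevation",
    canopy: str = "canopy_height",
    edge: str = "edge_distance",
) -> list[ModelSpec]:
    """The six candidate structures fitted per species.

    Null-type structures (no occupancy covariates, with or without year
    effects on phi/gamma/p) plus additive year-1 occupancy covariates.
    """
    mk = lambda cov, g, f, p: ModelSpec(
        psi1_covariates=cov, gamma_mode=g, phi_mode=f, p_mode=p,
        n_years=n_years, n_periods=n_periods,
    )
    return [
        mk((), "constant", "constant", "constant"),
        mk((), "by_year", "by_year", "constant"),
        mk((), "by_year", "by_year", "by_year"),
        mk((elevation,), "by_year", "by_year", "constant"),
        mk((elevation, canopy), "by_year", "by_year", "constant"),
        mk((elevation, edge), "by_year", "by_year", "constant"),
    ]
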