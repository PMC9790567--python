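"""MAP predictive priors and prior effective sample size (ESS).

The predictive distribution of the new trial's (intercept, baseline
effect) is obtained draw-by-draw from the posterior of the grand means
and between-study covariance of a historical-only hierarchical fit: for
each posterior draw of (mu0, mu1, tau0, tau1, rho), one (beta0*, beta1*)
is drawn from the implied (bi)variate normal.  The moment-matched normal
summary of those draws defines the MAP prior.

The amount of borrowed information is quantified by the variance-ratio
ESS: the ratio between the posterior variance of the coefficient under a
zero-heterogeneity (pooled) analysis of the historical controls and the
MAP-prior variance, times the total number of historical controls.

A fixed-heterogeneity two-stage closed form (inverse-variance weighting
of per-study estimates) is provided as an analytic oracle for the
one-stage machinery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from ._gibbs import McmcSettings
from .data import IPDDataset
from .model import AncovaMAP, AncovaMAPResults, MAP_METHODS
from .priors import PriorConfig

__all__ = [
    "MapPrior",
    "EssResult",
    "map_predictive",
    "predictive_from_hyper_draws",
    "two_stage_univariate_map",
    "prior_ess",
    "ess_workflow",
]


@dataclass
class MapPrior:
    """Predictive distribution of the new trial's control-arm parameters.

    ``draws`` has shape (n, 2) for bivariate methods and (n, 1) for the
    intercept-only univariate methods.  ``mean``/``cov`` are the
    moment-matched normal summary; ``normality`` holds per-parameter
    (skewness, excess kurtosis) of the draws as a diagnostic of the
    normal approximation underlying the variance-ratio ESS.
    """

    method: str
    parameters: tuple[str, ...]
    draws: np.ndarray
    n_historical: int
    mean: np.ndarray = field(init=False)
    cov: np.ndarray = field(init=False)
    normality: dict = field(init=False)

    def __post_init__(self):
        d = np.atleast_2d(self.draws)
        if d.shape[0] < d.shape[1]:
            raise ValueError("need more draws than parameters")
        self.mean = d.mean(axis=0)
        self.cov = np.atleast_2d(np.cov(d, rowvar=False, ddof=1))
        # symmetric PSD by construction of np.cov; guard tiny asymmetry
        self.cov = 0.5 * (self.cov + self.cov.T)
        self.normality = {
            p: {"skewness": float(sps.skew(d[:, j])),
                "excess_kurtosis": float(sps.kurtosis(d[:, j]))}
            for j, p in enumerate(self.parameters)
        }

    def variance(self, parameter: str) -> float:
        j = self.parameters.index(parameter)
        return float(self.cov[j, j])

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "parameters": list(self.parameters),
            "mean": self.mean.tolist(),
            "cov": self.cov.tolist(),
            "n_historical": self.n_historical,
            "normality": self.normality,
        }


def predictive_from_hyper_draws(
    mu0, tau0, mu1=None, tau1=None, rho=None, rng: np.random.Generator | None = None,
) -> np.ndarray:
    """One predictive (beta0*, beta1*) draw per posterior draw of the
    hyperparameters.  Vectorized; returns (n, 2) or (n, 1)."""
    rng = rng or np.random.default_rng()
    mu0 = np.asarray(mu0, float)
    tau0 = np.asarray(tau0, float)
    z0 = rng.standard_normal(mu0.shape)
    b0 = mu0 + tau0 * z0
    if mu1 is None:
        return b0[:, None]
    mu1 = np.asarray(mu1, float)
    tau1 = np.asarray(tau1, float)
    rho = np.zeros_like(mu0) if rho is None else np.asarray(rho, float)
    z1 = rng.standard_normal(mu0.shape)
    b1 = mu1 + tau1 * (rho * z0 + np.sqrt(1.0 - rho**2) * z1)
    return np.column_stack([b0, b1])


def map_predictive(results: AncovaMAPResults, seed: int | None = None) -> MapPrior:
    """MAP predictive prior from a historical-only hierarchical fit."""
    if results.method not in MAP_METHODS:
        raise ValueError(f"MAP predictive requires one of {MAP_METHODS}")
    if results.model.include_new_trial:
        raise ValueError("MAP prior must be built from a design-phase (historical-only) fit")
    rng = np.random.default_rng(seed)
    mu0 = results.flat("mu0")
    tau0 = results.flat("tau0")
    if results.method in ("mmap_cor", "mmap_ind"):
        mu1 = results.flat("mu1")
        tau1 = results.flat("tau1")
        rho = results.flat("rho") if results.method == "mmap_cor" else None
        draws = predictive_from_hyper_draws(mu0, tau0, mu1, tau1, rho, rng)
        params = ("intercept", "baseline_effect")
    else:
        draws = predictive_from_hyper_draws(mu0, tau0, rng=rng)
        params = ("intercept",)
    N = results.model.dataset.n_historical_controls
    return MapPrior(results.method, params, draws, N)


def two_stage_univariate_map(estimates, tau0: float) -> tuple[float, float]:
    """Closed-form univariate MAP prior for a known between-study SD.

    ``estimates`` is a sequence of (estimate, standard_error) pairs from
    the per-study fits.  With inverse-variance weights
    w_j = 1/(se_j^2 + tau0^2), the grand mean is normal with mean
    sum(w b)/sum(w) and variance 1/sum(w); the predictive (MAP prior)
    variance adds the between-study variance tau0^2.
    Returns (mean, variance) of the MAP prior.
    """
    est = np.asarray([e for e, _ in estimates], float)
    se = np.asarray([s for _, s in estimates], float)
    if est.size == 0:
        raise ValueError("need at least one study estimate")
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    if tau0 < 0:
        raise ValueError("tau0 must be non-negative")
    w = 1.0 / (se**2 + tau0**2)
    mean = float((w * est).sum() / w.sum())
    var = float(1.0 / w.sum() + tau0**2)
    return mean, var


def prior_ess(V0: float, V_tau: float, N: int) -> float:
    """Variance-ratio prior effective sample size: (V0 / V_tau) * N."""
    if not (V0 > 0 and V_tau > 0):
        raise ValueError("variances must be positive")
    if N < 1:
        raise ValueError("N must be >= 1")
    return (V0 / V_tau) * N


@dataclass(frozen=True)
class EssResult:
    """Prior ESS for one borrowed parameter."""

    parameter: str          # "intercept" | "baseline_effect"
    V0: float               # posterior variance under the tau=0 pooled fit
    V_tau: float            # MAP-prior (predictive) variance
    N: int                  # total historical controls
    ess: float
    normality: dict | None = None


def ess_workflow(
    dataset: IPDDataset,
    method: str = "mmap_cor",
    priors: PriorConfig | None = None,
    settings: McmcSettings | None = None,
    seed: int | None = None,
) -> list[EssResult]:
    """Design-phase ESS: fit the MAP model to the historical controls,
    build the predictive prior, and compare its variance against a
    zero-heterogeneity (pooled historical controls) reference fit."""
    hist = dataset.historical_only()
    settings = settings or McmcSettings()
    model = AncovaMAP(hist, method=method, priors=priors, include_new_trial=False)
    res = model.fit(settings=settings, seed=seed)
    prior = map_predictive(res, seed=None if seed is None else seed + 1)

    # tau = 0 reference: single pooled ANCOVA of the stacked controls
    ref = AncovaMAP(hist, method="pooling", priors=model.priors, include_new_trial=False)
    ref_res = ref.fit(settings=settings, seed=None if seed is None else seed + 2)
    N = hist.n_historical_controls

    out = []
    pairs = [("intercept", "beta0")]
    if method in ("mmap_cor", "mmap_ind"):
        pairs.append(("baseline_effect", "beta1"))
    for pname, ref_param in pairs:
        V_tau = prior.variance(pname)
        V0 = float(ref_res.flat(ref_param).var(ddof=1))
        out.append(EssResult(pname, V0, V_tau, N, prior_ess(V0, V_tau, N),
                             prior.normality[pname]))
    return out
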