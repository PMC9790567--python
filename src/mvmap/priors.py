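"""Hyperprior configuration for the hierarchical ANCOVA models.

The only data-driven part of the prior is the scale of the heterogeneity
prior for the between-study standard deviations (tau0, tau1).  Following
standard practice for meta-analytic-predictive priors, "large"
between-study heterogeneity for a regression coefficient is taken to be a
between-study SD equal to the within-study SD of that coefficient
(study-specific standard error times sqrt(n)); the heterogeneity prior is
then scaled so that a small tail probability (default 5%) sits above the
largest within-study SD over the historical trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from math import sqrt

import numpy as np
from scipy import stats

from .data import StudyAncovaFit

__all__ = [
    "HeterogeneityPrior",
    "NormalPrior",
    "InverseGammaPrior",
    "UniformPrior",
    "PriorConfig",
    "within_study_sd",
    "heterogeneity_scale",
    "default_prior_config",
]


@dataclass(frozen=True)
class NormalPrior:
    mean: float
    variance: float

    def __post_init__(self):
        if self.variance <= 0:
            raise ValueError("variance must be positive")


@dataclass(frozen=True)
class InverseGammaPrior:
    shape: float
    rate: float

    def __post_init__(self):
        if self.shape <= 0 or self.rate <= 0:
            raise ValueError("shape and rate must be positive")


@dataclass(frozen=True)
class UniformPrior:
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.upper:
            raise ValueError("need lower < upper")


_HN_FAMILIES = ("half_normal", "exponential", "uniform")


@dataclass(frozen=True)
class HeterogeneityPrior:
    """Prior on a between-study SD (tau >= 0).

    family : half_normal | exponential | uniform.
    scale : HN scale / exponential scale / uniform upper bound.
    """

    family: str
    scale: float

    def __post_init__(self):
        if self.family not in _HN_FAMILIES:
            raise ValueError(f"family must be one of {_HN_FAMILIES}")
        if not self.scale > 0:
            raise ValueError("scale must be positive")

    def quantile(self, q: float) -> float:
        if self.family == "half_normal":
            return float(stats.halfnorm(scale=self.scale).ppf(q))
        if self.family == "exponential":
            return float(stats.expon(scale=self.scale).ppf(q))
        return float(q * self.scale)

    def sf(self, x: float) -> float:
        """P(tau > x)."""
        if self.family == "half_normal":
            return float(stats.halfnorm(scale=self.scale).sf(x))
        if self.family == "exponential":
            return float(stats.expon(scale=self.scale).sf(x))
        return float(np.clip(1.0 - x / self.scale, 0.0, 1.0))


def within_study_sd(se: float, n: int) -> float:
    """Within-study SD of a regression coefficient: se * sqrt(n)."""
    if not se > 0:
        raise ValueError("se must be positive")
    if not n >= 1:
        raise ValueError("n must be >= 1")
    return se * sqrt(n)


def heterogeneity_scale(
    within_sds,
    family: str = "half_normal",
    tail_prob: float = 0.05,
) -> HeterogeneityPrior:
    """Scale the heterogeneity prior so P(tau > max(within_sds)) = tail_prob.

    Solves Quantile(family, 1 - tail_prob; scale) = max(within_sds).
    """
    within_sds = np.asarray(list(within_sds), dtype=float)
    if within_sds.size == 0:
        raise ValueError("need at least one within-study SD")
    if not (0.0 < tail_prob < 1.0):
        raise ValueError("tail_prob must lie in (0, 1)")
    if not np.all(within_sds > 0):
        raise ValueError("within-study SDs must be positive")
    big = float(within_sds.max())
    q = 1.0 - tail_prob
    if family == "half_normal":
        scale = big / stats.halfnorm.ppf(q)
    elif family == "exponential":
        scale = big / stats.expon.ppf(q)
    elif family == "uniform":
        scale = big / q
    else:
        raise ValueError(f"family must be one of {_HN_FAMILIES}")
    return HeterogeneityPrior(family, float(scale))


@dataclass(frozen=True)
class PriorConfig:
    """Complete hyperprior configuration for all analysis models.

    Defaults follow common weakly-informative choices for Bayesian ANCOVA:
    diffuse normals for the grand means and treatment effect, a vague
    inverse-gamma for per-study error variances, a negative-half uniform
    for the between-study correlation, and heterogeneity priors that must
    be supplied (they are data-scale dependent).
    """

    tau0_prior: HeterogeneityPrior
    tau1_prior: HeterogeneityPrior
    mu0_prior: NormalPrior = field(default_factory=lambda: NormalPrior(0.0, 1e4))
    mu1_prior: NormalPrior = field(default_factory=lambda: NormalPrior(0.0, 1e2))
    lambda_prior: NormalPrior = field(default_factory=lambda: NormalPrior(0.0, 1e4))
    sigma2_prior: InverseGammaPrior = field(default_factory=lambda: InverseGammaPrior(1e-3, 1e-3))
    rho_prior: UniformPrior = field(default_factory=lambda: UniformPrior(-1.0, 0.0))
    #: prior for study-specific baseline effects when they are modelled as
    #: independent fixed effects (separate-slopes univariate model)
    beta1_fixed_prior: NormalPrior = field(default_factory=lambda: NormalPrior(0.0, 1e2))

    def __post_init__(self):
        if not (-1.0 <= self.rho_prior.lower < self.rho_prior.upper <= 1.0):
            raise ValueError("rho prior bounds must satisfy -1 <= lower < upper <= 1")

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PriorConfig":
        return cls(
            tau0_prior=HeterogeneityPrior(**d["tau0_prior"]),
            tau1_prior=HeterogeneityPrior(**d["tau1_prior"]),
            mu0_prior=NormalPrior(**d.get("mu0_prior", {"mean": 0.0, "variance": 1e4})),
            mu1_prior=NormalPrior(**d.get("mu1_prior", {"mean": 0.0, "variance": 1e2})),
            lambda_prior=NormalPrior(**d.get("lambda_prior", {"mean": 0.0, "variance": 1e4})),
            sigma2_prior=InverseGammaPrior(**d.get("sigma2_prior", {"shape": 1e-3, "rate": 1e-3})),
            rho_prior=UniformPrior(**d.get("rho_prior", {"lower": -1.0, "upper": 0.0})),
            beta1_fixed_prior=NormalPrior(
                **d.get("beta1_fixed_prior", {"mean": 0.0, "variance": 1e2})
            ),
        )


def simulation_grid_priors() -> PriorConfig:
    """Fixed priors for the operating-characteristics simulation grid:
    half-normal heterogeneity scales 10 (intercept) and 0.36 (baseline
    effect), i.e. 95th percentiles at the large-heterogeneity values 20
    and 0.72 after rounding."""
    return PriorConfig(
        tau0_prior=HeterogeneityPrior("half_normal", 10.0),
        tau1_prior=HeterogeneityPrior("half_normal", 0.36),
    )


def default_prior_config(
    fits: list[StudyAncovaFit],
    family: str = "half_normal",
    tail_prob: float = 0.05,
    **overrides,
) -> PriorConfig:
    """Assemble the full prior configuration from per-study ANCOVA fits.

    tau0/tau1 heterogeneity priors are elicited from the within-study SDs
    of the intercept and baseline-effect estimates; everything else uses
    the package defaults unless overridden (keyword names match
    PriorConfig fields).
    """
    if not fits:
        raise ValueError("need at least one study fit")
    sd0 = [within_study_sd(f.se_b0, f.n) for f in fits]
    sd1 = [within_study_sd(f.se_b1, f.n) for f in fits]
    cfg = dict(
        tau0_prior=heterogeneity_scale(sd0, family, tail_prob),
        tau1_prior=heterogeneity_scale(sd1, family, tail_prob),
    )
    cfg.update(overrides)
    return PriorConfig(**cfg)
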