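"""Batched Gibbs samplers for the hierarchical ANCOVA models.

All models here are linear-Gaussian given the variance parameters, so the
posterior is explored with a blocked Gibbs sampler:

* study-specific coefficients, the treatment effect, the grand means and
  the per-study error variances have conjugate full conditionals;
* the between-study SDs (tau0, tau1) and correlation (rho) are updated by
  adaptive random-walk Metropolis on transformed scales, followed by an
  ancillarity-sufficiency interweaving (ASIS) step that re-draws
  (mu, tau) in the non-centred parameterization, where the conditionals
  are (truncated) normal.  The interweaving removes the funnel-shaped
  slow mixing that plain centred Gibbs exhibits when the heterogeneity is
  close to zero -- exactly the regime where borrowing is strongest.

Everything is vectorized over a leading batch axis, so thousands of
chains (e.g. all replicates of a simulation scenario at once) advance in
lock-step at the cost of a few numpy operations per update.  Shapes:
per-batch scalars are (K,), per-study quantities are (K, S) with the new
trial, when present, in the last column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtr, ndtri

from .priors import PriorConfig

__all__ = ["SuffStats", "McmcSettings", "sample_hierarchical", "sample_flat", "split_rhat"]

_TAU_FLOOR = 1e-8
_SIG_LO, _SIG_HI = 1e-12, 1e12


@dataclass
class McmcSettings:
    """MCMC protocol: number of chains, burn-in and kept iterations per
    chain.  The default mirrors a 4-chain run with 1000 burn-in and
    16,000 total kept draws."""

    chains: int = 4
    warmup: int = 1000
    draws: int = 4000          # kept per chain
    thin: int = 1
    seed: int | None = None
    rhat_threshold: float = 1.01

    def __post_init__(self):
        if self.chains < 1:
            raise ValueError("chains must be >= 1")
        if self.warmup < 0 or self.draws < 1 or self.thin < 1:
            raise ValueError("invalid MCMC protocol")


@dataclass
class SuffStats:
    """Per-study sufficient statistics of the design ``[1, yB, trt]``.

    All arrays have shape (K, S): batch x study.  ``include_new`` marks
    the last column as the new two-arm trial.
    """

    n: np.ndarray
    syb: np.ndarray     # sum yB
    syb2: np.ndarray    # sum yB^2
    st: np.ndarray      # sum trt
    sybt: np.ndarray    # sum yB*trt
    stt: np.ndarray     # sum trt^2 (= st for 0/1 coding)
    sy: np.ndarray      # sum y
    syyb: np.ndarray    # sum y*yB
    syt: np.ndarray     # sum y*trt
    yty: np.ndarray     # sum y^2
    include_new: bool = False

    @property
    def K(self) -> int:
        return self.n.shape[0]

    @property
    def S(self) -> int:
        return self.n.shape[1]

    @classmethod
    def from_arrays(cls, study_arrays, include_new: bool = False) -> "SuffStats":
        """Build from a list over the batch axis of lists over studies of
        (yb, y, trt) observation arrays."""
        K = len(study_arrays)
        S = len(study_arrays[0])
        out = {k: np.zeros((K, S)) for k in
               ("n", "syb", "syb2", "st", "sybt", "stt", "sy", "syyb", "syt", "yty")}
        for i, studies in enumerate(study_arrays):
            for j, (yb, y, trt) in enumerate(studies):
                yb = np.asarray(yb, float)
                y = np.asarray(y, float)
                trt = np.asarray(trt, float)
                out["n"][i, j] = yb.size
                out["syb"][i, j] = yb.sum()
                out["syb2"][i, j] = (yb * yb).sum()
                out["st"][i, j] = trt.sum()
                out["sybt"][i, j] = (yb * trt).sum()
                out["stt"][i, j] = (trt * trt).sum()
                out["sy"][i, j] = y.sum()
                out["syyb"][i, j] = (y * yb).sum()
                out["syt"][i, j] = (y * trt).sum()
                out["yty"][i, j] = (y * y).sum()
        return cls(include_new=include_new, **out)

    def repeat(self, times: int) -> "SuffStats":
        """Repeat each batch element ``times`` (one copy per chain)."""
        kw = {k: np.repeat(getattr(self, k), times, axis=0)
              for k in ("n", "syb", "syb2", "st", "sybt", "stt", "sy", "syyb", "syt", "yty")}
        return SuffStats(include_new=self.include_new, **kw)

    def stacked(self) -> "SuffStats":
        """Collapse all studies into a single pooled pseudo-study."""
        kw = {k: getattr(self, k).sum(axis=1, keepdims=True)
              for k in ("n", "syb", "syb2", "st", "sybt", "stt", "sy", "syyb", "syt", "yty")}
        return SuffStats(include_new=self.include_new, **kw)


# ---------------------------------------------------------------------
# small vectorized samplers
# ---------------------------------------------------------------------

def _mvn2(rng, pa, pb, pc, r0, r1):
    """Sample from the bivariate normal with precision [[pa,pb],[pb,pc]]
    and precision-weighted mean (r0, r1).  Elementwise over any shape."""
    det = pa * pc - pb * pb
    v00 = pc / det
    v01 = -pb / det
    v11 = pa / det
    m0 = v00 * r0 + v01 * r1
    m1 = v01 * r0 + v11 * r1
    l11 = np.sqrt(v00)
    l21 = v01 / l11
    l22 = np.sqrt(np.maximum(v11 - l21 * l21, 0.0))
    z0 = rng.standard_normal(m0.shape)
    z1 = rng.standard_normal(m0.shape)
    return m0 + l11 * z0, m1 + l21 * z0 + l22 * z1


def _norm(rng, prec, rhs):
    return rhs / prec + rng.standard_normal(np.shape(prec)) / np.sqrt(prec)


def _trunc_norm(rng, m, sd, lo=0.0, hi=np.inf):
    """Truncated normal via upper-tail inverse CDF (accurate far in the
    tail, vectorized)."""
    t_lo = ndtr((m - lo) / sd)                      # P(X > lo)
    t_hi = ndtr((m - hi) / sd) if np.isfinite(hi) else 0.0
    u = rng.random(np.shape(m))
    t = np.clip(t_hi + u * (t_lo - t_hi), 1e-300, 1.0)
    x = m - sd * ndtri(t)
    return np.clip(x, lo, hi)


def _tau_logprior(tau, family, scale):
    if family == "half_normal":
        return -0.5 * (tau / scale) ** 2
    if family == "exponential":
        return -tau / scale
    # uniform on [0, scale]
    return np.where(tau <= scale, 0.0, -np.inf)


def _tau_conditional_draw(rng, prec_lik, rhs_lik, family, scale):
    """Non-centred conjugate draw of a between-study SD given its
    standardized deviates: normal likelihood x {half-normal, exponential,
    uniform} prior, all reducing to truncated normals."""
    if family == "half_normal":
        prec = prec_lik + 1.0 / scale**2
        return _trunc_norm(rng, rhs_lik / prec, 1.0 / np.sqrt(prec))
    if family == "exponential":
        prec = prec_lik
        m = (rhs_lik - 1.0 / scale) / prec
        return _trunc_norm(rng, m, 1.0 / np.sqrt(prec))
    return _trunc_norm(rng, rhs_lik / prec_lik, 1.0 / np.sqrt(prec_lik), hi=scale)


# ---------------------------------------------------------------------
# hierarchical sampler (bivariate MAP / univariate variants)
# ---------------------------------------------------------------------

def sample_hierarchical(
    stats: SuffStats,
    priors: PriorConfig,
    settings: McmcSettings,
    rng: np.random.Generator,
    *,
    slope_mode: str = "random",     # "random" | "common" | "separate"
    rho_zero: bool = False,
    fix_tau0: float | None = None,
    fix_tau1: float | None = None,
    fix_rho: float | None = None,
    store: tuple[str, ...] = ("mu0", "mu1", "tau0", "tau1", "rho", "lam"),
) -> dict[str, np.ndarray]:
    """Run the blocked Gibbs sampler for one of the hierarchical models.

    slope_mode
        "random": study-specific baseline effects, exchangeable jointly
        with the intercepts (bivariate random effects; ``rho_zero``
        selects the independent-components variant);
        "common": one baseline effect shared by every study;
        "separate": study-specific baseline effects as independent fixed
        effects (no pooling of the slope).

    Returns a dict of stored draws, shape (K, draws) for scalars and
    (K, S, draws) for per-study parameters.
    """
    if slope_mode not in ("random", "common", "separate"):
        raise ValueError(f"unknown slope_mode {slope_mode!r}")
    K, S = stats.K, stats.S
    bivariate = slope_mode == "random"
    has_new = stats.include_new
    n, syb, syb2 = stats.n, stats.syb, stats.syb2
    st, sybt, stt = stats.st, stats.sybt, stats.stt
    sy, syyb, syt, yty = stats.sy, stats.syyb, stats.syt, stats.yty

    v_mu0, v_mu1 = priors.mu0_prior.variance, priors.mu1_prior.variance
    v_lam = priors.lambda_prior.variance
    v_b1fix = priors.beta1_fixed_prior.variance
    a0, b0 = priors.sigma2_prior.shape, priors.sigma2_prior.rate
    fam0, s0 = priors.tau0_prior.family, priors.tau0_prior.scale
    fam1, s1 = priors.tau1_prior.family, priors.tau1_prior.scale
    rlo, rhi = priors.rho_prior.lower, priors.rho_prior.upper

    # ---- initial state (jittered per batch element) ------------------
    n_safe = np.maximum(n, 1.0)
    varb = np.maximum(syb2 - syb**2 / n_safe, 1e-12)
    slope0 = np.where(n > 2, (syyb - sy * syb / n_safe) / varb, 0.0)
    icept0 = np.where(n > 0, (sy - slope0 * syb) / n_safe, 0.0)
    beta0 = icept0 + 0.1 * rng.standard_normal((K, S))
    beta1 = slope0 + 0.05 * rng.standard_normal((K, S))
    if slope_mode == "common":
        b1c = beta1.mean(axis=1)
        beta1 = np.repeat(b1c[:, None], S, axis=1)
    mu0 = beta0.mean(axis=1) + 0.1 * rng.standard_normal(K)
    mu1 = beta1.mean(axis=1) + 0.05 * rng.standard_normal(K)
    tau0 = np.full(K, 0.3 * s0) * np.exp(0.3 * rng.standard_normal(K)) \
        if fix_tau0 is None else np.full(K, float(fix_tau0))
    tau1 = np.full(K, 0.3 * s1) * np.exp(0.3 * rng.standard_normal(K)) \
        if fix_tau1 is None else np.full(K, float(fix_tau1))
    if fix_rho is not None:
        rho = np.full(K, float(fix_rho))
    elif rho_zero:
        rho = np.zeros(K)
    else:
        rho = np.clip(0.5 * (rlo + rhi) + 0.1 * rng.standard_normal(K), rlo + 1e-3, rhi - 1e-3)
    lam = 0.1 * rng.standard_normal(K)
    ss0 = np.maximum(
        yty - 2 * (beta0 * sy + beta1 * syyb) + beta0**2 * n + beta1**2 * syb2
        + 2 * beta0 * beta1 * syb, 1e-6)
    sigma2 = np.clip(ss0 / np.maximum(n - 2.0, 1.0), 1e-2, None)

    update_rho = bivariate and not rho_zero and fix_rho is None
    update_tau1 = bivariate and fix_tau1 is None
    update_tau0 = fix_tau0 is None
    tau0 = np.maximum(tau0, _TAU_FLOOR)
    tau1 = np.maximum(tau1, _TAU_FLOOR)

    # adaptive RW steps (log / logit scales)
    step_t0 = np.full(K, 0.5)
    step_t1 = np.full(K, 0.5)
    step_r = np.full(K, 0.8)

    n_iter = settings.warmup + settings.draws * settings.thin
    out: dict[str, np.ndarray] = {}
    per_study = {"beta0", "beta1", "sigma2"}
    for name in store:
        if name in per_study:
            out[name] = np.empty((K, S, settings.draws))
        else:
            out[name] = np.empty((K, settings.draws))
    kept = 0

    def _tau_rho_logpost(t0, t1, r, S00, S01, S11, M):
        if bivariate:
            den = 1.0 - r * r
            quad = (S00 / t0**2 - 2.0 * r * S01 / (t0 * t1) + S11 / t1**2) / den
            ld = -M * (np.log(t0) + np.log(t1) + 0.5 * np.log(den))
            return ld - 0.5 * quad + _tau_logprior(t0, fam0, s0) + _tau_logprior(t1, fam1, s1)
        return -M * np.log(t0) - 0.5 * S00 / t0**2 + _tau_logprior(t0, fam0, s0)

    M = float(S)
    for it in range(n_iter):
        warm = it < settings.warmup
        adapt = (it + 10.0) ** -0.6

        # -- Sigma_beta^{-1} elements --------------------------------
        if bivariate:
            den = 1.0 - rho * rho
            q00 = (1.0 / (tau0**2 * den))[:, None]
            q01 = (-rho / (tau0 * tau1 * den))[:, None]
            q11 = (1.0 / (tau1**2 * den))[:, None]
            pm0, pm1 = mu0[:, None], mu1[:, None]
        elif slope_mode == "separate":
            q00 = (1.0 / tau0**2)[:, None]
            q01 = np.zeros((K, 1))
            q11 = np.full((K, 1), 1.0 / v_b1fix)
            pm0, pm1 = mu0[:, None], 0.0
        else:  # common slope: intercept hierarchy only
            q00 = (1.0 / tau0**2)[:, None]
            pm0 = mu0[:, None]

        lam_col = np.zeros((K, S))
        if has_new:
            lam_col[:, -1] = lam

        # -- study coefficients ---------------------------------------
        if slope_mode == "common":
            # intercepts given shared slope
            b1c = beta1[:, 0][:, None]
            prec = n / sigma2 + q00
            rhs = (sy - b1c * syb - lam_col * st) / sigma2 + pm0 * q00
            beta0 = _norm(rng, prec, rhs)
            # shared slope
            prec1 = (syb2 / sigma2).sum(axis=1) + 1.0 / v_mu1
            rhs1 = ((syyb - beta0 * syb - lam_col * sybt) / sigma2).sum(axis=1)
            b1c = _norm(rng, prec1, rhs1)
            beta1 = np.repeat(b1c[:, None], S, axis=1)
        else:
            pa = n / sigma2 + q00
            pb = syb / sigma2 + q01
            pc = syb2 / sigma2 + q11
            r0 = (sy - lam_col * st) / sigma2 + q00 * pm0 + q01 * pm1
            r1 = (syyb - lam_col * sybt) / sigma2 + q01 * pm0 + q11 * pm1
            beta0, beta1 = _mvn2(rng, pa, pb, pc, r0, r1)

        # -- treatment effect -----------------------------------------
        if has_new:
            s2n = sigma2[:, -1]
            prec = stt[:, -1] / s2n + 1.0 / v_lam
            rhs = (syt[:, -1] - beta0[:, -1] * st[:, -1] - beta1[:, -1] * sybt[:, -1]) / s2n
            lam = _norm(rng, prec, rhs)
            lam_col[:, -1] = lam

        # -- grand means (centred) ------------------------------------
        sb0 = beta0.sum(axis=1)
        if bivariate:
            sb1 = beta1.sum(axis=1)
            pa = M * q00[:, 0] + 1.0 / v_mu0
            pb = M * q01[:, 0]
            pc = M * q11[:, 0] + 1.0 / v_mu1
            r0 = q00[:, 0] * sb0 + q01[:, 0] * sb1
            r1 = q01[:, 0] * sb0 + q11[:, 0] * sb1
            mu0, mu1 = _mvn2(rng, pa, pb, pc, r0, r1)
        else:
            prec = M / tau0**2 + 1.0 / v_mu0
            mu0 = _norm(rng, prec, sb0 / tau0**2)

        # -- heterogeneity: adaptive MH (centred) ---------------------
        d0 = beta0 - mu0[:, None]
        S00 = (d0 * d0).sum(axis=1)
        if bivariate:
            d1 = beta1 - mu1[:, None]
            S01 = (d0 * d1).sum(axis=1)
            S11 = (d1 * d1).sum(axis=1)
        else:
            S01 = S11 = None
        cur = _tau_rho_logpost(tau0, tau1, rho, S00, S01, S11, M)

        if update_tau0:
            prop = tau0 * np.exp(step_t0 * rng.standard_normal(K))
            prop = np.maximum(prop, _TAU_FLOOR)
            new = _tau_rho_logpost(prop, tau1, rho, S00, S01, S11, M)
            acc = np.log(rng.random(K)) < new - cur + np.log(prop / tau0)
            tau0 = np.where(acc, prop, tau0)
            cur = np.where(acc, new, cur)
            if warm:
                step_t0 = np.clip(step_t0 * np.exp(adapt * (acc - 0.44)), 1e-3, 5.0)
        if update_tau1:
            prop = tau1 * np.exp(step_t1 * rng.standard_normal(K))
            prop = np.maximum(prop, _TAU_FLOOR)
            new = _tau_rho_logpost(tau0, prop, rho, S00, S01, S11, M)
            acc = np.log(rng.random(K)) < new - cur + np.log(prop / tau1)
            tau1 = np.where(acc, prop, tau1)
            cur = np.where(acc, new, cur)
            if warm:
                step_t1 = np.clip(step_t1 * np.exp(adapt * (acc - 0.44)), 1e-3, 5.0)
        if update_rho:
            u = np.log((rho - rlo) / (rhi - rho))
            up = u + step_r * rng.standard_normal(K)
            e = np.exp(up)
            prop = (rlo + rhi * e) / (1.0 + e)
            new = _tau_rho_logpost(tau0, tau1, prop, S00, S01, S11, M)
            jac = np.log((prop - rlo) * (rhi - prop)) - np.log((rho - rlo) * (rhi - rho))
            acc = np.log(rng.random(K)) < new - cur + jac
            rho = np.where(acc, prop, rho)
            if warm:
                step_r = np.clip(step_r * np.exp(adapt * (acc - 0.44)), 1e-3, 5.0)

        # -- ASIS interweave: non-centred (mu, tau) redraw ------------
        z0 = (beta0 - mu0[:, None]) / tau0[:, None]
        if bivariate:
            w1 = (beta1 - mu1[:, None]) / tau1[:, None]
        inv_s2 = 1.0 / sigma2
        # mu0 | z0, ...
        B = beta1 if not bivariate else mu1[:, None] + tau1[:, None] * w1
        t0c = tau0[:, None]
        prec = (n * inv_s2).sum(axis=1) + 1.0 / v_mu0
        rhs = (((sy - t0c * z0 * n - B * syb - lam_col * st) * inv_s2).sum(axis=1))
        mu0 = _norm(rng, prec, rhs)
        # tau0 | z0, ...
        if update_tau0:
            prec_l = ((z0 * z0) * n * inv_s2).sum(axis=1)
            rhs_l = ((z0 * (sy - mu0[:, None] * n - B * syb - lam_col * st)) * inv_s2).sum(axis=1)
            tau0 = _tau_conditional_draw(rng, prec_l + 1e-12, rhs_l, fam0, s0)
            tau0 = np.maximum(tau0, _TAU_FLOOR)
        A = mu0[:, None] + tau0[:, None] * z0
        if bivariate:
            t1c = tau1[:, None]
            # mu1 | w1, ...
            prec = (syb2 * inv_s2).sum(axis=1) + 1.0 / v_mu1
            rhs = (((syyb - A * syb - t1c * w1 * syb2 - lam_col * sybt) * inv_s2).sum(axis=1))
            mu1 = _norm(rng, prec, rhs)
            # tau1 | w1, ...
            if update_tau1:
                prec_l = ((w1 * w1) * syb2 * inv_s2).sum(axis=1)
                rhs_l = ((w1 * (syyb - A * syb - mu1[:, None] * syb2 - lam_col * sybt))
                         * inv_s2).sum(axis=1)
                tau1 = _tau_conditional_draw(rng, prec_l + 1e-12, rhs_l, fam1, s1)
                tau1 = np.maximum(tau1, _TAU_FLOOR)
            beta1 = mu1[:, None] + tau1[:, None] * w1
        beta0 = mu0[:, None] + tau0[:, None] * z0

        # -- error variances ------------------------------------------
        cxty = beta0 * sy + beta1 * syyb + lam_col * syt
        quad = (beta0**2 * n + beta1**2 * syb2 + lam_col**2 * stt
                + 2 * beta0 * beta1 * syb + 2 * beta0 * lam_col * st
                + 2 * beta1 * lam_col * sybt)
        ss = np.maximum(yty - 2 * cxty + quad, 0.0)
        g = rng.gamma(a0 + 0.5 * n)
        sigma2 = np.clip((b0 + 0.5 * ss) / np.maximum(g, 1e-300), _SIG_LO, _SIG_HI)

        # -- storage ---------------------------------------------------
        if not warm and (it - settings.warmup) % settings.thin == 0:
            state = {"mu0": mu0, "mu1": mu1, "tau0": tau0, "tau1": tau1, "rho": rho,
                     "lam": lam, "beta0": beta0, "beta1": beta1, "sigma2": sigma2}
            for name, arr in out.items():
                arr[..., kept] = state[name]
            kept += 1

    return out


# ---------------------------------------------------------------------
# flat ANCOVA sampler (no borrowing / pooling / tau=0 reference)
# ---------------------------------------------------------------------

def sample_flat(
    stats: SuffStats,
    priors: PriorConfig,
    settings: McmcSettings,
    rng: np.random.Generator,
    *,
    store: tuple[str, ...] = ("beta0", "beta1", "lam"),
) -> dict[str, np.ndarray]:
    """Bayesian ANCOVA with a single (intercept, baseline-effect) pair and
    one error variance: used for the no-borrowing analysis (new trial
    only), the pooled analysis (all data stacked) and the tau=0 reference
    fit of the effective-sample-size calculation.  ``stats`` must contain
    exactly one (possibly stacked) pseudo-study."""
    if stats.S != 1:
        raise ValueError("sample_flat expects a single (stacked) study")
    K = stats.K
    n = stats.n[:, 0]
    syb, syb2 = stats.syb[:, 0], stats.syb2[:, 0]
    st, sybt, stt = stats.st[:, 0], stats.sybt[:, 0], stats.stt[:, 0]
    sy, syyb, syt, yty = stats.sy[:, 0], stats.syyb[:, 0], stats.syt[:, 0], stats.yty[:, 0]
    has_trt = bool(np.any(stt > 0))

    v0, v1 = priors.mu0_prior.variance, priors.mu1_prior.variance
    v_lam = priors.lambda_prior.variance
    a0, b0r = priors.sigma2_prior.shape, priors.sigma2_prior.rate

    n_safe = np.maximum(n, 1.0)
    varb = np.maximum(syb2 - syb**2 / n_safe, 1e-12)
    b1 = (syyb - sy * syb / n_safe) / varb + 0.05 * rng.standard_normal(K)
    b0 = (sy - b1 * syb) / n_safe + 0.1 * rng.standard_normal(K)
    lam = 0.1 * rng.standard_normal(K)
    sigma2 = np.clip(
        np.maximum(yty - 2 * (b0 * sy + b1 * syyb) + b0**2 * n + b1**2 * syb2
                   + 2 * b0 * b1 * syb, 1e-6) / n_safe, 1e-2, None)

    n_iter = settings.warmup + settings.draws * settings.thin
    out = {name: np.empty((K, settings.draws)) for name in store}
    kept = 0
    for it in range(n_iter):
        pa = n / sigma2 + 1.0 / v0
        pb = syb / sigma2
        pc = syb2 / sigma2 + 1.0 / v1
        r0 = (sy - lam * st) / sigma2
        r1 = (syyb - lam * sybt) / sigma2
        b0, b1 = _mvn2(rng, pa, pb, pc, r0, r1)
        if has_trt:
            prec = stt / sigma2 + 1.0 / v_lam
            rhs = (syt - b0 * st - b1 * sybt) / sigma2
            lam = _norm(rng, prec, rhs)
        ss = np.maximum(
            yty - 2 * (b0 * sy + b1 * syyb + lam * syt)
            + b0**2 * n + b1**2 * syb2 + lam**2 * stt
            + 2 * b0 * b1 * syb + 2 * b0 * lam * st + 2 * b1 * lam * sybt, 0.0)
        g = rng.gamma(a0 + 0.5 * n)
        sigma2 = np.clip((b0r + 0.5 * ss) / np.maximum(g, 1e-300), _SIG_LO, _SIG_HI)
        if it >= settings.warmup and (it - settings.warmup) % settings.thin == 0:
            state = {"beta0": b0, "beta1": b1, "lam": lam, "sigma2": sigma2}
            for name, arr in out.items():
                arr[:, kept] = state[name]
            kept += 1
    return out


# ---------------------------------------------------------------------
# diagnostics
# ---------------------------------------------------------------------

def split_rhat(draws: np.ndarray) -> np.ndarray:
    """Classic split-R-hat.  ``draws`` has shape (..., chains, n); the
    potential scale reduction factor is returned for the leading axes."""
    *lead, C, N = draws.shape
    half = N // 2
    x = draws[..., : 2 * half].reshape(*lead, 2 * C, half)
    m = x.mean(axis=-1)
    v = x.var(axis=-1, ddof=1)
    W = v.mean(axis=-1)
    B = half * m.var(axis=-1, ddof=1)
    var_plus = (half - 1) / half * W + B / half
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.sqrt(var_plus / W)
    return np.where(W > 0, out, 1.0)
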