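"""Model and Results objects for Bayesian ANCOVA with historical borrowing.

`AncovaMAP` is built from an :class:`~mvmap.data.IPDDataset` and a method
label; `fit()` runs MCMC and returns an :class:`AncovaMAPResults` holding
labelled posterior draws, convergence diagnostics, a `summary()` table,
treatment-effect inference and (for design-phase fits) the MAP predictive
prior of the new trial's intercept and baseline effect.

Methods
-------
no_borrowing   Bayesian ANCOVA on the new trial only.
mmap_cor       bivariate random effects for (intercept, baseline effect)
               with an unstructured between-study covariance (the
               correlated multivariate MAP).
mmap_ind       same with the between-study correlation fixed at zero.
umap_com       random intercepts, one baseline effect shared by all
               studies including the new trial.
umap_sep       random intercepts, study-specific fixed-effect baseline
               slopes.
pooling        all control data stacked with the new trial in one ANCOVA
               with common coefficients and a single error variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _gibbs
from ._gibbs import McmcSettings, SuffStats
from .data import IPDDataset, fit_all_studies
from .priors import PriorConfig, default_prior_config

__all__ = ["AncovaMAP", "AncovaMAPResults", "TreatmentEffect", "METHODS", "MAP_METHODS"]

METHODS = ("no_borrowing", "mmap_cor", "mmap_ind", "umap_com", "umap_sep", "pooling")
MAP_METHODS = ("mmap_cor", "mmap_ind", "umap_com", "umap_sep")

_SLOPE_MODE = {"mmap_cor": "random", "mmap_ind": "random",
               "umap_com": "common", "umap_sep": "separate"}


def _study_arrays(dataset: IPDDataset, study_ids) -> list[tuple]:
    out = []
    for sid in study_ids:
        sub = dataset.study(sid)
        out.append((sub["y_baseline"].to_numpy(float),
                    sub["y_followup"].to_numpy(float),
                    sub["arm"].to_numpy(float)))
    return out


@dataclass(frozen=True)
class TreatmentEffect:
    """Posterior summary for the treatment effect."""

    mean: float
    sd: float
    ci_lower: float
    ci_upper: float
    level: float
    reject: bool           # True when the credible interval excludes 0

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        flag = "excludes 0" if self.reject else "includes 0"
        return (f"lambda = {self.mean:.3f} (SD {self.sd:.3f}), "
                f"{100 * self.level:.0f}% CI [{self.ci_lower:.3f}, {self.ci_upper:.3f}] "
                f"({flag})")


class AncovaMAP:
    """Bayesian ANCOVA for a pretest-posttest trial with (optionally)
    borrowed historical control information.

    Parameters
    ----------
    dataset : IPDDataset
        Historical control arms and, for analysis-phase models, the new
        two-arm trial.
    method : str
        One of :data:`METHODS`.
    priors : PriorConfig, optional
        Hyperpriors; by default elicited from per-study ANCOVA fits of
        the historical trials (heterogeneity scales from within-study
        SDs, everything else at the package defaults).
    include_new_trial : bool, optional
        Analysis phase (joint fit of historical + new data) when True;
        design phase (historical controls only) when False.  Defaults to
        True when the dataset names a new study.
    """

    def __init__(
        self,
        dataset: IPDDataset,
        method: str = "mmap_cor",
        priors: PriorConfig | None = None,
        include_new_trial: bool | None = None,
    ):
        if method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}, got {method!r}")
        self.dataset = dataset
        self.method = method
        if include_new_trial is None:
            include_new_trial = dataset.new_study_id is not None
        if method == "no_borrowing" and not include_new_trial:
            raise ValueError("no_borrowing is an analysis-phase model; it needs the new trial")
        if include_new_trial:
            if dataset.new_study_id is None:
                raise ValueError(f"{method}: analysis phase requires a new study in the dataset")
            arms = set(dataset.study(dataset.new_study_id)["arm"].unique())
            if arms != {0, 1}:
                raise ValueError("the new trial must contain both arms")
        self.include_new_trial = bool(include_new_trial)
        if priors is None:
            priors = default_prior_config(fit_all_studies(dataset))
        self.priors = priors

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        new_study_id: str | None = None,
        historical_ids: list[str] | None = None,
        **kwargs,
    ) -> "AncovaMAP":
        """Build directly from a long-format DataFrame with canonical
        columns (study, arm, y_baseline, y_followup)."""
        ds = IPDDataset(df.copy(), new_study_id, historical_ids or [])
        return cls(ds, **kwargs)

    # -----------------------------------------------------------------
    def fit(
        self,
        settings: McmcSettings | None = None,
        seed: int | None = None,
        **fix,
    ) -> "AncovaMAPResults":
        """Run MCMC.  ``fix`` may carry ``fix_tau0``/``fix_tau1``/``fix_rho``
        to pin heterogeneity parameters (used for oracle checks and the
        tau=0 limit)."""
        settings = settings or McmcSettings()
        if seed is not None:
            settings = McmcSettings(settings.chains, settings.warmup, settings.draws,
                                    settings.thin, seed, settings.rhat_threshold)
        rng = np.random.default_rng(settings.seed)
        ds = self.dataset
        C = settings.chains

        if self.method == "no_borrowing":
            arrays = [_study_arrays(ds, [ds.new_study_id])]
            stats = SuffStats.from_arrays(arrays, include_new=True).repeat(C)
            raw = _gibbs.sample_flat(stats, self.priors, settings, rng,
                                     store=("beta0", "beta1", "lam", "sigma2"))
            study_ids = [ds.new_study_id]
        elif self.method == "pooling":
            ids = ds.study_ids if self.include_new_trial else list(ds.historical_ids)
            arrays = [_study_arrays(ds, ids)]
            stats = SuffStats.from_arrays(
                arrays, include_new=self.include_new_trial).stacked().repeat(C)
            store = ("beta0", "beta1", "lam", "sigma2") if self.include_new_trial \
                else ("beta0", "beta1", "sigma2")
            raw = _gibbs.sample_flat(stats, self.priors, settings, rng, store=store)
            study_ids = ids
        else:
            ids = list(ds.historical_ids)
            if self.include_new_trial:
                ids.append(ds.new_study_id)
            arrays = [_study_arrays(ds, ids)]
            stats = SuffStats.from_arrays(arrays, include_new=self.include_new_trial).repeat(C)
            store = ["mu0", "tau0", "beta0", "beta1", "sigma2"]
            if self.method in ("mmap_cor", "mmap_ind"):
                store += ["mu1", "tau1"]
            if self.method == "mmap_cor":
                store += ["rho"]
            if self.include_new_trial:
                store += ["lam"]
            raw = _gibbs.sample_hierarchical(
                stats, self.priors, settings, rng,
                slope_mode=_SLOPE_MODE[self.method],
                rho_zero=self.method == "mmap_ind",
                store=tuple(store), **fix)
            study_ids = ids
        # reshape (C, ...) draws
        draws = {k: v for k, v in raw.items()}
        return AncovaMAPResults(
            model=self, draws=draws, study_ids=study_ids, settings=settings)


class AncovaMAPResults:
    """Posterior draws and diagnostics from :meth:`AncovaMAP.fit`.

    ``draws`` maps parameter names to arrays of shape (chains, n_draws)
    for scalars and (chains, n_studies, n_draws) for per-study
    parameters.
    """

    def __init__(self, model: AncovaMAP, draws: dict, study_ids, settings: McmcSettings):
        self.model = model
        self.method = model.method
        self.draws = draws
        self.study_ids = list(study_ids)
        self.settings = settings

    # -- access --------------------------------------------------------
    def flat(self, name: str) -> np.ndarray:
        """Draws for a scalar parameter pooled over chains."""
        arr = self.draws[name]
        if arr.ndim != 2:
            raise ValueError(f"{name} is a per-study parameter; use draws[{name!r}]")
        return arr.reshape(-1)

    # -- diagnostics ---------------------------------------------------
    def to_inference_data(self):
        """Posterior draws as an ``arviz.InferenceData``."""
        import arviz as az

        post = {}
        coords = {"study": self.study_ids}
        dims = {}
        for name, arr in self.draws.items():
            if arr.ndim == 3:
                post[name] = np.transpose(arr, (0, 2, 1))
                dims[name] = ["study"]
            else:
                post[name] = arr
        return az.from_dict(posterior=post, coords=coords, dims=dims)

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        """Posterior means, SDs, equal-tailed intervals, split R-hat and
        bulk effective draw counts for every stored parameter."""
        import arviz as az

        alpha = (1.0 - level) / 2.0
        rows = []
        for name, arr in self.draws.items():
            items = [(name, arr)] if arr.ndim == 2 else [
                (f"{name}[{sid}]", arr[:, j, :]) for j, sid in enumerate(self.study_ids)]
            for label, a in items:
                flat = a.reshape(-1)
                rows.append({
                    "parameter": label,
                    "mean": flat.mean(),
                    "sd": flat.std(ddof=1),
                    f"q{100 * alpha:g}": np.quantile(flat, alpha),
                    f"q{100 * (1 - alpha):g}": np.quantile(flat, 1 - alpha),
                    "rhat": float(az.rhat(a[None] if a.ndim == 1 else a)) if a.shape[0] > 1
                    else np.nan,
                    "ess_bulk": float(az.ess(a)) if a.shape[0] > 1 else np.nan,
                })
        return pd.DataFrame(rows).set_index("parameter")

    @property
    def max_rhat(self) -> float:
        vals: list[float] = []
        for arr in self.draws.values():
            if arr.ndim == 2:
                vals.append(float(_gibbs.split_rhat(arr[None])[0]))
            else:
                a = np.moveaxis(arr, 1, 0)   # (S, C, n)
                vals.extend(_gibbs.split_rhat(a).tolist())
        return float(np.nanmax(vals))

    @property
    def converged(self) -> bool:
        return self.max_rhat <= self.settings.rhat_threshold

    # -- inference -----------------------------------------------------
    def treatment_inference(self, level: float = 0.95) -> TreatmentEffect:
        """Posterior mean, SD and equal-tailed credible interval of the
        treatment effect, with the interval-excludes-zero decision."""
        if "lam" not in self.draws:
            raise ValueError("treatment effect not in the model (design-phase fit?)")
        lam = self.flat("lam")
        alpha = (1.0 - level) / 2.0
        lo, hi = np.quantile(lam, [alpha, 1.0 - alpha])
        return TreatmentEffect(
            mean=float(lam.mean()), sd=float(lam.std(ddof=1)),
            ci_lower=float(lo), ci_upper=float(hi), level=level,
            reject=bool(lo > 0.0 or hi < 0.0))

    def map_prior(self, seed: int | None = None):
        """MAP predictive prior for the new trial (design-phase fits)."""
        from .map_prior import map_predictive

        return map_predictive(self, seed=seed)

    # -- export --------------------------------------------------------
    def to_tidy_frame(self) -> pd.DataFrame:
        """Tidy (chain, iteration, parameter, value) draw table."""
        frames = []
        for name, arr in self.draws.items():
            if arr.ndim == 2:
                C, N = arr.shape
                frames.append(pd.DataFrame({
                    "chain": np.repeat(np.arange(C), N),
                    "iteration": np.tile(np.arange(N), C),
                    "parameter": name,
                    "value": arr.reshape(-1),
                }))
            else:
                C, S, N = arr.shape
                for j, sid in enumerate(self.study_ids):
                    frames.append(pd.DataFrame({
                        "chain": np.repeat(np.arange(C), N),
                        "iteration": np.tile(np.arange(N), C),
                        "parameter": f"{name}[{sid}]",
                        "value": arr[:, j, :].reshape(-1),
                    }))
        return pd.concat(frames, ignore_index=True)
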