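"""Sampler correctness and the Model/Results API.

The Gibbs sampler is validated against independent references: the exact
prior distribution when no data enter, least-squares estimates in the
flat-prior limit, and internal consistency between model variants that
must coincide in distribution.
"""

import numpy as np
import pytest
import statsmodels.api as sm

from mvmap import AncovaMAP, McmcSettings, PriorConfig, simulation_grid_priors
from mvmap._gibbs import SuffStats, sample_hierarchical
from mvmap.model import AncovaMAPResults, METHODS
from mvmap.priors import HeterogeneityPrior, InverseGammaPrior

FAST = McmcSettings(chains=2, warmup=400, draws=1500)


def test_seeded_determinism(analysis_dataset):
    """Identical seed and settings give identical draws."""
    m = AncovaMAP(analysis_dataset, "mmap_cor", priors=simulation_grid_priors())
    a = m.fit(settings=FAST, seed=7)
    b = m.fit(settings=FAST, seed=7)
    for k in a.draws:
        np.testing.assert_array_equal(a.draws[k], b.draws[k])


def test_prior_only_run_recovers_priors():
    """With empty data the sampler must reproduce the prior: a direct
    check of the Metropolis and interweaving updates for (tau0, tau1,
    rho) against their closed-form prior distributions."""
    K, S = 4, 3
    zeros = [[(np.empty(0), np.empty(0), np.empty(0))] * S for _ in range(K)]
    stats = SuffStats.from_arrays(zeros, include_new=False)
    priors = PriorConfig(
        tau0_prior=HeterogeneityPrior("half_normal", 10.0),
        tau1_prior=HeterogeneityPrior("half_normal", 0.36),
        sigma2_prior=InverseGammaPrior(3.0, 2.0),   # keep sigma draws finite
    )
    rng = np.random.default_rng(5)
    out = sample_hierarchical(stats, priors, McmcSettings(chains=4, warmup=1000, draws=4000),
                              rng, store=("mu0", "tau0", "tau1", "rho"))
    tau0 = out["tau0"].ravel()
    tau1 = out["tau1"].ravel()
    rho = out["rho"].ravel()
    mu0 = out["mu0"].ravel()
    # half-normal(s): mean s*sqrt(2/pi), sd s*sqrt(1-2/pi)
    assert tau0.mean() == pytest.approx(10.0 * np.sqrt(2 / np.pi), rel=0.05)
    assert tau1.mean() == pytest.approx(0.36 * np.sqrt(2 / np.pi), rel=0.05)
    assert rho.mean() == pytest.approx(-0.5, abs=0.02)
    assert rho.min() >= -1.0 and rho.max() <= 0.0
    assert mu0.mean() == pytest.approx(0.0, abs=5.0)
    assert mu0.std() == pytest.approx(100.0, rel=0.1)


def test_flat_prior_limit_matches_least_squares(analysis_dataset):
    """No-borrowing posterior at diffuse priors agrees with OLS on the
    new trial."""
    m = AncovaMAP(analysis_dataset, "no_borrowing", priors=simulation_grid_priors())
    res = m.fit(settings=McmcSettings(chains=2, warmup=400, draws=4000), seed=3)
    sub = analysis_dataset.study("NEW")
    X = np.column_stack([np.ones(len(sub)), sub["y_baseline"], sub["arm"]])
    ols = sm.OLS(sub["y_followup"].to_numpy(), X).fit()
    for key, j in (("beta0", 0), ("beta1", 1), ("lam", 2)):
        draws = res.flat(key)
        assert draws.mean() == pytest.approx(ols.params[j], abs=0.1 * ols.bse[j])
        assert draws.std(ddof=1) == pytest.approx(ols.bse[j], rel=0.08)


def test_fixed_zero_correlation_reproduces_independent_variant(design_dataset):
    """MMAP with the correlation pinned at zero must match MMAP+IND in
    distribution."""
    priors = simulation_grid_priors()
    cor = AncovaMAP(design_dataset, "mmap_cor", priors=priors, include_new_trial=False)
    ind = AncovaMAP(design_dataset, "mmap_ind", priors=priors, include_new_trial=False)
    a = cor.fit(settings=FAST, seed=11, fix_rho=0.0)
    b = ind.fit(settings=FAST, seed=12)
    for k in ("mu0", "mu1", "tau0", "tau1"):
        da, db = a.flat(k), b.flat(k)
        scale = max(da.std(), 1e-6)
        assert abs(da.mean() - db.mean()) < 0.12 * scale
        assert da.std() == pytest.approx(db.std(), rel=0.12)


def test_degenerate_heterogeneity_limit_is_pooling():
    """As the tau priors collapse to zero the hierarchical posterior for
    the grand means approaches the pooled ANCOVA posterior.  A single
    historical study is used so that the per-study and common error
    variances coincide and the two models share one exact limit."""
    from mvmap import ScenarioConfig, generate_dataset

    ds = generate_dataset(ScenarioConfig(J=1, seed=77)).historical_only()
    tiny = PriorConfig(
        tau0_prior=HeterogeneityPrior("half_normal", 1e-4),
        tau1_prior=HeterogeneityPrior("half_normal", 1e-6),
    )
    hier = AncovaMAP(ds, "mmap_cor", priors=tiny,
                     include_new_trial=False).fit(settings=FAST, seed=21)
    pool = AncovaMAP(ds, "pooling", priors=tiny,
                     include_new_trial=False).fit(settings=FAST, seed=22)
    for hk, pk in (("mu0", "beta0"), ("mu1", "beta1")):
        dh, dp = hier.flat(hk), pool.flat(pk)
        assert dh.mean() == pytest.approx(dp.mean(), abs=0.15 * dp.std())
        assert dh.std() == pytest.approx(dp.std(), rel=0.15)


def test_draw_constraints_hold_everywhere(analysis_dataset):
    res = AncovaMAP(analysis_dataset, "mmap_cor",
                    priors=simulation_grid_priors()).fit(settings=FAST, seed=31)
    assert (res.flat("tau0") >= 0).all()
    assert (res.flat("tau1") >= 0).all()
    rho = res.flat("rho")
    assert ((rho >= -1) & (rho <= 0)).all()
    assert (res.draws["sigma2"] > 0).all()


def test_structural_parameter_sets(analysis_dataset):
    res = AncovaMAP(analysis_dataset, "mmap_cor",
                    priors=simulation_grid_priors()).fit(
        settings=McmcSettings(chains=2, warmup=100, draws=100), seed=1)
    assert res.draws["beta0"].shape[1] == 6      # 5 historical + new
    assert set(res.draws) == {"mu0", "tau0", "beta0", "beta1", "sigma2",
                              "mu1", "tau1", "rho", "lam"}


def test_no_borrowing_ignores_historical_records(analysis_dataset):
    """The no-borrowing posterior depends on the new trial only."""
    import pandas as pd
    perturbed = analysis_dataset.df.copy()
    hist_mask = perturbed["study"] != "NEW"
    perturbed.loc[hist_mask, "y_followup"] += 500.0
    from mvmap import IPDDataset
    ds2 = IPDDataset(perturbed, "NEW", list(analysis_dataset.historical_ids))
    p = simulation_grid_priors()
    a = AncovaMAP(analysis_dataset, "no_borrowing", priors=p).fit(settings=FAST, seed=4)
    b = AncovaMAP(ds2, "no_borrowing", priors=p).fit(settings=FAST, seed=4)
    np.testing.assert_array_equal(a.flat("lam"), b.flat("lam"))


class TestTreatmentInference:
    def _results(self, lam_draws):
        dummy = object.__new__(AncovaMAP)
        dummy.dataset = None
        res = AncovaMAPResults.__new__(AncovaMAPResults)
        res.model = dummy
        res.method = "no_borrowing"
        res.draws = {"lam": np.asarray(lam_draws, float).reshape(1, -1)}
        res.study_ids = []
        res.settings = McmcSettings(chains=2, warmup=0, draws=1)
        return res

    def test_interval_excluding_zero_rejects(self, rng):
        res = self._results(rng.uniform(0.2, 0.9, 2000))
        ti = res.treatment_inference()
        assert ti.reject and ti.ci_lower > 0

    def test_symmetric_draws_do_not_reject(self, rng):
        res = self._results(rng.normal(0.0, 1.0, 4000))
        assert not res.treatment_inference().reject

    def test_quantile_decision_matches_direct_computation(self, rng):
        draws = np.sort(rng.normal(-5.0, 1.0, 1000))
        res = self._results(draws)
        ti = res.treatment_inference()
        assert ti.ci_lower == pytest.approx(np.quantile(draws, 0.025))
        assert ti.ci_upper == pytest.approx(np.quantile(draws, 0.975))
        assert ti.reject and ti.ci_upper < 0

    def test_missing_lambda_is_error(self):
        res = self._results([0.0])
        res.draws = {}
        with pytest.raises(ValueError):
            res.treatment_inference()


def test_summary_and_diagnostics(analysis_dataset):
    res = AncovaMAP(analysis_dataset, "mmap_cor",
                    priors=simulation_grid_priors()).fit(settings=FAST, seed=41)
    summ = res.summary()
    assert "mu0" in summ.index and "beta0[NEW]" in summ.index
    assert (summ["sd"] > 0).all()
    assert res.max_rhat < 1.1
    idata = res.to_inference_data()
    assert "mu0" in idata.posterior


@pytest.mark.parametrize("method", METHODS)
def test_every_method_fits_and_infers(analysis_dataset, method):
    res = AncovaMAP(analysis_dataset, method, priors=simulation_grid_priors()).fit(
        settings=McmcSettings(chains=2, warmup=200, draws=500), seed=51)
    ti = res.treatment_inference()
    assert np.isfinite(ti.mean) and ti.sd > 0
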