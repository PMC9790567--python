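"""IPD container, CSV round trips and per-study ANCOVA fits."""

import numpy as np
import pandas as pd
import pytest

from mvmap import (
    IPDDataset,
    ScenarioConfig,
    fit_study_ancova,
    generate_dataset,
    read_ipd_csv,
    write_ipd_csv,
)
from mvmap.data import IPDValidationError


def _frame(rows):
    return pd.DataFrame(rows, columns=["study", "arm", "y_baseline", "y_followup"])


class TestReadWrite:
    def test_round_trip_is_bit_exact_for_decimal_inputs(self, tmp_path, rng):
        vals = np.round(rng.normal(24, 9, (30, 2)), 2)
        df = _frame([("H1", 0, a, b) for a, b in vals[:15]]
                    + [("H2", 0, a, b) for a, b in vals[15:]])
        ds = IPDDataset(df, None, ["H1", "H2"])
        path = tmp_path / "ipd.csv"
        write_ipd_csv(ds, path)
        back = read_ipd_csv(path)
        pd.testing.assert_frame_equal(back.df, ds.df, check_exact=True)

    def test_round_trip_preserves_records(self, analysis_dataset, tmp_path):
        path = tmp_path / "ipd.csv"
        write_ipd_csv(analysis_dataset, path)
        back = read_ipd_csv(path, new_study_id="NEW")
        pd.testing.assert_frame_equal(back.df, analysis_dataset.df)
        assert back.historical_ids == analysis_dataset.historical_ids
        assert back.new_study_id == "NEW"

    def test_structure_and_new_study_autodetect(self, analysis_dataset, tmp_path):
        path = tmp_path / "ipd.csv"
        write_ipd_csv(analysis_dataset, path)
        ds = read_ipd_csv(path)   # the only study with treated subjects is the new one
        assert len(ds.historical_ids) == 5
        assert ds.new_study_id == "NEW"

    def test_missing_followup_rows_are_dropped_and_counted(self, tmp_path):
        path = tmp_path / "miss.csv"
        path.write_text(
            "study,arm,y0,y1\n" +
            "\n".join(f"A,0,{i},{i + 1}" for i in range(5)) +
            "\nA,0,9.0,\nA,0,8.0,NA\n")
        ds = read_ipd_csv(path)
        assert ds.n_dropped == 2
        assert len(ds.df) == 5

    def test_missing_baseline_is_an_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("study,arm,y0,y1\nA,0,,1.0\nA,0,1,2\nA,0,2,3\n")
        with pytest.raises(IPDValidationError, match="baseline"):
            read_ipd_csv(path)

    def test_malformed_numeric_is_an_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("study,arm,y0,y1\nA,0,1.0,x\nA,0,1,2\nA,0,2,3\n")
        with pytest.raises(IPDValidationError, match="numeric"):
            read_ipd_csv(path)

    def test_column_map(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("trial,treated,pre,post\nA,0,1,2\nA,0,2,3\nA,0,3,4\n")
        ds = read_ipd_csv(path, column_map={
            "study": "trial", "arm": "treated", "y_baseline": "pre", "y_followup": "post"})
        assert len(ds.df) == 3


class TestValidation:
    def test_treated_subjects_in_historical_study_rejected(self):
        df = _frame([("H1", 0, 1.0, 2.0)] * 3 + [("H1", 1, 1.0, 2.0)])
        with pytest.raises(IPDValidationError, match="control-only"):
            IPDDataset(df, None, ["H1"])

    def test_too_few_records_rejected(self):
        df = _frame([("H1", 0, 1.0, 2.0)] * 2)
        with pytest.raises(IPDValidationError, match=">=3"):
            IPDDataset(df, None, ["H1"])

    def test_empty_rejected(self):
        with pytest.raises(IPDValidationError):
            IPDDataset(_frame([]), None, ["H1"])


class TestStudyAncova:
    def test_identity_relationship(self):
        yb = np.linspace(0, 10, 8)
        df = _frame([("A", 0, b, b) for b in yb])
        fit = fit_study_ancova(IPDDataset(df, None, ["A"]), "A")
        assert fit.b0_hat == pytest.approx(0.0, abs=1e-10)
        assert fit.b1_hat == pytest.approx(1.0, abs=1e-12)
        assert fit.sigma_hat == pytest.approx(0.0, abs=1e-10)

    def test_collinear_three_points(self):
        df = _frame([("A", 0, 0.0, 1.0), ("A", 0, 1.0, 3.0), ("A", 0, 2.0, 5.0)])
        fit = fit_study_ancova(IPDDataset(df, None, ["A"]), "A")
        assert fit.b0_hat == pytest.approx(1.0, abs=1e-10)
        assert fit.b1_hat == pytest.approx(2.0, abs=1e-10)

    def test_agrees_with_normal_equations(self, rng):
        """Brute-force least squares oracle on random small datasets."""
        for _ in range(5):
            n = int(rng.integers(6, 30))
            yb = rng.normal(20, 5, n)
            y = rng.normal(1.0 + 1.2 * yb, 3.0)
            df = _frame([("A", 0, float(b), float(v)) for b, v in zip(yb, y)])
            fit = fit_study_ancova(IPDDataset(df, None, ["A"]), "A")
            X = np.column_stack([np.ones(n), yb])
            coef = np.linalg.solve(X.T @ X, X.T @ y)
            resid = y - X @ coef
            s2 = resid @ resid / (n - 2)
            se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
            assert fit.b0_hat == pytest.approx(coef[0], rel=1e-10)
            assert fit.b1_hat == pytest.approx(coef[1], rel=1e-10)
            assert fit.se_b0 == pytest.approx(se[0], rel=1e-10)
            assert fit.se_b1 == pytest.approx(se[1], rel=1e-10)
            assert fit.sigma_hat == pytest.approx(np.sqrt(s2), rel=1e-10)

    def test_dropping_missing_rows_equals_prefiltered_fit(self, tmp_path):
        ds = generate_dataset(ScenarioConfig(J=1, seed=3))
        path = tmp_path / "x.csv"
        write_ipd_csv(ds, path)
        with open(path, "a") as fh:
            fh.write("H1,0,10.0,\n")    # one row with missing follow-up
        noisy = read_ipd_csv(path, new_study_id="NEW")
        assert noisy.n_dropped == 1
        a = fit_study_ancova(noisy, "H1")
        b = fit_study_ancova(ds, "H1")
        for field in ("b0_hat", "b1_hat", "se_b0", "se_b1", "sigma_hat"):
            assert getattr(a, field) == pytest.approx(getattr(b, field), rel=1e-12)
        assert a.n == b.n

    def test_constant_baseline_is_rank_deficient(self):
        df = _frame([("A", 0, 5.0, float(i)) for i in range(5)])
        with pytest.raises(ValueError, match="constant"):
            fit_study_ancova(IPDDataset(df, None, ["A"]), "A")

    def test_within_study_sd_matches_design_values(self):
        """A two-arm study of n=120 generated at the default settings has
        within-study SDs (se * sqrt(n)) near 20 for the intercept and
        0.72 for the baseline effect."""
        vals0, vals1 = [], []
        for s in range(30):
            ds = generate_dataset(ScenarioConfig(J=1, heterogeneity="No", seed=1000 + s))
            f = fit_study_ancova(ds, "NEW")
            assert f.n == 120
            vals0.append(f.se_b0 * np.sqrt(f.n))
            vals1.append(f.se_b1 * np.sqrt(f.n))
        assert np.mean(vals0) == pytest.approx(20.0, rel=0.07)
        assert np.mean(vals1) == pytest.approx(0.72, rel=0.07)
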