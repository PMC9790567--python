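"""IPD data model for multi-study pretest-posttest trials.

Individual-participant data (IPD) are held in long format, one row per
subject, with a study label, a binary treatment indicator, the outcome
measured at baseline and the same outcome at follow-up.  Historical
studies contribute control arms only; the (optional) new study may have
both arms.  Per-study frequentist ANCOVA fits provide the summary
statistics used for prior elicitation and forest plots.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "DEFAULT_COLUMNS",
    "IPDDataset",
    "StudyAncovaFit",
    "read_ipd_csv",
    "write_ipd_csv",
    "fit_study_ancova",
    "fit_all_studies",
]

#: default CSV column names: study label, treatment arm, baseline, follow-up
DEFAULT_COLUMNS = {"study": "study", "arm": "arm", "y_baseline": "y0", "y_followup": "y1"}

_CANONICAL = ["study", "arm", "y_baseline", "y_followup"]


class IPDValidationError(ValueError):
    """Raised when an IPD table violates the data-model invariants."""


@dataclass
class IPDDataset:
    """Long-format IPD for one or more historical control arms and
    optionally one new two-arm trial.

    Parameters
    ----------
    df : DataFrame with canonical columns ``study`` (str), ``arm`` (0/1),
        ``y_baseline``, ``y_followup`` (finite floats).
    new_study_id : label of the new trial, or ``None`` for a
        historical-only (design phase) dataset.
    historical_ids : ordered study labels of the historical trials.
    n_dropped : rows removed because the follow-up outcome was missing.
    """

    df: pd.DataFrame
    new_study_id: str | None = None
    historical_ids: list[str] = field(default_factory=list)
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)
        if not self.historical_ids:
            ids = [s for s in self.df["study"].unique() if s != self.new_study_id]
            self.historical_ids = list(ids)
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        df = self.df
        if df.empty:
            raise IPDValidationError("dataset contains no records")
        known = set(self.historical_ids)
        if self.new_study_id is not None:
            known.add(self.new_study_id)
        unknown = set(df["study"].unique()) - known
        if unknown:
            raise IPDValidationError(f"records reference unknown studies: {sorted(unknown)}")
        if not set(np.unique(df["arm"])) <= {0, 1}:
            raise IPDValidationError("arm must be 0 (control) or 1 (treated)")
        for col in ("y_baseline", "y_followup"):
            vals = df[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(vals)):
                raise IPDValidationError(f"non-finite values in {col}")
        if len(self.historical_ids) < 1:
            raise IPDValidationError("at least one historical study is required")
        hist = df[df["study"].isin(self.historical_ids)]
        if (hist["arm"] != 0).any():
            bad = hist.loc[hist["arm"] != 0, "study"].unique()
            raise IPDValidationError(
                f"historical studies must be control-only; treated rows in {sorted(bad)}"
            )
        counts = df.groupby("study").size()
        small = counts[counts < 3]
        if len(small):
            raise IPDValidationError(
                f"every study needs >=3 records; too few in {sorted(small.index)}"
            )

    # -- convenience ---------------------------------------------------
    @property
    def study_ids(self) -> list[str]:
        ids = list(self.historical_ids)
        if self.new_study_id is not None:
            ids.append(self.new_study_id)
        return ids

    @property
    def n_historical_controls(self) -> int:
        return int(self.df["study"].isin(self.historical_ids).sum())

    def study(self, study_id: str) -> pd.DataFrame:
        sub = self.df[self.df["study"] == study_id]
        if sub.empty:
            raise KeyError(f"unknown study {study_id!r}")
        return sub

    def historical_only(self) -> "IPDDataset":
        """Design-phase view: historical control arms only."""
        sub = self.df[self.df["study"].isin(self.historical_ids)]
        return IPDDataset(sub.copy(), None, list(self.historical_ids), self.n_dropped)


def read_ipd_csv(
    path,
    column_map: dict[str, str] | None = None,
    new_study_id: str | None = None,
    historical_ids: list[str] | None = None,
) -> IPDDataset:
    """Read long-format IPD from a CSV file.

    ``column_map`` maps canonical names (study, arm, y_baseline, y_followup)
    to the file's column names; defaults to ``study, arm, y0, y1``.
    Rows with a missing follow-up outcome are dropped (their count is kept
    on the returned dataset); rows with a missing baseline are an error.
    If ``new_study_id`` is omitted, every study is treated as historical
    unless exactly one study contains treated subjects, in which case that
    study is taken to be the new trial.
    """
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        unknown = set(column_map) - set(_CANONICAL)
        if unknown:
            raise ValueError(f"unknown canonical column(s) {sorted(unknown)}")
        colmap.update(column_map)

    raw = pd.read_csv(path, na_values=["NA", "NaN", ""], keep_default_na=True)
    missing = [v for v in colmap.values() if v not in raw.columns]
    if missing:
        raise IPDValidationError(f"missing columns in {path}: {missing}")
    df = raw[[colmap[k] for k in _CANONICAL]].copy()
    df.columns = _CANONICAL

    if df["y_baseline"].isna().any():
        rows = df.index[df["y_baseline"].isna()].tolist()
        raise IPDValidationError(f"missing baseline outcome in rows {rows[:10]}")
    for col in ("y_baseline", "y_followup", "arm"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (TypeError, ValueError) as exc:
            raise IPDValidationError(f"malformed numeric field in column {col}: {exc}") from exc
    keep = df["y_followup"].notna()
    n_dropped = int((~keep).sum())
    df = df[keep].copy()
    df["arm"] = df["arm"].astype(int)
    df["study"] = df["study"].astype(str)

    if new_study_id is None:
        treated = df.loc[df["arm"] == 1, "study"].unique()
        if len(treated) == 1:
            new_study_id = str(treated[0])
        elif len(treated) > 1:
            raise IPDValidationError(
                f"several studies contain treated subjects ({sorted(treated)}); "
                "pass new_study_id explicitly"
            )
    if historical_ids is None:
        historical_ids = [s for s in df["study"].unique() if s != new_study_id]
    return IPDDataset(df, new_study_id, list(historical_ids), n_dropped)


def write_ipd_csv(dataset: IPDDataset, path, column_map: dict[str, str] | None = None) -> None:
    """Write a dataset back to CSV (lossless for float64 values)."""
    colmap = dict(DEFAULT_COLUMNS)
    if column_map:
        colmap.update(column_map)
    out = dataset.df[_CANONICAL].copy()
    out.columns = [colmap["study"], colmap["arm"], colmap["y_baseline"], colmap["y_followup"]]
    out.to_csv(path, index=False)


@dataclass(frozen=True)
class StudyAncovaFit:
    """Least-squares ANCOVA summary for a single study."""

    study_id: str
    b0_hat: float        # intercept estimate
    b1_hat: float        # baseline-effect estimate
    se_b0: float
    se_b1: float
    n: int
    sigma_hat: float     # residual SD, denominator n - p

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("ANCOVA fit needs n >= 3")
        if not (self.se_b0 > 0 and self.se_b1 > 0):
            raise ValueError("standard errors must be positive")


def fit_study_ancova(dataset: IPDDataset, study_id: str) -> StudyAncovaFit:
    """Frequentist ANCOVA for one study: ``y_followup ~ 1 + y_baseline``
    (plus a treatment term when the study has both arms).

    Only the intercept and baseline-effect estimates and their standard
    errors are exported, since borrowing concerns the control arms only.
    """
    sub = dataset.study(study_id)
    y = sub["y_followup"].to_numpy(dtype=float)
    yb = sub["y_baseline"].to_numpy(dtype=float)
    arm = sub["arm"].to_numpy(dtype=float)
    two_arm = arm.max() > 0
    X = np.column_stack([np.ones_like(yb), yb] + ([arm] if two_arm else []))
    n, p = X.shape
    if n <= p:
        raise ValueError(f"study {study_id!r}: n={n} too small for p={p} parameters")
    if np.ptp(yb) == 0:
        raise ValueError(f"study {study_id!r}: baseline outcome is constant (rank-deficient)")
    res = sm.OLS(y, X).fit()
    resid_sd = float(np.sqrt(res.ssr / (n - p)))
    if resid_sd == 0.0:
        # exact fit: report zero residual SD but keep SEs positive for the
        # data-model invariants (degenerate, test-only situation)
        se = np.full(p, np.finfo(float).tiny)
    else:
        se = np.asarray(res.bse, dtype=float)
    return StudyAncovaFit(
        study_id=study_id,
        b0_hat=float(res.params[0]),
        b1_hat=float(res.params[1]),
        se_b0=float(se[0]),
        se_b1=float(se[1]),
        n=int(n),
        sigma_hat=resid_sd,
    )


def fit_all_studies(dataset: IPDDataset, historical_only: bool = True) -> list[StudyAncovaFit]:
    ids = dataset.historical_ids if historical_only else dataset.study_ids
    return [fit_study_ancova(dataset, s) for s in ids]
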