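"""Outcome classification and the prognostic linear regression models.

The 12-month outcome is a six-category modified Glasgow Outcome Scale
(mGOS): death < VS < MCS < severe disability < moderate disability < good
recovery. Improvement means a strict upgrade from the baseline category (VS
for UWS subjects, MCS for MCS subjects); death is never an improvement.

The prognostic models regress the binary improvement indicator on
demographics (sex, age, duration), diagnosis dummies, the CRS-R score, and
either the 8 per-hemisphere ApEn channels or the 5 per-hemisphere C-ApEn
pairs — a linear probability model fit by OLS, which is what the reported
coefficient/SE/t/R^2/F output format implies. A logistic fit is available
behind a flag. Entropy predictors default to pain-minus-rest differences
(the pain-activation reading); raw pain-condition levels are available via
``predictor_kind='pain_level'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .channels import AFFECTED_CHANNELS, DEFAULT_PAIRS, UNAFFECTED_CHANNELS, PairSpec

logger = logging.getLogger(__name__)

#: mGOS ordinal scale, coded 1-6.
MGOS_ORDER: tuple[str, ...] = (
    "death", "VS", "MCS", "severe_disability", "moderate_disability",
    "good_recovery")
MGOS_CODE: dict[str, int] = {c: i + 1 for i, c in enumerate(MGOS_ORDER)}

#: Baseline mGOS category per diagnostic group.
BASELINE_CATEGORY: dict[str, str] = {"UWS": "VS", "MCS": "MCS"}


def classify_improvement(group: str, mgos_12m: str) -> int:
    """1 iff the 12-month category strictly exceeds the group baseline."""
    if group not in BASELINE_CATEGORY:
        raise ValueError(f"group must be UWS or MCS, got {group!r}")
    if mgos_12m not in MGOS_CODE:
        raise ValueError(f"unknown mGOS category {mgos_12m!r}")
    return int(MGOS_CODE[mgos_12m] > MGOS_CODE[BASELINE_CATEGORY[group]])


def outcome_summary(meta: pd.DataFrame) -> pd.DataFrame:
    """Improved count and percentage per group.

    ``meta`` needs columns ``group`` and ``mgos_12m`` (or a precomputed
    ``improved``). Percentages are rounded to the nearest integer, matching
    the usual reporting convention.
    """
    df = meta.copy()
    if "improved" not in df.columns:
        df["improved"] = [classify_improvement(g, m)
                          for g, m in zip(df["group"], df["mgos_12m"])]
    rows = []
    for group, sub in df.groupby("group"):
        n = len(sub)
        k = int(sub["improved"].sum())
        rows.append((group, n, k, int(round(100.0 * k / n))))
    return pd.DataFrame(rows, columns=["group", "n", "improved", "pct_improved"]
                        ).set_index("group")


_MODELS = ("apen_affected", "apen_unaffected", "capen_affected", "capen_unaffected")


def model_predictors(model: str, pairs: PairSpec = DEFAULT_PAIRS) -> list[str]:
    """Entropy predictor names (channels or pairs) for one model design."""
    if model == "apen_affected":
        return list(AFFECTED_CHANNELS)
    if model == "apen_unaffected":
        return list(UNAFFECTED_CHANNELS)
    if model == "capen_affected":
        return [f"{a}-{b}" for a, b in pairs.affected]
    if model == "capen_unaffected":
        return [f"{a}-{b}" for a, b in pairs.unaffected]
    raise ValueError(f"model must be one of {_MODELS}, got {model!r}")


def entropy_responses(table: pd.DataFrame, kind: str = "difference") -> pd.DataFrame:
    """Wide per-subject entropy predictors from a tidy entropy table.

    ``table`` is the tidy output of ``apen_matrix``/``capen_pairs`` (value
    column ``apen`` or ``capen``, measure column ``channel`` or ``pair``).
    ``kind``: 'difference' (pain minus eyes-closed, the default reading of
    pain activation), 'pain_level', or 'eyes_closed_level'.
    """
    value = "apen" if "apen" in table.columns else "capen"
    measure = "channel" if "channel" in table.columns else "pair"
    wide = table.pivot_table(index="subject_id", columns=["condition", measure],
                             values=value)
    if kind == "difference":
        out = wide["pain"] - wide["eyes_closed"]
    elif kind == "pain_level":
        out = wide["pain"]
    elif kind == "eyes_closed_level":
        out = wide["eyes_closed"]
    else:
        raise ValueError(f"unknown predictor kind {kind!r}")
    out.columns.name = None
    return out


def build_design_matrix(meta: pd.DataFrame, responses: pd.DataFrame,
                        model: str,
                        pairs: PairSpec = DEFAULT_PAIRS) -> pd.DataFrame:
    """Design matrix: intercept, sex, age, duration, TBI, stroke, CRS-R,
    plus the model's entropy predictors.

    Sex is coded male=1; diagnosis dummies are TBI and stroke against an
    'other' reference (both dummies plus an intercept are only estimable
    when a third diagnosis category exists). Raises on rank deficiency,
    naming the aliased columns.
    """
    meta = meta.set_index("subject_id") if "subject_id" in meta.columns else meta
    predictors = model_predictors(model, pairs)
    missing = [c for c in predictors if c not in responses.columns]
    if missing:
        raise ValueError(f"entropy responses missing predictors {missing}")
    common = meta.index.intersection(responses.index)
    meta = meta.loc[common]
    resp = responses.loc[common, predictors]

    X = pd.DataFrame(index=common)
    X["intercept"] = 1.0
    X["sex"] = (meta["sex"] == "male").astype(float)
    X["age"] = meta["age"].astype(float)
    X["duration"] = meta["duration"].astype(float)
    X["TBI"] = (meta["diagnosis"] == "TBI").astype(float)
    X["stroke"] = (meta["diagnosis"] == "stroke").astype(float)
    X["crs_r"] = meta["crs_r"].astype(float)
    for c in predictors:
        X[c] = resp[c].astype(float)

    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        aliased = _aliased_columns(X)
        raise ValueError(
            f"design matrix is rank deficient (rank {rank} < {X.shape[1]}); "
            f"aliased columns: {aliased}")
    return X


def _aliased_columns(X: pd.DataFrame) -> list[str]:
    """Columns that do not increase the rank when added left to right."""
    out = []
    cols: list[np.ndarray] = []
    rank = 0
    for name in X.columns:
        cols.append(X[name].to_numpy())
        new_rank = np.linalg.matrix_rank(np.column_stack(cols))
        if new_rank == rank:
            out.append(name)
            cols.pop()
        rank = new_rank
    return out


@dataclass
class RegressionTable:
    """Per-predictor estimates plus the overall fit summary."""

    coefficients: pd.DataFrame   # estimate, std_error, t, p per predictor
    r_squared: float
    adj_r_squared: float
    f_statistic: float
    f_df: tuple[int, int]
    f_pvalue: float
    residual_se: float
    residual_df: int
    n: int
    model: str

    def __post_init__(self) -> None:
        # residual df must equal n minus the number of estimated parameters
        assert self.residual_df == self.n - len(self.coefficients), \
            "residual-df identity violated"

    def to_frame(self) -> pd.DataFrame:
        return self.coefficients.copy()


def fit_improvement_model(X: pd.DataFrame, improved: pd.Series | np.ndarray,
                          model: str = "custom",
                          method: str = "ols") -> RegressionTable:
    """OLS (linear probability) fit of improvement on a design matrix.

    ``method='logistic'`` substitutes a logit fit (coefficient table only;
    R^2 columns then carry the pseudo-R^2 and the LR statistic).
    """
    y = np.asarray(improved, dtype=float)
    if len(y) != len(X):
        raise ValueError("label length does not match design")
    if len(y) <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    if method == "logistic":
        fit = sm.Logit(y, X.to_numpy()).fit(disp=0)
        coef = pd.DataFrame(
            {"estimate": fit.params, "std_error": fit.bse,
             "t": fit.tvalues, "p": fit.pvalues}, index=list(X.columns))
        return RegressionTable(
            coefficients=coef, r_squared=float(fit.prsquared),
            adj_r_squared=float("nan"), f_statistic=float(fit.llr),
            f_df=(int(fit.df_model), int(fit.df_resid)),
            f_pvalue=float(fit.llr_pvalue),
            residual_se=float("nan"), residual_df=int(fit.df_resid),
            n=len(y), model=model)
    if method != "ols":
        raise ValueError("method must be 'ols' or 'logistic'")
    fit = sm.OLS(y, X.to_numpy()).fit()
    coef = pd.DataFrame(
        {"estimate": fit.params, "std_error": fit.bse,
         "t": fit.tvalues, "p": fit.pvalues}, index=list(X.columns))
    return RegressionTable(
        coefficients=coef,
        r_squared=float(fit.rsquared),
        adj_r_squared=float(fit.rsquared_adj),
        f_statistic=float(fit.fvalue),
        f_df=(int(fit.df_model), int(fit.df_resid)),
        f_pvalue=float(fit.f_pvalue),
        residual_se=float(np.sqrt(fit.mse_resid)),
        residual_df=int(fit.df_resid),
        n=len(y),
        model=model)


def fit_all_models(meta: pd.DataFrame, apen_table: pd.DataFrame,
                   capen_table: pd.DataFrame,
                   predictor_kind: str = "difference",
                   pairs: PairSpec = DEFAULT_PAIRS,
                   method: str = "ols") -> dict[str, RegressionTable]:
    """Fit the four prognostic designs (ApEn/C-ApEn x affected/unaffected)."""
    meta = meta.set_index("subject_id") if "subject_id" in meta.columns else meta
    if "improved" not in meta.columns:
        meta = meta.copy()
        meta["improved"] = [classify_improvement(g, m)
                            for g, m in zip(meta["group"], meta["mgos_12m"])]
    out = {}
    for model in _MODELS:
        table = apen_table if model.startswith("apen") else capen_table
        responses = entropy_responses(table, predictor_kind)
        X = build_design_matrix(meta, responses, model, pairs)
        out[model] = fit_improvement_model(
            X, meta.loc[X.index, "improved"], model=model, method=method)
    return out
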