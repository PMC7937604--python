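"""Group comparisons: pain-minus-rest difference scores, per-measure Welch
t-tests, and two-sample Hotelling T^2 over channel blocks.

The per-measure tests compare UWS and MCS either on eyes-closed baseline
levels or on condition differences. Because 16 channels (or 10 pairs) are
tested at once, the block-level Hotelling T^2 serves as the multiple-
comparison correction: one multivariate test per channel block (affected /
unaffected ApEn channels; affected / unaffected C-ApEn pairs). Significance
stars follow the three-tier convention *P<0.1, **P<0.05, ***P<0.01.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .channels import AFFECTED_CHANNELS, DEFAULT_PAIRS, UNAFFECTED_CHANNELS, PairSpec

logger = logging.getLogger(__name__)


def condition_difference(table: pd.DataFrame) -> pd.DataFrame:
    """Pain minus eyes-closed per subject per measure (tidy).

    Accepts the tidy output of ``apen_matrix`` (value column ``apen``,
    measure column ``channel``) or ``capen_pairs`` (``capen``/``pair``).
    Subjects missing either condition are dropped and logged.
    """
    value = "apen" if "apen" in table.columns else "capen"
    measure = "channel" if "channel" in table.columns else "pair"
    wide = table.pivot_table(index="subject_id", columns=["condition", measure],
                             values=value)
    for cond in ("eyes_closed", "pain"):
        if cond not in wide.columns.get_level_values(0):
            raise ValueError(f"condition {cond!r} absent from table")
    ec, pain = wide["eyes_closed"], wide["pain"]
    complete = ec.notna().all(axis=1) & pain.notna().all(axis=1)
    dropped = list(wide.index[~complete])
    if dropped:
        logger.warning("subjects dropped from difference table "
                       "(incomplete conditions): %s", dropped)
    diff = (pain - ec).loc[complete]
    out = diff.reset_index().melt(id_vars="subject_id", var_name=measure,
                                  value_name="difference")
    return out


def ttest_by_measure(values: pd.DataFrame, groups: pd.Series,
                     equal_var: bool = False) -> pd.DataFrame:
    """Two-sample t-test (Welch by default) per measure.

    ``values``: tidy frame with columns (subject_id, <measure>, <value>),
    where <measure> is 'channel' or 'pair' and <value> the last column.
    ``groups``: subject_id -> 'UWS'/'MCS'. Returns per-measure group means,
    SDs, n's, t, two-sided p, and the significance tier.
    """
    measure = "channel" if "channel" in values.columns else "pair"
    value_col = values.columns[-1]
    rows = []
    for meas, sub in values.groupby(measure, sort=False):
        g = groups.loc[sub["subject_id"]].to_numpy()
        x = sub[value_col].to_numpy()
        uws, mcs = x[g == "UWS"], x[g == "MCS"]
        if len(uws) < 2 or len(mcs) < 2:
            raise ValueError("need at least 2 subjects per group")
        if uws.std() == 0 and mcs.std() == 0:
            t, p = (0.0, np.nan) if uws.mean() == mcs.mean() else (np.inf, np.nan)
            logger.warning("measure %s has zero variance in both groups", meas)
        else:
            t, p = sstats.ttest_ind(uws, mcs, equal_var=equal_var)
        rows.append((meas, len(uws), float(uws.mean()), float(uws.std(ddof=1)),
                     len(mcs), float(mcs.mean()), float(mcs.std(ddof=1)),
                     float(t), float(p), significance_stars(p)))
    return pd.DataFrame(rows, columns=[
        measure, "n_uws", "mean_uws", "sd_uws", "n_mcs", "mean_mcs", "sd_mcs",
        "t", "p", "stars"])


@dataclass(frozen=True)
class HotellingResult:
    """Two-sample Hotelling T^2 with its exact F transformation.

    F = ((n1 + n2 - k - 1) / (k (n1 + n2 - 2))) * T^2 on (k, n1+n2-k-1)
    degrees of freedom. Both the raw T^2 and the F statistic are reported;
    the p-value comes from the F distribution.
    """

    t2: float
    f: float
    df1: int
    df2: int
    p: float
    k: int
    n1: int
    n2: int


def hotelling_two_sample(x1: np.ndarray, x2: np.ndarray) -> HotellingResult:
    """Two-sample Hotelling T^2 for subjects x measures arrays."""
    x1 = np.atleast_2d(np.asarray(x1, dtype=float))
    x2 = np.atleast_2d(np.asarray(x2, dtype=float))
    n1, k = x1.shape
    n2, k2 = x2.shape
    if k != k2:
        raise ValueError("groups must share the measure dimension")
    if min(n1, n2) <= k:
        raise ValueError(f"per-group n must exceed k={k} measures")
    d = x1.mean(axis=0) - x2.mean(axis=0)
    s_pooled = (((n1 - 1) * np.cov(x1, rowvar=False)
                 + (n2 - 1) * np.cov(x2, rowvar=False)) / (n1 + n2 - 2))
    s_pooled = np.atleast_2d(s_pooled)
    try:
        sol = np.linalg.solve(s_pooled, d)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "pooled covariance is singular; drop collinear measures or add "
            "a ridge before testing") from exc
    t2 = float((n1 * n2) / (n1 + n2) * d @ sol)
    df1, df2 = k, n1 + n2 - k - 1
    f = (df2 / (k * (n1 + n2 - 2))) * t2
    p = float(sstats.f.sf(f, df1, df2))
    return HotellingResult(t2=t2, f=float(f), df1=df1, df2=df2, p=p,
                           k=k, n1=n1, n2=n2)


def default_blocks(pairs: PairSpec = DEFAULT_PAIRS) -> dict[str, list[str]]:
    """Channel/pair blocks for the multivariate tests."""
    return {
        "apen_affected": list(AFFECTED_CHANNELS),
        "apen_unaffected": list(UNAFFECTED_CHANNELS),
        "capen_affected": [f"{a}-{b}" for a, b in pairs.affected],
        "capen_unaffected": [f"{a}-{b}" for a, b in pairs.unaffected],
    }


def hotelling_blocks(values: pd.DataFrame, groups: pd.Series,
                     blocks: dict[str, list[str]] | None = None,
                     pairs: PairSpec = DEFAULT_PAIRS) -> pd.DataFrame:
    """Hotelling T^2 per channel/pair block on a tidy value frame."""
    measure = "channel" if "channel" in values.columns else "pair"
    value_col = values.columns[-1]
    wide = values.pivot_table(index="subject_id", columns=measure,
                              values=value_col)
    if blocks is None:
        blocks = {name: cols for name, cols in default_blocks(pairs).items()
                  if all(c in wide.columns for c in cols)}
    rows = []
    for name, cols in blocks.items():
        sub = wide[cols].dropna()
        g = groups.loc[sub.index]
        n_min = min((g == "UWS").sum(), (g == "MCS").sum())
        if n_min <= len(cols):
            logger.warning("block %s skipped: per-group n=%d does not exceed "
                           "k=%d measures", name, n_min, len(cols))
            continue
        res = hotelling_two_sample(sub[g == "UWS"].to_numpy(),
                                   sub[g == "MCS"].to_numpy())
        rows.append((name, res.k, res.t2, res.f, res.df1, res.df2, res.p,
                     significance_stars(res.p)))
    return pd.DataFrame(rows, columns=["block", "k", "t2", "f", "df1", "df2",
                                       "p", "stars"])


def significance_stars(p: float) -> str:
    """Three-tier star convention: *P<0.1, **P<0.05, ***P<0.01."""
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "***"
    if p < 0.05:
        return "**"
    if p < 0.1:
        return "*"
    return ""


def describe_cohort(meta: pd.DataFrame) -> pd.DataFrame:
    """Baseline table: group means +/- SD with t-tests for interval
    variables, counts with chi-squared tests for categorical ones."""
    rows = []
    g = meta["group"]
    for var in ("age", "duration", "crs_r"):
        uws = meta.loc[g == "UWS", var].astype(float)
        mcs = meta.loc[g == "MCS", var].astype(float)
        t, p = sstats.ttest_ind(uws, mcs, equal_var=False)
        rows.append((var, f"{uws.mean():.1f} ± {uws.std(ddof=1):.1f}",
                     f"{mcs.mean():.1f} ± {mcs.std(ddof=1):.1f}",
                     float(p)))
    for var in ("sex", "diagnosis"):
        tab = pd.crosstab(meta[var], g)
        chi2, p, _, _ = sstats.chi2_contingency(tab)
        uws_counts = ", ".join(f"{idx}: {v}" for idx, v in tab["UWS"].items())
        mcs_counts = ", ".join(f"{idx}: {v}" for idx, v in tab["MCS"].items())
        rows.append((var, uws_counts, mcs_counts, float(p)))
    return pd.DataFrame(rows, columns=["variable", "UWS", "MCS", "p"])


def render_comparison_table(result: pd.DataFrame, title: str = "") -> str:
    """Readable text table: mean +/- SD per group, p with stars."""
    measure = result.columns[0]
    lines = []
    if title:
        lines += [title, "-" * len(title)]
    lines.append(f"{measure:<14} {'UWS':>16} {'MCS':>16} {'p':>10}")
    for _, row in result.iterrows():
        uws = f"{row['mean_uws']:.3f} ± {row['sd_uws']:.3f}"
        mcs = f"{row['mean_mcs']:.3f} ± {row['sd_mcs']:.3f}"
        p = f"{row['p']:.4g}{row['stars']}"
        lines.append(f"{row[measure]:<14} {uws:>16} {mcs:>16} {p:>10}")
    return "\n".join(lines)
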