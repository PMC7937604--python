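"""Simulation studies validating the analysis end to end.

Three reusable experiments, each a pure function of its seed:

* ``direction_study`` — replicate synthetic cohorts through the full
  signal pipeline and check the qualitative group pattern (MCS above UWS at
  rest on every channel; pain responses larger in MCS on unaffected-side
  measures; no affected-side ApEn group difference at the block level);
* ``null_calibration`` — empirical type-I error of the Welch t and the
  Hotelling T^2 under a simulated null;
* ``recovery_study`` — coverage of the prognostic OLS confidence intervals
  for the generating coefficients of the synthetic outcome model.

These back both the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .pipeline import run_full_analysis
from .prognosis import build_design_matrix, entropy_responses, \
    fit_improvement_model
from .simulate import CohortConfig, generate_cohort
from .stats import hotelling_two_sample, ttest_by_measure

#: Outcome model used by the recovery study: every nonzero generating
#: coefficient belongs to the fitted design (apen_affected), so OLS is
#: consistent for the truth and CI coverage is meaningful.
RECOVERY_COEFFICIENTS = {"intercept": 0.10, "crs_r": 0.03,
                         "P_A": 1.2, "O_A": -0.8}


def direction_study(n_replicates: int = 10, n_per_group: int = 30,
                    epoch_len: int = 8192, seed: int = 2024) -> pd.DataFrame:
    """Qualitative group pattern across replicate signal-tier cohorts.

    Per cohort: (a) eyes-closed ApEn larger in MCS on all 16 channels;
    (b) pain-minus-rest differences larger in MCS on every unaffected-side
    measure (8 ApEn channels + 5 C-ApEn pairs); (c) the affected-side ApEn
    difference block shows no group difference (Hotelling p > 0.05 — the
    block test is the multiplicity-corrected read-out). ``passed`` is the
    conjunction.
    """
    rows = []
    for i in range(n_replicates):
        cfg = CohortConfig(n_uws=n_per_group, n_mcs=n_per_group,
                           epoch_len=epoch_len, seed=seed + i)
        res = run_full_analysis(cfg, signals=True)

        base = res.ttest_baseline_apen
        baseline_ordered = bool((base["mean_mcs"] > base["mean_uws"]).all())

        da = res.ttest_diff_apen.set_index("channel")
        dc = res.ttest_diff_capen.set_index("pair")
        un_apen = da.loc[[c for c in da.index if c.endswith("_U")]]
        un_capen = dc.loc[[p for p in dc.index if p.endswith("_U")]]
        unaffected_larger = bool(
            (un_apen["mean_mcs"] > un_apen["mean_uws"]).all()
            and (un_capen["mean_mcs"] > un_capen["mean_uws"]).all())

        hot = res.hotelling.set_index("block")
        affected_nonsig = bool(hot.loc["apen_affected", "p"] > 0.05)

        rows.append((i, baseline_ordered, unaffected_larger, affected_nonsig,
                     baseline_ordered and unaffected_larger and affected_nonsig))
    return pd.DataFrame(rows, columns=[
        "replicate", "baseline_ordered", "unaffected_larger",
        "affected_nonsignificant", "passed"])


def null_calibration(n_replicates: int = 1000, n_per_group: int = 30,
                     k: int = 5, alpha: float = 0.05,
                     seed: int = 2024) -> dict[str, float]:
    """Empirical rejection rates of both tests under the null.

    Both groups are drawn from the same multivariate normal; Welch is
    checked on a single measure, Hotelling on k measures.
    """
    rng = np.random.default_rng(seed)
    welch_rej = 0
    hotelling_rej = 0
    subjects = ([f"u{i}" for i in range(n_per_group)]
                + [f"m{i}" for i in range(n_per_group)])
    groups = pd.Series(["UWS"] * n_per_group + ["MCS"] * n_per_group,
                       index=subjects)
    for _ in range(n_replicates):
        values = pd.DataFrame({
            "subject_id": subjects,
            "channel": "C_A",
            "apen": rng.standard_normal(2 * n_per_group)})
        p = ttest_by_measure(values, groups)["p"].iloc[0]
        welch_rej += p < alpha
        res = hotelling_two_sample(rng.standard_normal((n_per_group, k)),
                                   rng.standard_normal((n_per_group, k)))
        hotelling_rej += res.p < alpha
    return {"welch": welch_rej / n_replicates,
            "hotelling": hotelling_rej / n_replicates,
            "n_replicates": n_replicates}


def recovery_study(n_replicates: int = 50, n_per_group: int = 250,
                   seed: int = 2024,
                   coefficients: dict[str, float] | None = None,
                   model: str = "apen_affected") -> pd.DataFrame:
    """CI coverage of the generating coefficients across replicates.

    Feature-tier cohorts of 2 x n_per_group subjects; the outcome follows
    ``coefficients`` (default :data:`RECOVERY_COEFFICIENTS`); the fitted
    design's truth vector is the coefficient map with zeros elsewhere.
    Returns per-predictor coverage of the 95% CI and, for zero
    coefficients, the rate of (correct) non-significance at alpha = 0.05.
    """
    coefficients = coefficients or RECOVERY_COEFFICIENTS
    covered: dict[str, int] = {}
    nonsig: dict[str, int] = {}
    columns: list[str] = []
    for i in range(n_replicates):
        cfg = CohortConfig(n_uws=n_per_group, n_mcs=n_per_group,
                           seed=seed + i, outcome_coefficients=dict(coefficients))
        cohort = generate_cohort(cfg, signals=False)
        meta = cohort.meta
        responses = entropy_responses(cohort.apen_proxy if "apen" in model
                                      else cohort.capen_proxy)
        X = build_design_matrix(meta, responses, model)
        y = meta.set_index("subject_id").loc[X.index, "improved"]
        fit = fit_improvement_model(X, y, model=model)
        columns = list(X.columns)
        tcrit = sstats.t.ppf(0.975, fit.residual_df)
        for name in columns:
            est = fit.coefficients.loc[name, "estimate"]
            se = fit.coefficients.loc[name, "std_error"]
            truth = coefficients.get(name, 0.0)
            lo, hi = est - tcrit * se, est + tcrit * se
            covered[name] = covered.get(name, 0) + (lo <= truth <= hi)
            if name not in coefficients:
                nonsig[name] = nonsig.get(name, 0) + \
                    (fit.coefficients.loc[name, "p"] >= 0.05)
    rows = []
    for name in columns:
        rows.append((name, coefficients.get(name, 0.0),
                     covered[name] / n_replicates,
                     (nonsig[name] / n_replicates
                      if name not in coefficients else np.nan)))
    return pd.DataFrame(rows, columns=["predictor", "truth", "ci_coverage",
                                       "nonsignificant_rate"])
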