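# docentropy

Non-linear dynamic EEG analysis for outcome prediction in disorders of
consciousness (DOC).

Patients surviving severe brain injury in an unresponsive wakefulness
syndrome (UWS, also called vegetative state) or a minimally conscious
state (MCS) are hard to prognosticate at the bedside. One quantitative
approach measures the *irregularity* of the EEG: **approximate entropy
(ApEn)** of each channel indexes local cortical complexity, and
**cross-approximate entropy (C-ApEn)** between channel pairs indexes the
(a)synchrony of residual cortical networks. Comparing both measures
between an eyes-closed baseline and a pain-stimulation condition, on
16-channel 10–20 EEG relabeled to the affected/unaffected hemisphere,
gives per-patient response profiles; a linear probability model then
relates those profiles (plus CRS-R and demographics) to 12-month
improvement on the modified Glasgow Outcome Scale (mGOS).

This package implements that full pipeline for clinical neurophysiology
and biostatistics researchers: reading/preprocessing recordings, the
entropy measures (with a brute-force oracle), group statistics (Welch t
per measure, Hotelling T² per channel block), the prognostic regressions —
and a synthetic cohort generator with the assumed statistical structure,
so everything runs and is validated without patient data.

## The measures

With templates `x_i = (u_i, …, u_{i+m−1})`, Chebyshev distance,
self-matches included and `r = 0.2·SD`:

    Φ^m(r) = (N−m+1)^{-1} Σ_i ln [ #{j : d(x_i,x_j) ≤ r} / (N−m+1) ]
    ApEn(m, r, N) = Φ^m(r) − Φ^{m+1}(r)

C-ApEn is identical in design but matches templates of one (z-scored)
series against targets of another; the central electrode always supplies
the templates. Defaults: `m = 2`, `r = 0.2·SD`, epochs of 32,768 samples
at 500 Hz (65.536 s). See `docs/methods.md` for conventions (zero-match
handling, standardization, tie-breaks) and the generator's design.

## Worked example

```python
import numpy as np
from docentropy import ApEnParams, CohortConfig, apen, generate_channel_signal
from docentropy.pipeline import run_full_analysis

# ApEn tracks the irregularity dial of the synthetic signal family
rng = np.random.default_rng(0)
p = ApEnParams(n_points=8192)
calm = generate_channel_signal(0.2, 8192, 500, rng)       # oscillation-dominated
irregular = generate_channel_signal(0.6, 8192, 500, rng)  # noise-dominated
print(f"ApEn calm={apen(calm, p):.3f}  irregular={apen(irregular, p):.3f}")

# Full analysis of a 98 UWS + 64 MCS synthetic cohort (fast feature tier)
res = run_full_analysis(CohortConfig(seed=1), signals=False)
print(res.outcome)
reg = res.regressions["apen_affected"]
print(reg.coefficients.loc[["crs_r", "P_A"]].round(4))
print(f"R^2 {reg.r_squared:.3f}, residual df {reg.residual_df}")
```

prints

```
ApEn calm=0.657  irregular=1.291
        n  improved  pct_improved
group
MCS    64        40            62
UWS    98        24            24
       estimate  std_error       t       p
crs_r    0.0463     0.0084  5.5307  0.0000
P_A      0.8985     0.8056  1.1153  0.2665
R^2 0.215, residual df 147
```

The low ApEn of the oscillation-dominated signal versus the
noise-dominated one is the complexity ordering the measure is built to
detect. In the simulated cohort, roughly a quarter of UWS and two thirds
of MCS subjects improve by 12 months (the generator's calibrated rates);
the affected-side ApEn regression keeps 147 residual degrees of freedom
(162 subjects − 15 parameters), recovers the CRS-R effect clearly, and —
at this single-cohort sample size — estimates the P_A pain-response
coefficient near its generating value of 1.0 with a wide standard error.

Passing `signals=True` (the default) instead synthesizes full 16-channel
recordings and measures entropy from them: notch filter, artifact-free
epoch selection, affected-side determination (imaging field, or the ApEn
tie-break when unknown), montage relabeling, then the same statistics.
That path costs minutes, not seconds; scale `n_uws/n_mcs/epoch_len`
accordingly.

## Command line

```sh
docentropy simulate --config cohort.yaml --out cohort/     # write a cohort
docentropy preprocess --in rec.csv --out epoch.csv --epoch 32768
docentropy entropy --in cohort/ --out tables/
docentropy stats --entropy tables/apen.csv --pairs tables/capen.csv \
    --meta cohort/metadata.csv --out stats/
docentropy prognosis --entropy tables/apen.csv --pairs tables/capen.csv \
    --meta cohort/metadata.csv --out prog/
docentropy run --config cohort.yaml --out results/         # all of the above
```

Recordings travel as CSV (one column per channel, JSON sidecar with the
sampling rate); EDF is read when `mne` is installed.

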