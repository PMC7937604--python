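# Methods

## The measures

**Approximate entropy (ApEn).** For a series `u` of length `N`, embedding
dimension `m` and tolerance `r`, templates are the overlapping runs
`x_i = (u_i, …, u_{i+m−1})`. With Chebyshev distance and self-matches
included,

    C_i^m(r) = #{ j : d(x_i, x_j) ≤ r } / (N − m + 1)
    Φ^m(r)   = mean_i ln C_i^m(r)          (over the N − m + 1 templates)
    ApEn     = Φ^m(r) − Φ^{m+1}(r)

ApEn is non-negative in expectation and grows with signal irregularity: it
is the negative average log conditional probability that runs close for `m`
points stay close for `m + 1`. Defaults are the canonical EEG settings
`m = 2`, `r = 0.2·SD`, applied to analysis epochs of 32,768 samples at
500 Hz (65.536 s). Because `r` scales with the SD, ApEn is invariant under
affine amplitude maps; the implementation z-scores internally and uses
`r = r_factor` on the unit-SD scale, which is the same statistic.

**Cross-approximate entropy (C-ApEn).** The two-series analogue: templates
from one channel are matched against targets from another, measuring
asynchrony (lower = more synchronized). Both series are z-scored before
matching and `r` is taken relative to unit SD — cross-channel amplitudes
differ, and without a convention the statistic would depend on which
channel's SD sets `r`. Since self-matches are included in ApEn,
`capen(u, u) = apen(standardize(u))` exactly; the tests assert this
bitwise. C-ApEn is asymmetric; the central electrode (C_A or C_U) always
supplies the templates, matching the order in which the ten designated
pairs are written (local: C–P, C–F, C–MT; distant: C–FP, C–O, per
hemisphere).

**Zero matches.** A cross-template with no match has undefined `ln C`.
Such templates are excluded from the Φ average and counted; a value is
flagged unreliable when more than 10% of templates at either embedding
level had no match. The alternative (flooring counts at one) was rejected
because it biases short toy series, exactly where the flag matters.

**Kernels.** The optimized implementation sorts templates by first
coordinate; each template's candidate set is then one contiguous window
(first-coordinate distance lower-bounds the Chebyshev distance), and the
remaining coordinates are checked branchlessly inside the window so the
inner loop vectorizes. Counts at dimensions m and m+1 accrue in one pass.
Windows are a filter, never an approximation: a brute-force double-loop
oracle (`reference.py`, kept free of shared code) agrees to 1e−12 on random
short series for m ∈ {1, 2, 3}. Ties at the tolerance boundary use `≤ r`.
Constant series return ApEn 0 with a warning (all templates identical).

## Montage and preprocessing

Recordings are the 16-channel 10–20 subset (FP1/2, F3/4, C3/4, P3/4, O1/2,
F7/8, T3/4, T5/6; T7/T8/P7/P8 accepted as synonyms), earlobe-referenced at
acquisition, 0.3–100 Hz bandwidth, 500 Hz sampling. The 0.3–100 Hz
band-pass is treated as an acquisition property and not re-applied; only
the 50-Hz mains notch (zero-phase second-order IIR, Q = 30) runs in
software.

The analysis epoch is the earliest run of `n_points` consecutive samples in
which no channel exceeds an absolute amplitude threshold (default 100 µV).
This is an automated, reproducible stand-in for expert visual epoch
selection; the threshold is configurable and the selected window start is
recorded.

Channels are relabeled left/right → affected/unaffected once the more
severely injured hemisphere is known: from imaging when available,
otherwise the hemisphere with the lower mean eyes-closed ApEn over its 8
channels is labeled affected (lower complexity = more severe impairment).
An exact tie resolves to left with a logged warning. The temporal chain
F7/F8, T3/T4, T5/T6 maps to AT (anterior), MT (middle), PT (posterior)
temporal by standard 10–20 nomenclature.

## Group statistics

Pain-minus-rest difference scores are formed per subject per measure.
Group comparisons use the Welch (unequal-variance) two-sample t per
measure; the pooled-variance test is available via a flag. Because 16
channels or 10 pairs are tested at once, the block-level two-sample
Hotelling T² is the multiple-comparison correction: one multivariate test
per channel block (8 affected / 8 unaffected ApEn channels; 5 affected /
4–5 unaffected C-ApEn pairs), with the exact F transform
`F = ((n1+n2−k−1)/(k(n1+n2−2)))·T²` on `(k, n1+n2−k−1)` df. Both T² and F
are reported, as conventions for the printed statistic differ. No further
multiplicity correction is applied beyond the blocks. Significance stars
follow *P<0.1, **P<0.05, ***P<0.01.

## Outcome and prognosis

The 12-month outcome is the six-category modified Glasgow Outcome Scale
(death < VS < MCS < severe < moderate disability < good recovery, coded
1–6). Improvement is a strict upgrade from the baseline category — VS for
UWS subjects, MCS for MCS subjects; death is never an improvement.

The prognostic models regress the binary improvement indicator on
intercept, sex (male = 1), age, duration, diagnosis dummies (TBI and
stroke against an `other` reference), CRS-R total, and either the 8
per-hemisphere ApEn channels or the 5 per-hemisphere C-ApEn pairs. OLS on
the 0/1 outcome (a linear probability model) is the default because that
is what coefficient/SE/t/R²/F output implies; a logistic fit sits behind a
flag. Entropy predictors default to pain-minus-rest differences (the
pain-activation reading); raw condition levels are available. With
n = 162 the ApEn designs leave 147 residual df (15 parameters) and the
C-ApEn designs 150 (12 parameters). Note the `other` diagnosis reference is
required: with an exhaustive TBI/stroke coding, both dummies plus an
intercept are collinear and the design is rank-deficient (the package
raises, naming the aliased column).

## The synthetic cohort generator

No public dataset accompanies this analysis, so validation runs on
synthetic cohorts with the assumed statistical structure.

**Signal tier.** Each channel is
`(1 − g)·oscillation + g·noise`, where the oscillation is a random-phase
1–4 Hz plus 8–12 Hz pair, the noise is 0.3–100 Hz band-limited Gaussian,
and `g` (the irregularity dial) controls complexity: measured ApEn rises
monotonically in `g`, steeply up to `g ≈ 0.5` and saturating above.
Channels within a hemisphere mix an independent component with a shared
latent source (`√(1−c)·own + √c·shared`); at `c = 1` paired channels are
identical and pair C-ApEn equals channel ApEn. Because C-ApEn is an
all-pairs template statistic, it responds to coupling through
*distributional* similarity, not time-locked correlation: the shared
source lowers pair C-ApEn by suppressing the between-channel irregularity
traits, which is why those traits are part of the generator. Signals are scaled to 15 µV SD, comfortably
inside the 100 µV artifact threshold.

Group structure (the defaults, fixed once after calibrating the ApEn
response of this signal family): UWS baseline irregularity 0.20, MCS 0.35
(between-subject SD 0.05; additionally each channel carries a persistent
topographic irregularity trait, SD 0.08, shared by both conditions), both
on the steep segment of the response so pain gains translate into entropy
elevations without saturation; the
affected hemisphere sits 0.06 lower (more impaired = less complex, which
also makes the ApEn tie-break recover the true side); pain adds +0.06
(UWS) / +0.16 (MCS) on the unaffected hemisphere and exactly 0 (both
groups) on the affected one — pain activation is modeled as an
unaffected-hemisphere, consciousness-level-dependent phenomenon, and the
affected gain must be identical across groups for the intended
affected-side null to hold exactly on the saturating ApEn response (a
common nonzero step would land on group-different slope points and leak a
small systematic difference);
hemispheric coupling 0.5 (UWS) vs 0.3 (MCS). CRS-R is an integer 0–23 with
group-shifted normals (5 ± 2.5 vs 13 ± 2.5). Diagnosis mixes
TBI/stroke/other at 0.50/0.45/0.05 — the small `other` class keeps both
dummies estimable. The imaging-known affected side is withheld
(`unknown`) for 15% of subjects to exercise the tie-break.

**Outcome model.** Improvement follows a clamped linear-probability model,
by default `p = 0.01 + 0.035·CRS-R + 1.0·ΔApEn(P_A) + 0.6·ΔC-ApEn(C_U–MT_U)`,
calibrated once so the expected improvement rates are ≈26% (UWS) and ≈66%
(MCS). Given improvement status, the 12-month category is drawn from
conditional mixes that emulate the observed outcome distributions
(improved UWS land in MCS or severe disability; non-improved UWS rarely
die; non-improved MCS stay MCS).

**Feature tier.** Statistical validations that need hundreds of subjects
and dozens of replicates (null calibration, CI coverage) cannot afford
entropy on full signals. The generator therefore also emits entropy tables
directly through a fixed affine proxy map from the same latent parameters
(ApEn ≈ 0.24 + 2.0·irregularity; C-ApEn ≈ ApEn level + 0.03 − 0.02·c),
with per-channel level noise SD 0.04 and difference noise SD 0.05. The
proxy constants were calibrated once against the signal tier and are part
of the generator definition, not free parameters. Both tiers share one
latent parameterization, so the downstream code is identical.

**Determinism.** One master seed; subject `i`'s stream is
`SeedSequence(seed, spawn_key=(i,))`, so cohorts are order-independent and
bit-reproducible.

**What the generator does not emulate.** No forward head model, no 1/f
background, no physiological artifacts beyond an optional amplitude-spike
injector, no mains interference, no non-stationarity within an epoch, no
real relationship between diagnosis and EEG. Passing tests therefore show
that the pipeline recovers structure that is present by construction —
directionally faithful to the modeled study — not that it would behave
identically on clinical EEG.

## Validation studies and problem sizes

* **Direction study**: 10 replicate signal cohorts, 30 subjects per group,
  8,192-sample epochs (the full pipeline, entropy measured from signals).
  Checks per cohort: MCS > UWS eyes-closed ApEn on all 16 channels; larger
  MCS pain-minus-rest response on every unaffected-side measure (8
  channels + 5 pairs); affected-side ApEn differences non-significant at
  the Hotelling block level, the block test being the analysis's own
  multiplicity correction (requiring all eight univariate affected tests
  to clear 0.05 would fail ≈ 1 − 0.95⁸ ≈ 34% of true-null cohorts by
  construction). Pass requires ≥ 8/10 cohorts.
* **Null calibration**: 1,000 replicates of two n = 30 groups from one
  normal distribution; Welch (1 measure) and Hotelling (k = 5) must reject
  3–7% at α = 0.05.
* **Recovery study**: 50 feature-tier cohorts of 500 subjects whose
  outcome follows known coefficients lying inside the fitted design
  (intercept 0.10, CRS-R 0.03, P_A 1.2, O_A −0.8 in the affected-ApEn
  design), so OLS is consistent for the truth. Every coefficient's 95% CI
  must cover its generating value in ≥ 90% of replicates, and true-zero
  coefficients must be non-significant in ≥ 90%.

## Numerical choices and degenerate inputs

* Population SD (ddof = 0) everywhere in the entropy layer.
* Distance comparisons are inclusive (`≤ r`); boundary ties are counted.
* ApEn of a constant series is 0 (warning); cross-entropy of constant
  series mean-centers without scaling, so identical constants match
  everywhere and give 0.
* `filtfilt` edge transients in the generator's noise are removed by
  generating a 200-sample margin per side and trimming.
* Singular pooled covariance in Hotelling raises with advice rather than
  silently regularizing; blocks that exceed the per-group sample size are
  skipped with a warning in the pipeline, not fabricated.
* The epoch selector is re-checkable: its output always satisfies its own
  artifact criterion, and reapplying it is the identity.

## Known limitations

* The generator's entropy scale (≈0.6–1.2) sits above typical clinical
  EEG ApEn (≈0.5–0.8); directions and contrasts, not absolute levels, are
  the validated quantities.
* The proxy map linearizes a saturating response; it is accurate on the
  calibrated segment (irregularity 0.1–0.5) only.
* C-ApEn at the canonical (m=2, r=0.2) settings is insensitive to
  instantaneous (lag-0) dependence between channels — matching counts sum
  over all template pairs, of which time-aligned ones are a ~1/N
  fraction. The coupling dial therefore acts through suppression of
  between-channel irregularity heterogeneity, and its measured effect is
  modest; group contrasts in C-ApEn are driven mainly by irregularity.
* One bilateral pain epoch is generated by default; a two-epoch mode
  exists (`two_epoch_pain`) but downstream analysis uses the single `pain`
  condition.
* EDF files are read (via `mne`) but written only as CSV + JSON sidecar;
  no EDF writer dependency is available.

## Calibration caveat: the affected-side block test

The affected-side pain response is null by construction (the affected
hemisphere's generative parameters are identical in both conditions), but
the two groups' difference-score covariances are not equal: ApEn-estimate
noise depends on how smooth the underlying signal is, so the UWS group
(smoother by design) has a different per-channel variance and shared-latent
correlation than the MCS group. The classical two-sample Hotelling T²
assumes a common covariance; under these conditions its empirical type-I
error at n = 30 per group and k = 8 channels measures ~8–10% rather than
5% (replicate simulations at 2,048- and 8,192-sample epochs; equalizing
the group couplings does not remove it). The direction study's ≥ 8/10
margin absorbs this in expectation, but individual replicate sets can
dip to 7/10. This mirrors a real property of the analysis, not a bug in
the test: group-dependent signal smoothness makes the equal-covariance
assumption of the multivariate test only approximately true.
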