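# Methods

## Model and procedure

The pipeline estimates gestational-week (GW) specific 95% reference
intervals (RIs) for serum creatinine (SCr) in healthy pregnancy and derives
an eGFR formula from the physiological hyperfiltration those intervals
encode.

**Binning.** GW 0-3 (pre-implantation, assumed hemodynamically unchanged)
is a fixed first bin; its median SCr is the baseline BSC. Weeks 4-41 are
covered by 3-4-week bins. The default layout places bin edges at
`4 + round(38·i/11)`, i = 0..11, giving 11 bins of alternating width 3 and
4 and hence 12 gestational periods (GPs) in total; a uniform width of 3 or
4 can be configured instead. Bins below `min_per_bin = 20` measurements
(the CLSI small-subclass minimum) are merged forward greedily; a leftover
tail merges into the last closed period.

**Mean-of-two bootstrap.** Each GP is amplified to t = 120 values — the
CLSI recommended observation count — by drawing two member values (without
replacement within a pair, independently across the 120 iterations) and
recording their mean. The resample must satisfy: Pearson kurtosis in
[2.5, 3.5] (normal = 3; the Pearson convention is used because the window
is centred on 3), skewness in [−0.5, 0.5], Shapiro-Wilk p ≥ 0.05. Sorted,
the 3rd and 118th values form the 95% interval; for general t the ranks
are `ceil(0.025·t)` and `t + 1 − ceil(0.025·t)` (an epsilon guard protects
the ceiling against floating-point products like 0.025·120 →
3.0000000000000027). Verification requires ≥ 95% of the GP's original
measurements inside the closed interval.

**Retry policy.** The procedure is silent on failed attempts; we redraw
with the next state of one deterministic stream, cap at
`max_attempts = 1000`, and surface failure. When the cap is reached the
*first* Gaussian-passing attempt is returned (unbiased in interval width,
mirroring a sequential stopping rule) or, failing that, the last attempt;
`accepted` stays false and the caller decides.

**A quantitative note on coverage.** Averaging pairs shrinks dispersion by
√2, so the 3rd-118th range of the resample spans ≈ ±1.386σ of the original
data and is expected to cover only ~83% (Gaussian) to ~91% (right-skewed)
of it. The ≥ 95% verification is therefore essentially unattainable for
well-behaved GPs of realistic size: in simulation, the best coverage over
hundreds of retries plateaus near 0.90-0.92 and a Normal(50, 5²) GP of 200
never passes. The package implements the rule exactly as stated and keeps
`accepted` as the full conjunction, but the end-to-end pipeline proceeds
with non-accepted sets (logging which GPs fell short) instead of aborting;
`smooth_limits` retains a strict `require_accepted=True` default for
callers who want the letter of the rule. Accepted-implies-coverage is
asserted in the tests as the implication it is.

**Smoothing.** For each requested percentile (by default 2.5/50/97.5, plus
95/75 for the external comparison), a point is placed at each GP's
midpoint — the symmetric choice of abscissa; the pre-implantation GP is
excluded — at the order-statistic quantile of its resample set. The
polynomial degree (1-5, raw ascending-power basis so coefficients read
like the canonical equation; conditioning is acceptable on [4, 41]) is
selected by 3-fold cross-validation: per repeat one random fold partition
(sizes differing by ≤ 1, re-drawn every repeat) is shared across degrees,
the argmin-MSE degree is recorded with ties broken toward the smaller
degree, and the modal degree over 1000 repeats wins (mode ties also break
small). The final curve is OLS on all points, domain GW 4-41.

**Gestational eGFR.** `eGFR = (2 − SCr/BSC) × normal_GFR × BSC/median(GW)`
with BSC = 55.25 μmol/L and normal_GFR = 103.1 mL/min (110.1 mL/min/1.73 m²
× 1.62 m² / 1.73 m²). The prose definition of k_gw (median/BSC) and the
displayed formula (BSC/median) are reciprocal; the displayed formula
governs, as it is what the final equation uses. SCr ≥ 2·BSC yields
eGFR ≤ 0 and is flagged with a warning rather than silently returned. The
eGFR RI re-runs binning/bootstrap/smoothing on the transformed values
(GW ≥ 4 only); nominal bounds of the first eGFR period are clipped to
GW ≥ 4 so the empty pre-implantation bin cannot distort its midpoint.

**Increment columns.** The canonical table's increment column is
reproduced exactly only when computed from the 0.1-rounded median
(e.g. GW 22: 100·(39.8/55.25 − 1) → −28.0%, while the unrounded value
gives −27.9%); the package follows the rounded-median convention. The eGFR
increment baseline is configurable; the pipeline uses the eGFR implied by
the pre-implantation median SCr (`normal_GFR·(2 − median₀₋₃/BSC)`,
≈ normal_GFR), since the baseline behind the canonical eGFR increment
column is not stated and is not recoverable from the rounded table values;
the canonical eGFR percentile columns themselves derive from a refit on
the original (unavailable) cohort and are not asserted against.

**External comparison.** Study percentile values (95/75/50) are rounded to
0.1 μmol/L, differenced against the external (Harel et al.) values, and
the differences rounded to 0.1 *before* aggregation — the only arithmetic
that reproduces the canonical comparison table cell-for-cell. Trimester
assignment: GW ≤ 13 → 1, ≤ 27 → 2, else 3. The canonical aggregate rows are
labelled "%" but the columns are μmol/L; the package reports μmol/L.

## Synthetic cohort generator

Defaults emulate the study conditions: 957 subjects, 1484 measurements
(each subject at least one; at most one per subject per GW), sampling
weights 10%/20%/70% across GW 0-13/14-27/28-41 (uniform within each
block). Per week, SCr follows a shifted log-normal
`loc + scale·exp(σZ)` parameterised so the median equals the truth curve
(the canonical degree-4 polynomial for GW ≥ 4, 55.25 μmol/L for GW 0-3),
the coefficient of variation equals `dispersion` and the skewness equals
`skew`. Defaults `dispersion = 0.25`, `skew = 0.76` are back-solved from
the width of the canonical reference interval at GW 22 (97.5th/median =
55.7/39.8 on the √2-shrunk resample scale ⇒ original log-sd ≈ 0.24) and
correspond to an essentially plain log-normal (loc ≈ 0). Per-GP skewness
of generated cohorts stays well below 1.5, the regime in which the
mean-of-two bootstrap is considered applicable.

`true_quantile` gives the generator's closed-form quantile
(`loc + scale·exp(σ·Φ⁻¹(p))`) as an independent oracle for recovery tests.

What the generator does *not* emulate: instrument discretisation and
inter-analyser bias, exclusion/chart-review selection effects, within-
subject correlation across weeks (repeat measurements are drawn
independently), and any pathology. Passing tests therefore demonstrate
correctness of the pipeline's statistics on data with the assumed shape,
not robustness to real-world laboratory artefacts.

## Simulation-study sizes

- *Variance law*: Gaussian GP σ = 5, size 500, 200 Monte-Carlo
  repetitions; mean CI width is checked within 15% of 2·1.96·σ/√2
  (observed ≈ 3% off). Width is taken from the first Gaussian-passing
  resample, which is unbiased; conditioning on maximal coverage would
  select wide intervals.
- *Degree recovery*: truth curves of degree 1-4 (degree 4 = the canonical
  median polynomial; degree 3 shaped like the canonical lower limit);
  50 cohorts per degree of 100 000 measurements / 50 000 subjects so that
  per-GP median noise (≈ 0.1-0.3 μmol/L) stays below the quartic-vs-cubic
  shape difference at the GP midpoints (≈ 0.7 μmol/L); degree selection
  with 100 fold-repartition repeats. Recovery ≥ 80% is required. A caveat
  inherent to the procedure: 3-fold CV on 11 points has an irreducible
  ≈ 14% chance of modal overfit when the truth is exactly linear
  (scale-free in the noise level), so the degree-1 arm sits naturally near
  the 80% bound.
- Pipeline-level tests run study-sized cohorts (1484 measurements) with
  reduced retry/repeat budgets (`max_attempts` 20-40, `repeats` 60-100),
  which leaves the statistics unchanged and keeps the suite fast.

## Numerical choices and degenerate inputs

- OLS via `numpy.linalg.lstsq` on the raw-power Vandermonde design; rank
  deficiency (e.g. duplicate abscissae at interpolation size) raises.
- Degenerate resamples (zero variance) fail the Gaussian screen with
  reason "zero variance"; a degenerate interval (lower = upper) is marked
  invalid and never accepted.
- Closed intervals throughout: boundary values count as covered and as
  "within" in patient flagging.
- All randomness flows from explicit seeds; the pipeline derives stage
  seeds from one master `SeedSequence`, so reruns are byte-identical.
- Cohort generation resolves duplicate (subject, GW) draws by redrawing
  the week; values ≤ 0 (possible only for extreme settings of the shifted
  log-normal) are rejection-sampled away.

## Known limitations

- The coverage verification is, as discussed above, near-impossible to
  satisfy generically; results downstream of non-accepted GPs are clearly
  flagged in the period diagnostics.
- The chosen polynomial degrees on any particular cohort (historically 4
  for the upper and 3 for the lower SCr limit, 4/4 for eGFR) are
  realisations of a stochastic search; the package asserts degree
  *recovery* on known truth, not those specific outcomes.
- Upper/lower/median curves are fit independently and may cross near the
  domain edges when intervals are extremely narrow (e.g. zero-dispersion
  cohorts); the combined table asserts ordering and will surface this.
- The eGFR formula is a deterministic transform of SCr calibrated to East
  Asian reference values for normal GFR and BSA; no claim is made for
  other populations, cystatin-C-based estimation, or pathological
  pregnancies.
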