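# Methods

## Scope and units

`synbath` analyses ex vivo airway pharmacology experiments of two kinds:
semi-logarithmic concentration–response curves (CRCs) of bronchorelaxant
drugs, alone and in isoeffective combination, and 12-hour electrical-field-
stimulation (EFS) time courses of the neurogenic contractile tone. One
canonical unit system is used throughout: concentrations in mol/L (log10
internally), effects as fractions of the papaverine (100 μM) maximal
relaxation, times in minutes. Percentages appear only in rendered reports
and in the delta/AUC summaries, which are conventionally printed on the %
scale.

## Concentration–response fitting

The variable-slope four-parameter logistic
`Y = Bottom + (Top − Bottom)/(1 + 10^((LogEC50 − X)·HillSlope))` is fitted
by bounded least squares (SciPy trust-region reflective). Defaults:

* parameter box Bottom ∈ [−0.05, 0.2], Top ∈ [0.5, 1.1], Hill ∈ (0, 5],
  LogEC50 within the data grid ± 2 decades. On the normalised scale these
  are physiological rather than restrictive: the plateau anchors 0 and
  papaverine anchors 1, and E_max slightly above 1 (seen in PCLS
  preparations) remains representable. An unconstrained mode is available
  (`constrained=False`).
* deterministic starting rule — Bottom/Top from the data extremes, LogEC50
  at the grid point nearest half-range, Hill = 1 — so fits are exactly
  reproducible.
* replicate handling: fit per subject, then summarise pEC50 and E_max as
  mean ± SEM over subjects (n = subjects), the standard reporting unit for
  organ-bath studies; a pooled fit is possible by concatenating subjects.
* guard rails: at least five distinct concentrations; response range below
  2 % of E_max raises a no-fit error (flat data); optimiser failure raises
  a convergence error with diagnostics.

Fitted responses above 1 are retained for fitting; clipping to [0, 1]
happens only where effects enter the Bliss model, and is recorded in the
assessment output.

## Bliss Independence and replicate statistics

The expected effect of independent agents is `1 − Π(1 − E_i)` (the expanded
inclusion–exclusion forms are exposed for 2 and 3 agents and agree with the
complement product to machine precision). Inputs are validated against the
admissible window [−0.05, 1.10] and clipped to [0, 1]; outputs are clamped
to [0, 1] so floating-point round-off cannot produce an expectation above 1.

Uncertainty of the expectation is propagated two ways:

* **by-subject pairing** (default): the BI expectation is computed within
  each matched subject, then summarised as mean ± SEM. This respects the
  paired design of organ-bath studies, where the same rings provide the
  single-agent and combination measurements.
* **delta method**: first-order variance propagation through the BI formula
  from the per-drug means ± SEMs, for data where subjects cannot be
  matched. On independently drawn replicates the two SEMs agree in RMS
  within a few percent; on strongly correlated subjects only the by-subject
  scheme is correct, which is why it is the default.

The interaction call at each condition is a two-sided t-test of observed
vs expected replicates: paired when per-subject expectations exist (exact
under normality, important at n = 3), Welch otherwise. Classification:
synergistic if Δ > 0 and p < α, antagonistic if Δ < 0 and p < α, additive
otherwise; |Δ| below numerical noise (10⁻¹⁰ percentage points) is additive
regardless of the test, so that degenerate zero-variance comparisons cannot
produce spurious calls. Note that a calibrated two-sided test at level α
flags *departure from additivity* at rate α under the null; each direction
(synergy, antagonism) is flagged at α/2. No multiple-testing correction is
applied across conditions by default, matching common practice in this
literature; Holm-style correction can be applied downstream on the reported
p-values.

For the EFS synergism curve the per-time test defaults to Welch: at n = 3
the paired test has only 2 degrees of freedom and noticeably lower power,
and a per-time Monte-Carlo oracle showed the Welch variant recovers a 9-h
synergy window within one grid step in ≈97 % of runs versus ≈70 % for the
paired test, while remaining (slightly conservatively) calibrated under the
null. A treatment × time two-way ANOVA over the whole curve is also
reported, matching how sustained synergism is usually tested.

## Time-course metrics

* **Normalisation**: relaxation % = 100·(1 − amplitude/pre-treatment
  reference); invariant to common rescaling of amplitude and reference.
* **Trend**: least-squares polynomial, degree selected by small-sample
  corrected AIC and capped at 4 to avoid Runge artifacts on ~145-point
  traces; exactly-polynomial data short-circuit to their true degree. A
  pre-build oracle confirmed that on a saturating trace (onset half-time
  ≈ 18 min, 12-h plateau) the quartic trend recovers t½ within one 5-min
  grid step.
* **t½ (onset)**: earliest time the trend reaches half its maximum, found
  by dense bracketing plus Brent root refinement; flagged undefined when
  the trend never crosses half-maximum from below.
* **Plateau**: mean of the trend over the final 3 h (window configurable),
  excluding a terminal declining segment (trend below 90 % of the window
  maximum at the end of the record).
* **AUC**: trapezoidal integral of the synergism (observed − expected)
  curve in %·h; interval additivity holds to ≤1e−9 by construction. The
  AUC is computed on the delta curve, not the raw relaxation curve — the
  head-to-head comparisons are comparisons *of the synergism*, and the
  magnitudes (AUC₀₋₁ ≈ 20 %·h at Δ ≈ 20 %) are only consistent with that
  reading. The raw-curve AUC remains available by passing the relaxation
  trace instead.
* **Duration of synergism**: end time (hours post-treatment) of the longest
  run of time points with Δ > 0 and p < α, merging runs across single
  isolated non-significant points (5-min sampling at n = 3 makes one-point
  dropouts likely; the tolerance is switchable). The end-time convention —
  rather than run length — matches the reporting convention "synergistic
  for N h after treatment": with a smooth onset the first minutes are never
  individually significant, yet the synergism clearly lasts until its end
  point.

Head-to-head comparison of two combinations produces per-metric differences
(a − b) with Welch tests from the summary statistics; when per-subject AUC
replicates are supplied, a combination × interval two-way ANOVA p-value is
attached.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, with
a known truth, and writes the same tidy CSV schema the readers consume (raw
tensions plus papaverine / pre-treatment references), so the normalisation
code paths are exercised too.

* Per-drug truths are 4PL parameter sets; the built-in defaults use the
  reported potencies (pEC50 8.44 glycopyrronium, 7.39 indacaterol; E_max
  0.9968 and 0.9228) with Hill 1. The forskolin truth for triple designs is
  back-derived from its isoeffective EC30 (56.2 nM) assuming Hill 1.
* Noise is additive Gaussian on the normalised-effect scale
  (default sd 0.05 per measurement, i.e. subject-level SEM ≈ 2.9 % at
  n = 3, within the 2–15 % SEM range typical of such experiments),
  truncated to [−0.05, 1.10]. An optional per-subject shared offset models
  between-subject correlation (default off; the within-subject correlation
  structure of real preparations is not published, so it is a parameter,
  not an assumption).
* Combination CRCs are built on the Bliss surface at isoeffective
  concentrations; an injected `synergy_delta` shifts the surface additively
  (then clips to [0, 1]), matching how Δ is reported. Levels outside any
  drug's attainable range are flagged, not dropped.
* EFS traces rise with a saturating-exponential onset (half-time default
  18.3 min, the reported onset of the combination) to the per-drug effect
  level; the combination follows the BI expectation of the single traces
  plus the synergy term inside the configured window (default 0–540 min).
  Outside the window the synergy decays with a 2-min half-time — a
  sub-grid transition that keeps the ground-truth window edge crisp, since
  no washout functional form is published. A zero-mean time-control trace
  is included by default.
* Everything is determined by the config seed; identical configs produce
  byte-identical tables.

**What passing tests do and do not show.** The generator is phenomenological:
no receptor kinetics, no cAMP dynamics, no drift, homoscedastic Gaussian
noise, and (by default) no between-subject heterogeneity. Estimator
recovery on this synthetic suite demonstrates correctness of the
computations and calibration of the tests under the stated noise model,
not robustness to the heavier-tailed, drifting, correlated noise of real
organ baths. Two deliberate consequences of the truncation: ensemble means
converge to the generating curve only away from the truncation boundaries
(the clip at −0.05 biases near-zero responses upward by ≈0.4 % of E_max at
noise 0.05), and injected deltas near the response ceiling are attenuated
by the [0, 1] clip.

## Problem sizes in validation

The validation suite uses 200 simulated experiments per drug for pEC50
recovery, 1000 simulated additive experiments for null calibration of the
interaction call (binomial 95 % CI at these rates: ±1.35 % around α,
±0.97 % around α/2), and 40 simulated 12-h EFS studies for synergy
recovery; these sizes give Monte-Carlo standard errors an order of
magnitude below the tolerances being checked while keeping the whole suite
fast on a single CPU.
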