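# Methods

This note documents the generative model, the estimators, the numerical
choices and the limits of what the synthetic validation shows.

## Task generator

Each run crosses money (1-5), shocks (1-5) and action context
(active/passive) once with long anticipation-to-movement intervals (AMI,
uniform on [6, 7] s) — 50 long trials per run — plus 12 short-AMI fillers
(uniform on [0.5, 5.5] s) whose conditions are drawn without replacement
from the factorial cells, preserving marginal balance; the draw order is
shuffled within run. Three runs give 186 trials, of which the 150 long
trials form the analysis set (short trials exist to keep the agent engaged,
and because the cardiac response is too slow to score on them). Onsets
accumulate ITI (uniform [9, 11] s) + AMI + movement window (0.7 s) +
outcome screen (1.5 s). Outcomes are categorical per choice:
money/shocks/nothing with probabilities .40/.40/.20 after approach and
.10/.10/.80 after avoid. The shock-intensity staircase starts at level 2 of
10 and moves +1 / 0 / -1 for ratings <= 3 / = 4 / = 5, clipped to [1, 10];
the step size is a package choice (the calibration procedure it emulates
fixes only the direction rules).

## Cardiac generator and Dhr

Each subject has a baseline heart rate b_i ~ Normal(65, 7) BPM and a
bradycardia offset; each long trial has a latent deceleration
delta_it ~ Normal(-1.77 + offset_i, 2.0) BPM with offset SD 1.0. The
instantaneous rate is b_i before onset, ramps linearly to b_i + delta_it by
5 s and stays flat through 7 s, so the scoring window sits on the plateau.
Beat times are generated by stepping one inter-beat interval (IBI) at a
time, evaluating the rate at the interval midpoint (one fixed-point
refinement) so the stamped BPM series tracks the ramp with minimal lag;
optional per-beat BPM noise (default SD 0.5) is added before stepping, and
the first beat carries a uniform phase jitter. The deceleration is drawn
independently of money, shocks and context — the generator's null that the
condition model (below) must confirm.

Scoring follows the empirical definition: BPM = 60/IBI stamped at the
interval's second beat, linearly interpolated to a 10 Hz grid;
Dhr = mean BPM over [onset+5, onset+7] minus mean BPM over [onset-1, onset].
With noise off, the full simulate -> convert -> score path reproduces the
latent delta to < 0.06 BPM (ramp/window discretization); the tested bound is
0.1 BPM. Quality flags (never exceptions) mark trials whose windows are
uncovered, contain an IBI outside [0.33, 2.0] s, or have stamp gaps above
2.0 s — the gap bound equals the largest plausible IBI, since a slow but
regular heart is not an artifact. Exclusions drop short-AMI trials, flagged
trials, and active-response trials faster than 200 ms, in that order, with a
count-per-rule report.

## Choice, RT and heart-rate models

Continuous predictors are z-scored pooled across all retained trials of all
subjects; `Dms = money - shocks` is differenced on raw levels first and then
standardized (so its z-scale is half the money scale); action context is
coded -1 (active) / +1 (passive); choice, where it appears as a predictor,
+1 (approach) / -1 (avoid). The standardization statistics are computed once
on the analysis set and frozen for regressor building. The
difference-then-standardize order for Dms is one of two defensible readings
of "standardized predictors"; it is the package's committed convention, and
the regressor-correlation diagnostics below are sensitive to it at the third
decimal.

The choice family (base / AV / VC / AI, plus a saturated `full` variant with
all Dhr interactions) is fitted by pooled maximum likelihood: L-BFGS on the
Bernoulli log-likelihood with analytic gradient, probabilities clamped at
1e-12, tight tolerances (ftol 1e-14) so estimates agree with an independent
GLM fit to ~1e-5. Complete or quasi-separation (|coefficient| > 12) is
flagged and clamped, never silent. Uncertainty comes from a nonparametric
bootstrap over subjects (default 500 resamples, warm-started); HDIs are
narrowest-window intervals over the bootstrap draws, and significance labels
follow the two-interval rule (95% HDI excludes 0: significant; only 90%:
marginal). An optional hierarchical fit adds per-subject random intercepts
through a variational mixed logistic approximation; on data without subject
heterogeneity its point estimates match pooled ML within bootstrap
uncertainty, which is the regime the recovery experiments use. Model
comparison uses AIC on identical data (fits carry a data fingerprint and
refuse cross-data comparison); ties break toward fewer parameters.

Response times are shifted-lognormal, `rt = shift + exp(Normal(X beta,
sigma))`, defined only on button-press trials (approach in the active
context, avoid in the passive one — about half the trials). With a known
shift the ML solution is OLS on `log(rt - shift)`; an unknown shift is
profiled on a 50-point grid over [0, min rt), rejecting any candidate at or
above the smallest RT. Generator defaults put the median RT near 0.45 s
(shift 0.2 s, location intercept log 0.25, sigma 0.25) with slopes of
-0.04 (choice), +0.04 (money x choice), -0.04 (shocks x choice) and +0.03
(Dhr) on the log-seconds scale: avoid responses are faster, reward speeds
approach, threat slows it, and weaker bradycardia (higher Dhr) slows
responding. The trial-wise heart-rate condition model is Gaussian OLS of raw
Dhr (BPM) on the money x shocks x context factorial; its intercept is the
grand anticipatory deceleration and its slopes test the generator's
condition-independence null.

## Model-based regressors and design matrices

Trial-wise DVs are computed from fixed group-level parameter sets — the
package ships canonical rows for all four models (base intercept 0.73, money
1.54, shocks -1.10, ..., AV shocks:Dhr 0.07, VC Dms:Dhr -0.09, AI ac:Dhr
0.05) — at the group rather than subject level, because the regressors are
meant to carry the shared computational signal, not individual differences.
Since each freezing model deviates from the base model by one term, full-DV
regressors rank-correlate with the base DV at ~0.998 per subject; the GLM
therefore uses difference scores `DVdiff = DV_base - DV_variant` (positive =
variant predicts relatively more avoidance), which drops the mean
per-subject |Spearman rho| to ~0.04 (AV), ~0.09-0.11 (VC) and ~0.02 (AI).
VC retains the largest residual correlation because its canonical row also
differs slightly from the base row in the shared terms; with the committed
Dms convention the residual sits near the 0.1 boundary, and with the
alternative (z-difference) convention it would drop to ~0.08 while the
pre-differencing correlation fell below 0.998 — the committed convention
favors the collinearity diagnostic. Sign-split follow-up regressors assign
strictly positive and strictly negative DVdiff trials to disjoint columns
(exact zeros join neither; an empty side is dropped with a warning).

Design matrices are built at 0.1 s microtime resolution: event boxcars,
parametric modulators demeaned across their events before convolution (this
is the orthogonalization against the unmodulated regressor; modulators are
deliberately not orthogonalized against each other, so shared variance goes
to the error term), convolution with a canonical double-gamma HRF (peak
delay 6, undershoot delay 16, dispersions 1, undershoot ratio 1/6, unit
peak; the implemented kernel peaks at 5.0 s on a 0.1 s grid), downsampling
to the TR = 1.5 s grid, and a discrete-cosine drift set up to the 1/128 Hz
high-pass cutoff plus a constant. Synthetic BOLD validation uses OLS with a
rank check that names collinear columns; AR(1) prewhitening is deliberately
out of scope at toy scale.

## Parameter recovery and problem sizes

The recovery harness simulates analysis-ready tables directly: balanced
long-trial factorials, exogenous standardized Dhr ~ N(0, 1), no random
effects — the conditions under which pooled ML is consistent for the
generating values. Headline recovery experiments use 300 subjects x 150
trials (45,000 trials) for the choice and RT coefficients and 58 x 150 for
the heart-rate and regressor diagnostics (the empirical cohort size); the
test suite uses smaller replicates (tens of subjects) chosen to keep the
full suite under ten seconds while leaving comfortable statistical margins.
At 45,000 trials the money/shock coefficients recover within ~0.02 and the
bradycardia interactions within ~0.01-0.02 of their generating values;
interval calibration is checked coarsely (bootstrap 90% HDIs cover a null
generating value most of the time at small n).

When subject heterogeneity is wanted (the full dataset simulator's default),
per-subject coefficient deviations are drawn with SD = 0.5 x |group
coefficient| — a package choice, exposed in `AgentParams`, since no
empirical value is available — and the hierarchical fitter, not pooled ML,
is then the appropriate estimator.

## What the synthetic validation does not show

The generator emulates the statistical structure the analysis assumes —
factorial balance, condition-independent bradycardia, logistic choice,
shifted-lognormal RTs, clean beat series. It does not emulate raw
photoplethysmography, MR artifacts, respiratory coupling, missing runs,
unbalanced cells after real exclusions, or any systematic relation between
cardiac state and conditions. Passing recovery therefore certifies the
estimators and the pipeline plumbing, not the empirical claims; effect
estimates on real data additionally face measurement noise in Dhr and
between-subject variance that the recovery conditions deliberately switch
off. The hierarchical fitter is a variational approximation with random
intercepts only; maximal random-effect structures and exact posterior
sampling are out of scope.
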