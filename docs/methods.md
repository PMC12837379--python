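# Methods

## Scope and data model

combodex analyses a two-agent viability screen in which each agent is
titrated alone and the pair is titrated together at one fixed mixing
ratio (here 10:1 by concentration), plus the downstream marker panels of
such a study. The in-memory unit is the well record (agents, doses in
µM, replicate, response); wells aggregate into dose–response series
(mean ± SD per total dose). Raw plate signals are normalized to percent
of the mean of all dose-0 control wells; percent-viability input passes
through untouched. Viabilities above 100 % are retained but flagged, so
downstream consumers can decide on exclusion.

The packaged study tables store the source's printed values verbatim,
including a control viability of 98 % even though viability is defined
relative to control. We deliberately do not re-normalize: the fixture's
job is side-by-side comparison, and every derived inhibition fraction
uses fa = 1 − V/100 (so the printed "58 % reduction at Q100" is
reproduced from V = 42 exactly). Three of the five combination
viabilities were never printed; the fixture fills them with
reconstructions labelled synthetic, chosen to respect the source's
qualitative statements (all pairs supra-additive at low dose, Bliss
excess +15 points at the middle pair) — they are used only where a full
five-point combination series is structurally required and never as
evidence.

## Dose–response fitting

The 4PL V(D) = bottom + (top − bottom)/(1 + (D/EC50)^h) is fitted by
bounded least squares on replicate means (the granularity at which such
studies report data; per-replicate fitting is a config flag, default
off). Initialization: top = max mean, bottom = min mean, EC50 = the dose
whose mean is nearest the half-range; multi-start over h ∈
{0.5, 1, 2, 4} with bounds bottom ∈ [0, min mean], top ∈ [0.9·max,
1.1·max + 5], h ∈ (0.1, 10], EC50 ∈ [min positive dose/10, 10·max dose].
Dose 0 enters the fit as-is (the 4PL is defined there with value top)
and anchors the upper asymptote. Non-convergence is flagged, not raised.
The absolute IC50 solves V(D) = 50 in closed form and is undefined
(with a warning) when the fitted curve never crosses 50.

At least four distinct doses are required; on noise-free 4PL data the
fit recovers the generating parameters to ~1e−6 relative (verified in
the suite).

## Median-effect and Combination Index

Linearization retains points with dose > 0 and 0.01 ≤ fa ≤ 0.99 —
log-odds diverge at the extremes, and clamped fa = 0 stimulation points
carry no dose–effect information — and reports exclusions with reasons.
Unweighted OLS gives m (slope) and Dm = 10^(−intercept/m); r is the
linear correlation of the retained points. fa is computed from mean
viability per dose. A non-positive slope is returned but marked
unreliable.

The fixed-ratio combination is fitted as a single agent at total dose,
components recovered by the ratio weights — the standard fixed-ratio
construction. CI uses α = 0 by default (mutually exclusive; the
classical choice when the source defines both but states neither);
the Fa–CI grid is 0.25–0.90 in steps of 0.05 (14 points) — the range is
the convention, the step our choice. Classification uses strict
thresholds around 1 with a configurable additive band (default ±0.05)
to absorb float and replicate noise; ΔBliss uses a ±0.01 band because an
exact-equality additive class is empirically empty.

A structural point that shapes the tests: a Loewe-additive fixed-ratio
mixture of two median-effect agents is itself exactly a median-effect
curve only when the two slopes coincide (then 1/Dm_mix = w₁/Dm₁ +
w₂/Dm₂ at the shared m). The noise-free CI-closure checks therefore use
equal-slope ground truth, which is also precisely the mutually-exclusive
regime the α = 0 CI equation assumes; with unequal slopes the combo fit
is an approximation and CI deviates from 1 by a few percent even without
noise, which the analysis drivers show rather than hide.

## Reference models

Bliss and HSA work on inhibition fractions throughout. Single-agent
effects for the per-pair table are taken at exactly the component doses
of the design (the fixed-ratio layout measures singles at those doses);
linear interpolation on fa is available behind a flag, default off, and
out-of-range component doses yield per-pair errors rather than a failed
table. The CI and ΔBliss sign conventions disagree by construction
(synergy is CI < 1 but ΔBliss > 0); both labels are reported per model
and never merged.

## Markers and qPCR

Fold change is the ratio of group means; percent change is
(fold − 1)·100, and the two are kept exactly scale-consistent. Total
apoptosis is Q2 + Q4 with the Methods-text quadrant convention
(Q3 viable, Q4 early apoptotic); published figure captions sometimes
swap Q3/Q4, and this package fixes the convention at Q4 = early.
ΔCt is the mean of per-replicate (Ct_target − Ct_reference) — pairing
within a well before averaging, the standard ΔΔCt practice — then
ΔΔCt = ΔCt_treated − ΔCt_control and RQ = 2^−ΔΔCt. Inferential group
statistics (ANOVA and post hoc tests) are out of scope; summaries report
mean, SD, n.

## Synthetic-data generator

The generator emulates the study's conditions: six-level single-agent
grids (0 + five positive doses matching the 10–100 µM / 1–10 µM
design), a 10:1 fixed ratio, biological triplicates, and multiplicative
replicate noise — viability × exp(N(0, σ)) with σ = ln(1 + CV),
truncated at 0, keeping viability positive and the CV interpretable.
The default CV is 5 %, a realistic replicate scatter for MTT triplicates
(the source prints no CV). Default ground-truth potencies (Dm 85 and
6.5 µM, m 1.3 and 1.0) mirror the median-effect fits of the packaged
single-agent series.

Combination ground truth has three modes: `loewe` solves
d₁/Dx₁(fa) + d₂/Dx₂(fa) = 1 by Brent root finding, parameterized in
log10-odds t = log10(fa/(1−fa)) over [−30, 30] (tolerance 1e−12, ≤ 200
iterations) — the residual is strictly monotone for positive slopes so
the root is unique, and the log-odds scale stays well-conditioned even
when the root lies within 1e−9 of fa = 0 or 1, where an fa-space solve
loses precision; `bliss` composes
the single-agent effects independently; `potency_shift` evaluates the
Loewe effect at doses scaled by a strength s, making the true CI equal
1/s at every effect level — the calibrated synergy ground truth used in
closure tests. Randomness comes from numpy's PCG64 `default_rng`
seeded per output stream from the config seed, so identical configs give
identical records across runs and platforms.

What the generator does **not** emulate: plate spatial effects (edge
rows, drift), pharmacokinetics or growth kinetics, non-fixed-ratio
(checkerboard) designs, and raw flow-cytometry or fluorescence event
data. Passing tests therefore demonstrate correctness of the estimators
under the stated noise model, not robustness to spatially structured
artefacts.

## Numerical choices and degenerate inputs

SSE-based multi-start selection with 1e−10 tie tolerance for the 4PL;
closed-form inversions (IC50, Dx) rather than iterative ones wherever
the model allows; combination grouping keyed by the unordered agent
pair with the mixing ratio rounded to 6 significant digits (float-safe),
and a grouping error when one pair appears at inconsistent ratios.
fa ∈ {0, 1}, non-positive doses, zero-variance correlation inputs,
empty groups and mismatched qPCR targets are all rejected with domain
errors; fits that are possible but untrustworthy (non-positive slope,
non-convergence, undefined IC50) are returned flagged and surfaced as
report warnings.

## Problem sizes

The suite and the acceptance script run desk-scale problems: 6-point
curves, 48-well screens, 100 random sham models × 19 effect levels, and
50 stochastic repetitions — sizes chosen to match the study design and
keep the full validation loop in seconds.

## Known limitations

The printed study values are partly irreconcilable: the GEM series
contradicts its printed IC50, the high-dose combination observations
imply negative ΔBliss despite a synergy narrative, and the Fa–CI
headline values (1.32 at Fa 0.7, 0.78 at Fa 0.9) cannot be reproduced
because the underlying combination series was not printed. The
reproduction pipeline reports computed and printed values side by side
and never forces agreement. Confidence intervals on 4PL and
median-effect parameters, CI confidence bands, checkerboard surface
scores (ZIP/Loewe surfaces) and efficiency-corrected qPCR (Pfaffl) are
out of scope.
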