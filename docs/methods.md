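# Methods

## Model

Lesion volume `V(t)` (cm³, time in months) follows the Von Bertalanffy
power law `dV/dt = α V^β` with `V(t0) = V0`. For `β ≠ 1` the closed form is
`V(t) = [V0^(1−β) + α(1−β)(t−t0)]^(1/(1−β))`; for `β = 1` it is
exponential. For `β > 1` the solution diverges at the finite blow-up time
`t* = t0 + V0^(1−β)/(α(β−1))`; evaluation at or beyond `t*` raises an error
naming it. Only growing lesions are modelled (`α > 0`); a shrinking series
needs no RN/PD discrimination and the exponent is undefined for it, so such
series are flagged ineligible rather than fitted.

Assumptions worth keeping in mind: the law is a phenomenological summary of
net growth with negligible cell loss; it carries no treatment-effect or
regression term, so it only describes the *growing* segment of a lesion's
history, and `β` is an empirical shape parameter, not a mechanistic rate.

## Exact three-point identification

Three increasing volumes determine the three parameters exactly. `V0` is
pinned to the first measurement; eliminating `α` leaves a 1-D root problem
`g(β) = r` with `r = (t2−t1)/(t1−t0)` (see README for `g`). `g` is positive
and strictly decreasing from `+∞` to `0`, so the root exists and is unique;
it is found by bracketed Brent iteration with default bracket `(−5, 10)`,
doubled outward to at most `(−50, 100)`, tolerance `1e−10` on `β`.

Numerical choices:

* The solve runs on `log g(β) − log r` (same root): differences of powers
  are expressed through `expm1`/`log1p`, which avoids catastrophic
  cancellation near `β = 1` and overflow at the extremes of the expanded
  bracket.
* `|β − 1| < 1e−7` is reported as exactly 1 with the exponential branch
  (`g` and `α` use their analytic log-ratio limits there); the closed form
  is 0/0 at `β = 1`. Near that switch, `d ln V/dβ = s²/2 + s·ln V0` with
  `s = αΔt`, so branch continuity at the `1e−6` level holds for the
  moderate per-interval growth (`s ≲ 1`) of 3-monthly follow-up.
* A fit is reported `converged` only if the resulting trajectory reproduces
  all three volumes to ≤ 1e−6 relative error and any blow-up lies beyond
  the third scan; otherwise the result carries a diagnostic message.
* Series longer than three points: the identification uses the first three
  (it is an exact 3-point construction); later points are retained for
  inspection only.

Two-point rates use the natural logarithm,
`λ = log(V_b/V_a)/(t_b−t_a)`; any fixed base would rescale both groups
identically, leaving ranks, p-values and AUC unchanged.

## Robustness screen

Each of the three volumes is multiplied by an independent `1 + u`,
`u ~ Uniform(−b, +b)` with `b = 0.05` by default — the maximum-entropy
distribution on a bounded interval, with the stated bound respected
exactly. The exponent is refitted for 200 perturbed triplets; triplets that
lose monotonicity are discarded and redrawn (the fit is undefined for
them), up to `100 × n_reps` total draws, after which a partial result is
returned. A lesion is robust when `|summary(β*) − β| < 0.5` strictly, where
the summary is the mean (and, reported alongside, the median). Identical
seed and settings reproduce the result bit for bit.

## Cohort statistics

`β` is the score, RN the positive class (higher score ⇒ RN). The empirical
ROC is built over all distinct-score thresholds and integrated
trapezoidally; with ties counting one half this equals the normalised
Mann–Whitney U, which the test suite checks by exhaustive pair counting.
Group comparison uses the tie-corrected Kruskal–Wallis H with the
chi-squared p-value; for two groups this coincides with the two-sided
asymptotic Mann–Whitney test. The chi-squared approximation is asymptotic —
at very small group sizes (a few per group) it can be far from the exact
permutation p-value, which matters for tiny strata but not at the 60+41
scale the pipeline targets (type-I error calibration at that size is part
of the test suite). The operating point maximises Youden's
`J = sensitivity + specificity − 1`, ties broken toward higher sensitivity,
then lower threshold. Strata: whole cohort, upfront-WBRT lesions,
single-session SRS and fractionated SRT; when several strata run in one
invocation the p-values get a Bonferroni adjustment across them, with raw p
always reported. Tests are two-sided at α = 0.05.

A one-sample Kolmogorov–Smirnov check against a normal with the *sample's*
mean and SD is reported to justify the nonparametric path. Because the
reference is fitted to the same sample, this p-value is conservative
(biased high) for genuinely normal data — it never gates any computation.

## Synthetic cohorts: what they emulate, and what not

The generator reproduces the observable structure of the clinical cohort
the method was developed on (which is not publicly deposited): 60 PD + 41
RN lesions; exponents drawn per group from normals centred on 0.52 (PD) and
2.10 (RN); scan times `(0, Δ1, Δ1+Δ2)` with `Δ1, Δ2` jittered around 3.04
and 2.42 months (normal jitter, SD 0.5, truncated by redraw at half the
mean); baseline volume lognormal with median 0.5 cm³ and log-SD 0.85
(central range ≈ 0.05–6 cm³ — brain metastases are small); multiplicative
Uniform(±5%) measurement noise, with non-increasing noisy triplets redrawn
(cap 1000 attempts). `α` is derived from a log-uniformly drawn total growth
ratio `V2/V0 ∈ [1.2, 10]` by inverting the closed form, which guarantees a
realistic, non-exploding three-point series for every exponent — sampling
`α` directly would silently reject most `β > 1` draws through blow-up.
Ground truth (parameters and noiseless rates) is stored beside, never
inside, the observable table. One global seed governs everything through
per-lesion substreams derived from `(seed, lesion index)`, so cohorts are
reproducible and stable under size changes.

Free calibration choices (the printed cohort summaries constrain none of
them): exponent spreads 0.9 (PD) and 1.3 (RN), the `V0` distribution, and
the growth-ratio range. With these defaults the full pipeline lands in a
plausible neighbourhood of the reported discrimination (AUC ≈ 0.75–0.85
across seeds) and reproduces the qualitative findings: strongly significant
group separation, and two-point rate orderings that flip between scan pairs
(PD faster over the first pair, RN over the second).

What the generator does **not** emulate: within-patient correlation of
lesions, scanner- or site-specific noise, segmentation bias (noise here is
unbiased and exactly bounded, so synthetic robust fractions run higher than
clinically reported), non-normal exponent dispersion, and any association
between subgroup membership and dynamics (subgroup tags are independent
draws, so subgroup analyses exercise the plumbing, not subgroup biology).
Passing tests therefore validate the machinery and its statistical
calibration, not clinical performance.

## Pipeline and I/O

Cohorts are CSV (one row per scan); times are re-based to months since each
lesion's first scan on read (the model is translation-invariant and
absolute dates are identifying), and volumes are cm³ internally with an
explicit `mm3` conversion flag to avoid silent thousand-fold errors.
Malformed rows (duplicate times, non-positive volumes) produce per-row
diagnostics with configurable fail-fast. Lesions failing the
three-increasing-point criterion are loaded but flagged ineligible.
`run_pipeline` writes the per-lesion table, per-stratum JSON results, ROC
point files and a manifest (config, seed, version, errors); reruns with the
same seed and config are byte-identical.

## Problem sizes and limitations

Default analysis scales are those of the emulated study (101 lesions, 200
robustness replicates); test-suite sweeps use 100–2,000 draws per property,
which the exact 1-D fit (tens of microseconds) makes cheap. Known
limitations: the exponent needs three increasing volumes, so the method is
silent on stable or shrinking lesions; a 3-point exact fit propagates
measurement error directly into `β` (hence the robustness screen); extreme
noisy triplets can push the root outside the hard bracket, which is
reported as a failed fit rather than extrapolated; and no uncertainty
interval on `β` beyond the perturbation screen is provided.
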