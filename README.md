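# bmgrowth

Growth-dynamics discrimination of **radiation necrosis (RN)** from
**progressive disease (PD)** in brain metastases followed with volumetric
MRI after stereotactic radiotherapy (SRS/FSRT).

Both conditions enlarge on contrast-enhanced T1-weighted imaging and look
alike on any single scan, but their *dynamics* differ: the inflammatory
growth of RN is fast yet transient, while tumor regrowth is steadier. With
three consecutive volume measurements `(V0, V1, V2)` at times
`(t0, t1, t2)`, the Von Bertalanffy power law

```
dV/dt = α V^β,   V(t0) = V0
```

is identified **exactly** (three data, three parameters): `V0` is the first
measurement and `β` solves the interpolation condition

```
g(β) = [V2^(1−β) − V1^(1−β)] / [V1^(1−β) − V0^(1−β)] = (t2−t1)/(t1−t0),
```

with `α` back-substituted. The dimensionless growth exponent `β` is the
classification score: `β > 1` means super-exponential (accelerating,
finite-time blow-up) dynamics typical of RN; PD tends to `β < 1`. The
two-point rates `λ = log(V_b/V_a)/(t_b−t_a)` are computed for both scan
pairs; their group ordering flips between pairs, which is why the rate alone
cannot discriminate and the exponent can.

The package is aimed at quantitative imaging / mathematical-oncology work:
a library API (fit, robustness screen, cohort statistics, synthetic cohort
generator), narrative `examples/`, and a thin `bmgrowth` CLI for
file-based runs.

## Worked example

```python
import bmgrowth as bg

series = bg.LesionSeries(
    lesion_id="BM-07", patient_id="patient-03",
    times=(0.0, 3.0, 5.4),        # months since first scan
    volumes=(0.41, 0.69, 1.52),   # cm^3
)
fit = bg.fit_vb_exponent(series)
rates = bg.growth_rates(series)
print(fit.params.beta, fit.params.alpha, rates.lambda1, rates.lambda2)
```

prints (see `examples/02_fit_exponent.py`):

```
status          : converged (7 iterations)
growth exponent : beta  = 1.9992
rate coefficient: alpha = 0.3297
lambda1 (scans 1-2): 0.1735 /month
lambda2 (scans 2-3): 0.3291 /month
```

`β ≈ 2.0` with `λ2 > λ1`: the lesion's growth is accelerating — the dynamic
signature of radiation necrosis. A perturb-and-refit screen
(`bg.assess_robustness`, ±5% volume noise, 200 refits) confirms the
exponent is stable (`robust_by_mean = True`), and at cohort level
`bg.run_discrimination` compares the PD and RN exponent distributions
(Kruskal–Wallis) and builds the ROC with its Youden-optimal operating
point, overall and within the treatment subgroups (upfront WBRT,
single-session SRS, fractionated SRT). The clinical dataset behind the
method is not publicly deposited, so `bg.generate_cohort` produces
synthetic cohorts calibrated to its printed summaries (group sizes 60/41,
exponent means 0.52/2.10, scan intervals ~3.04/2.42 months, ±5% noise) for
testing and demonstration; ground truth is recorded separately from the
observable table.

Command-line equivalent of the full chain:

```
bmgrowth run --seed 0 --outdir results/run0
```

which writes `lesions.csv` (per-lesion β, α, λ1, λ2, robustness verdicts),
per-stratum `discrimination_*.json`, ROC point files and a run manifest.

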