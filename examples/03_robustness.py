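"""Is a fitted exponent stable under +-5% volume-measurement error?

Perturbs each of the three volumes by independent multiplicative
Uniform(-5%, +5%) noise, refits 200 times, and compares the mean and median
perturbed exponent against the original with the |difference| < 0.5 rule.
"""

import bmgrowth as bg

series = bg.LesionSeries(
    lesion_id="BM-07",
    patient_id="patient-03",
    times=(0.0, 3.0, 5.4),
    volumes=(0.41, 0.69, 1.52),
)
result = bg.assess_robustness(series, n_reps=200, noise_bound=0.05, seed=7)

print(f"original beta        : {result.beta_original:.4f}")
print(f"perturbed mean beta  : {result.beta_perturbed_mean:.4f}")
print(f"perturbed median beta: {result.beta_perturbed_median:.4f}")
print(f"robust by mean       : {result.robust_by_mean}")
print(f"robust by median     : {result.robust_by_median}")
print(f"successful refits    : {result.n_successful}/{result.n_requested}")

# A robust verdict means segmentation errors of up to 5% per volume shift
# the average refitted exponent by less than 0.5 — the exponent, not noise,
# is driving the classification for this lesion.
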