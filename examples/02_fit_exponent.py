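"""Identify the growth exponent of one lesion from three dated volumes.

Three strictly increasing volumes determine (V0, alpha, beta) exactly; the
two-point growth rates lambda1/lambda2 come from the same data and their
ordering mirrors the exponent's position relative to 1.
"""

import bmgrowth as bg

series = bg.LesionSeries(
    lesion_id="BM-07",
    patient_id="patient-03",
    times=(0.0, 3.0, 5.4),        # months since first scan
    volumes=(0.41, 0.69, 1.52),   # contrast-enhancing volume, cm^3
)
fit = bg.fit_vb_exponent(series)
rates = bg.growth_rates(series)

print(f"status          : {fit.status} ({fit.iterations} iterations)")
print(f"growth exponent : beta  = {fit.params.beta:.4f}")
print(f"rate coefficient: alpha = {fit.params.alpha:.4f}")
print(f"lambda1 (scans 1-2): {rates.lambda1:.4f} /month")
print(f"lambda2 (scans 2-3): {rates.lambda2:.4f} /month")

# beta > 1 with lambda2 > lambda1: this lesion's growth is accelerating
# (super-exponential), the dynamic signature associated with radiation
# necrosis rather than steady tumor regrowth.
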