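"""End-to-end cohort analysis on a calibrated synthetic cohort.

Generates the default 101-lesion cohort (60 progressive-disease, 41
radiation-necrosis), fits every lesion's exponent, and runs the group
comparison and ROC classification, including the treatment subgroups.
"""

import bmgrowth as bg

cohort = bg.generate_cohort(bg.CohortConfig(), seed=0)
fits = [(l.series, bg.fit_vb_exponent(l.series)) for l in cohort]
fits = [(s, f) for s, f in fits if f.converged]

suite = bg.run_discrimination_suite(fits, strata=("all", "WBRT", "SRS", "FSRT"))
for stratum, res in suite.items():
    if isinstance(res, bg.StratumError):
        print(f"{stratum:>5}: {res}")
        continue
    thr, sens, spec = res.operating_point
    print(
        f"{stratum:>5}: PD n={res.n_pd:3d} mean beta={res.beta_summary_pd['mean']:5.2f} | "
        f"RN n={res.n_rn:3d} mean beta={res.beta_summary_rn['mean']:5.2f} | "
        f"p={res.p_value:.2e} (adj {res.p_adjusted:.2e}) AUC={res.auc:.3f} "
        f"sens={sens:.3f} spec={spec:.3f} @ beta>{thr:.2f}"
    )

lam = suite["all"].lambda_summary
print(
    "\nrate orderings: "
    f"lambda1 PD {lam['PD']['lambda1_mean']:.3f} vs RN {lam['RN']['lambda1_mean']:.3f}; "
    f"lambda2 PD {lam['PD']['lambda2_mean']:.3f} vs RN {lam['RN']['lambda2_mean']:.3f}"
)

# RN lesions carry systematically larger exponents (accelerating, transient
# growth), giving a clearly significant group difference and a usable ROC.
# The two-point rates flip ordering between scan pairs — lambda alone is not
# a reliable discriminator, which is exactly why the exponent is the score.
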