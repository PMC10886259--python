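"""A five-arm virtual trial on a shared cohort (small demo scale).

Simulates Y90 monotherapy, ICI monotherapy and the three combination
sequences (A concurrent, B Y90-first, C ICI-first, 60-day interval) on
the same 500 virtual patients, then prints Kaplan-Meier summaries of
progression-free survival (targeted lesion) and the distant-metastasis
rate (non-targeted lesion crossing 0.1 cc) plus log-rank comparisons.
"""

from y90ici import CohortSpec, five_arm_specs, run_trial

result = run_trial(
    CohortSpec(n=500, seed=7),
    five_arm_specs(dose=400.0, delta=0.12, interval=60.0),
    horizon_months=120.0,
)

summary = result.summary_frame()
cols = ["median_pfs_months", "pfs_1y_pct", "pfs_3y_pct", "dm_1y_pct", "dm_3y_pct"]
print(summary[cols].round(1).to_string())

print("\npairwise log-rank (PFS):")
pfs = result.comparisons.query("endpoint == 'pfs'")
for _, row in pfs.iterrows():
    print(f"  {row.arm_a:>8} vs {row.arm_b:<8} chi2={row.chi2:8.1f}  p={row.p:.3g}")

print(
    "\nNaN medians are 'not reached': more than half of the arm is still\n"
    "progression-free at 10 years.  The combination arms dominate both\n"
    "monotherapies; concurrent dosing (A) is at least as good as the\n"
    "sequential arms, and giving Y90 first (B) beats ICI first (C)."
)
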