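"""How the gap between Y90 and ICI administration affects outcomes.

Sweeps the interval between the two modalities for the sequential arms
(B: Y90 first, C: ICI first) at intermediate intensity, with the
concurrent arm A as the interval-independent reference.  Longer gaps
leave the non-targeted lesion longer under single-modality pressure.
"""

from y90ici import CohortSpec, interval_sweep

grid = interval_sweep(
    CohortSpec(n=300, seed=11),
    intervals=[30.0, 90.0, 180.0, 300.0],
    presets={"mid": (400.0, 0.12)},
    horizon_months=120.0,
)

table = grid.pivot(index="interval_days", columns="arm", values="dm3y_pct").round(1)
print("3-year distant-metastasis rate (%) by administration interval:")
print(table.to_string())
print(
    "\nArm A (concurrent) is unaffected by the interval; for the sequential\n"
    "arms the 3-year DM burden grows with the gap, and the Y90-first\n"
    "sequence tracks the concurrent arm more closely than ICI-first."
)
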