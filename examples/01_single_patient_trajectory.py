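"""Simulate one average patient under concurrent Y90 + ICI therapy.

Builds the population-mean patient (107 cc targeted lesion, 0.107 cc
non-targeted lesion, 5.61e9 circulating lymphocytes), treats with
400 Gy of Y90 radioembolization plus a biweekly ICI course starting the
same day, and prints the four compartments at key times.  The targeted
tumor is ablated by ~5 orders of magnitude within a month; the
non-targeted lesion is held in check by the ICI-boosted immune kill.
"""

from y90ici import ModelParameters, SystemState, build_arm_plan, simulate

p = ModelParameters()
patient = SystemState(TI=1.07e11, TNI=1.07e8, I=0.0, L=5.61e9)
plan = build_arm_plan(
    "A", total_dose=400.0, delta_durva=0.12, interval=0.0, q=p.q, p=p,
    horizon=1825.0,
)

traj = simulate(patient, plan, p)
print(f"{'day':>6} {'targeted':>12} {'non-targeted':>13} {'inactivated':>12} {'lymphocytes':>12}")
for day in (0, 1, 7, 26, 90, 180, 365, 730, 1825):
    s = traj.state_at(day)
    print(f"{day:>6} {s.TI:12.3e} {s.TNI:13.3e} {s.I:12.3e} {s.L:12.3e}")

print(
    "\nThe day-1 radiation fraction kills ~97% of targeted cells (they move\n"
    "to the inactivated pool and recruit lymphocytes); after the 26-day\n"
    "decay course the targeted lesion is far below the 0.1 cc detection\n"
    "limit and stays controlled while the ICI course is active."
)
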