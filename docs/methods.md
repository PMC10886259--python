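# Methods

## Model structure and assumptions

The simulator couples a predator–prey-style tumor–immune system to
event-based radiation kill. Four state variables are tracked in absolute
cell counts: targeted tumor cells `TI` (inside the radioembolized
territory), non-targeted tumor cells `TNI` (outside it, e.g. an occult
metastasis), inactivated tumor cells `I` (radiation-killed cells that
persist, release antigen and recruit lymphocytes before clearing), and
circulating lymphocytes `L`.

Key assumptions, in the package's own terms:

- **Exponential tumor growth** at rate `a` for both lesions; no carrying
  capacity. Immune kill is bilinear in tumor and lymphocytes with a
  geometric saturation `g + TI + TNI` in the denominator, so immune
  pressure per cell weakens as total burden grows.
- **Y90 is purely local, ICIs purely systemic.** Radiation never touches
  `TNI`; the only route by which radioembolization helps the
  non-targeted lesion is indirect — debulking `TI` shrinks the
  saturation denominator and the `I` pool recruits lymphocytes. There is
  deliberately no direct radiation-induced immune-activation term.
- **Radiation as instantaneous events.** The continuously decaying
  source is discretized into daily fractions weighted by the decay curve
  (26 fractions = 10 half-lives, >99.9% of the decay; renormalized so
  the physical doses sum exactly to the prescription). Each fraction
  applies linear–quadratic survival to `TI` (with `beta_T = alpha_T /
  (alpha/beta)`, alpha/beta = 10 Gy) and moves the killed cells to `I`;
  cell conservation at each event is exact by construction.
- **Effectiveness q.** The physical absorbed dose `D` enters the LQ
  exponent as the effective dose `q·D`. q absorbs everything that
  separates a radioembolization prescription from an equally effective
  uniform dose (microsphere heterogeneity, dose–volume effects); it is a
  per-patient constant on [0, 1].
- **Lymphocyte irradiation.** Circulating lymphocytes transiting the
  perfused territory receive `kappa_blood` times each fraction's
  physical dose and survive linearly with `alpha_L = 0.737 /Gy`.
  `kappa_blood` is a free parameter (default 0.05) — only a small part
  of the circulating pool is exposed per day. It is exposed in the
  configuration because no measurement pins it down.
- **ICI pharmacodynamics.** A dose at time `t_k` resets the normalized
  concentration to 1; it decays with the 21-day elimination half-life.
  The immune-kill rate is multiplied by `1 + delta_durva * C_max *
  C(t)/C_max` (so 2.2 at dosing for delta = 0.12, 1.6 one half-life
  later). The reset-at-each-dose reading was chosen over superposing all
  past doses because the concentration scale is defined per
  administration; with biweekly dosing the multiplier then cycles
  between 2.2 and ~1.75 rather than accumulating without bound.
- **No death process, no toxicity.** Progression is the only PFS event;
  patients without events are censored at the horizon. Normal-tissue
  and systemic toxicity are out of scope.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| a | tumor growth rate | 0.01 | 1/d |
| f | lymphocyte decay | 0.033 | 1/d |
| r | inactivated-cell clearance | 0.14 | 1/d |
| omega1 | immune kill efficiency | 0.119 | 1/d |
| omega2 / omega3 | recruitment by live / inactivated tumor | 0.003 / 0.009 | 1/d |
| g | geometric saturation | 7.330e10 | cells |
| s | lymphocyte supply | 1.470e8 | cells/d |
| alpha_T | tumor LQ alpha | N(0.148, 0.024) | 1/Gy |
| alpha/beta | tumor LQ ratio | 10 | Gy |
| alpha_L | lymphocyte radiosensitivity | 0.737 | 1/Gy |
| C_max, T1/2 | ICI concentration scale, half-life | 10 mg/kg, 21 d | |
| delta_durva | ICI effectiveness | N(0.12, 0.04) | — |
| T1/2 (Y90) | radionuclide half-life | 2.6 | d |
| q | Y90 effectiveness | N(0.12, 0.04), calibrated | — |
| kappa_blood | lymphocyte dose fraction | 0.05 | — |

The tumor-free lymphocyte equilibrium is `s/f = 4.45e9` cells, close to
the sampled baseline mean of 5.61e9 (1122/mm³ × 5 L).

## Virtual cohort

Per patient: targeted baseline `T0` (mean 1.07e11 cells = 107 cc at 1e9
cells/cc), non-targeted baseline fixed at 0.1% of `T0`, lymphocytes
`L0 ~ N(5.61e9, 2.345e9)` truncated above 1e8, `alpha_T ~ N(0.148,
0.024)` truncated positive, and `q`, `delta_durva ~ N(0.12, 0.04)`
truncated to [0, 1] (resampling on rejection, so means stay near the
nominal values). The same cohort — same draws — is reused for every arm
and sweep cell, making all treatment contrasts within-patient.

The spread of `T0` is the one population quantity with no published
summary. The default is a lognormal with log-sd 0.70 about the 1.07e11
mean: this is the unique spread for which 40% of non-targeted baselines
exceed the 0.1 cc detection limit, the fraction reported for the cohort
this generator emulates; no normal distribution with the stated mean can
produce a below-half fraction, which is why the lognormal family was
adopted. A truncated-normal alternative (`T0_family="normal"`,
coefficient of variation `T0_cv`) is retained for sensitivity analyses.

What the generator does **not** emulate: correlations between baseline
covariates (e.g. larger tumors with lower lymphocyte counts), multiple
metastatic sites, measurement error in RECIST assessments, accrual and
loss to follow-up. Passing tests therefore show internal consistency of
the model and pipeline, not fidelity to any real patient population.

## Endpoints

RECIST categories use the sphere-equivalent diameter
`(6V/pi)^(1/3)`: PD at ≥ +20% vs baseline, PR at ≤ −30%, CR when the
lesion falls below the 0.1 cc imaging detection limit (1e8 cells), SD
otherwise; boundaries inclusive. The same detection limit defines both
CR (lesion disappears) and the distant-metastasis event (non-targeted
lesion appears), which keeps the two observables on one physical scale.
Progression is measured against the **baseline** diameter (not the
nadir, which RECIST 1.1 proper would use): this is the reading of the
response definitions the implementation follows, and it makes
progression equivalent to the cell count crossing 1.728 × its baseline.
Crossing times are interpolated linearly between integration samples so
Kaplan–Meier curves carry no step-size artifacts. Patients whose
non-targeted lesion is already detectable at day 0 are DM events at time
zero in the default all-patients analysis; an evaluable-only curve
restricted to initially undetectable lesions is always computed
alongside.

## Calibration of q

A 10,000-patient cohort receives Y90 monotherapy at 400 Gy (the center
of the studied 300–500 Gy range); RECIST is assessed at 6 months; the
(mu, sigma) of the [0,1]-truncated normal for q are searched to minimize
the L1 distance between simulated and target proportions
(CR 79 / PR 20 / SD 0 / PD 0) — a coarse grid followed by Nelder–Mead,
with all evaluations reusing one cohort and one set of uniform draws
mapped through the truncated-normal quantile function (common random
numbers; the objective is smooth enough for the local step). At the
published distribution (0.12, 0.04) the simulated profile is CR 77.8 /
PR 20.8 / SD 1.2 / PD 0.2 — already essentially the clinical target.
The objective is nearly flat along a one-dimensional manifold of
(mu, sigma) pairs with ~79% CR, so the reported optimum (mu ≈ 0.10,
sigma ≈ 0.01 at study scale) should be read together with that
degeneracy; the mean is identified to within about ±0.02.

## Numerics

- Fixed-step classical RK4, default `dt = 0.25 d`, vectorized across the
  cohort; radiation events applied exactly at their scheduled instants
  between steps. Halving the step changes the targeted burden at 5 years
  by far less than 0.5% on default parameters. The dynamics are
  non-stiff at these rates, so no implicit scheme is needed.
- Event times, snapshot times and the horizon must be multiples of the
  step (checked; an error names the offender).
- RK4 stage states are clipped at zero before evaluating rates; a
  completed step may undershoot zero by at most 1e-6 × the patient's
  initial burden (clamped), anything larger aborts integration with the
  time point named. Non-finite states abort likewise.
- Kaplan–Meier estimation, Greenwood variance, Brookmeyer–Crowley median
  intervals and log-rank tests are delegated to `lifelines`; time-point
  confidence limits use the log–log (Kalbfleisch–Prentice) transform so
  they stay in [0, 1]. The test suite cross-checks both the product-limit
  curve and the log-rank statistic against direct enumeration on small
  instances, and verifies the log-rank type-I error (0.054 at nominal
  0.05 over 2,000 null replicates).
- Seeding: a single master seed drives the cohort stream and a separate
  calibration stream (`SeedSequence([seed, tag])`), so every reported
  number is reproducible from one integer.

## Problem sizes

Study-scale computations use 10,000 virtual patients and a 120-month
horizon (medians near 5 years need the long follow-up); the calibration
assesses at 6 months. Demonstration scripts and most tests use cohorts
of 150–2,000 patients, which reproduce every qualitative conclusion; the
qualitative arm-ordering and dose-monotonicity checks run at n = 2,000.

## Known limitations

- **Late regrowth is slow by construction.** With the default rates, the
  immune kill available against a small (post-ablation) lesion is at
  most `omega1 · (s/f) / g ≈ 0.0072/d` against growth `a = 0.01/d`, so a
  deeply debulked lesion regrows at ≥ 350 days per e-fold once the ICI
  course ends, and at the grid midpoint more than half the cohort is
  still progression-free at 10 years: combination-arm median PFS is
  typically *not reached* at the default horizon. Published cohort
  summaries that pair a ~79% 6-month complete-response rate with
  16–57-month median PFS under the same parameter set are mutually
  inconsistent under these dynamics (regrowth from below detection to
  +20% of a ~107 cc baseline within months would require a growth rate
  several times `a`); this package reports what the stated equations and
  parameters actually produce. Early-phase quantities (ICI-monotherapy
  median PFS, 1-year PFS rates, baseline and 1-year DM fractions,
  response calibration) are insensitive to the issue and do match.
- **3-year DM vs dose.** Because a larger prescription also enlarges the
  lymphocyte blood dose (`kappa_blood` × physical dose), the 3-year DM
  rate improves monotonically with ICI effectiveness but can tick up
  slightly (<1 pp) with radiation dose. Setting `kappa_blood = 0`
  removes the reversal at the cost of removing radiation lymphotoxicity
  altogether.
- Single lesion per compartment; no multi-organ spread, no spatial dose
  distribution, no stochastic extinction at small cell numbers (a
  "cured" lesion below one cell can still regrow deterministically —
  mitigated by the CR detection threshold, not by absorbing states).
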