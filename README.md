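# y90ici

Tumor–immune dynamics and in-silico clinical trials for **yttrium-90
radioembolization (Y90-RE) combined with immune checkpoint inhibitors
(ICIs)** in hepatocellular carcinoma.

Y90-RE is a local therapy: a beta-emitting radionuclide delivered into the
hepatic artery irradiates the targeted lesion as it decays (half-life
2.6 d). Checkpoint inhibition (durvalumab, anti-PD-L1) is systemic: it
boosts immune-mediated kill of both the irradiated lesion and any disease
outside the perfused territory. Whether the two should be given together,
and in which order and at which doses when they cannot be, is an open
scheduling question. This package simulates virtual patient cohorts under
the five candidate regimens (each monotherapy; concurrent; Y90 first; ICI
first) and compares them with standard survival analysis, so that dose
grids and inter-drug intervals can be explored before committing to a
trial design.

## The model

Four compartments — targeted tumor cells $T_I$, non-targeted tumor cells
$T_{NI}$, inactivated (radiation-killed, antigen-releasing) cells $I$, and
circulating lymphocytes $L$ — evolve between radiation events as

$$
\begin{aligned}
\dot T_I &= a\,T_I-\omega_1'(t)\,\frac{T_I\,L}{g+T_I+T_{NI}},\qquad
\dot T_{NI} = a\,T_{NI}-\omega_1'(t)\,\frac{T_{NI}\,L}{g+T_I+T_{NI}},\\
\dot I &= -r\,I,\qquad
\dot L = \omega_2\frac{(T_I+T_{NI})\,L}{g+T_I+T_{NI}}
       +\omega_3\frac{I\,L}{g+I}+s-f\,L ,
\end{aligned}
$$

with the ICI boost
$\omega_1'(t)=\omega_1\bigl(1+\delta_{\mathrm{durva}}\,C_{\max}
e^{-\ln 2\,(t-t_{\mathrm{last}})/T_{1/2}^{\omega}}\bigr)$
refreshed at each biweekly administration. Radiation acts as
instantaneous events: the decaying Y90 source is discretized into daily
fractions $D_j$ (summing to the prescription), the targeted lesion
survives each with the linear–quadratic fraction
$e^{-\alpha_T qD_j-\beta_T (qD_j)^2}$ (killed cells move to $I$), and
lymphocytes survive linearly with $e^{-\alpha_L D_{L_j}}$. The
dimensionless effectiveness $q$ maps physical absorbed dose to effective
dose; its population distribution is calibrated so that simulated 6-month
RECIST proportions under Y90 monotherapy match clinical response data
(CR 79 / PR 20 / SD 0 / PD 0), yielding $q\sim N(0.12,\,0.04)$ truncated
to $[0,1]$.

Virtual patients sample baseline burden, lymphocyte count,
radiosensitivity $\alpha_T$, $q$ and $\delta_{\mathrm{durva}}$; the same
cohort is reused across arms (common random numbers). Endpoints are
progression-free survival (targeted lesion reaching +20% of its baseline
sphere-equivalent diameter) and distant metastasis (non-targeted lesion
crossing the 0.1 cc detection limit), summarized with Kaplan–Meier
curves, medians, time-point rates and log-rank tests.

## Worked example

Calibrating the Y90 effectiveness distribution
(`python examples/03_calibrate_q.py`):

```
target profile:  CR 79%  PR 20%  SD 0%  PD 0%
fitted q ~ truncated N(mu=0.123, sigma=0.039) on [0, 1]
achieved profile: CR 79.0%  PR 20.0%  SD 0.8%  PD 0.2%
L1 objective 0.011 after 42 cohort simulations
```

A 400 Gy prescription must act like roughly 48 Gy of uniformly effective
dose (mean q ≈ 0.12) to reproduce the observed response mix.

Running the five-arm trial on 500 shared patients
(`python examples/04_virtual_trial.py`):

```
          median_pfs_months  pfs_1y_pct  pfs_3y_pct  dm_1y_pct  dm_3y_pct
arm
Y90_mono               84.1        99.8        95.4       94.4      100.0
ICI_mono                5.3        24.8        14.4       73.2       84.6
A                       NaN        99.8        99.8       50.2       50.2
B                       NaN        99.8        99.8       61.2       61.2
C                       NaN        99.8        99.8       58.8       58.8
```

`NaN` medians are *not reached* (most of the arm is still
progression-free at 10 years). The combination arms dominate both
monotherapies for both endpoints; the concurrent arm A is at least as
good as the sequential arms, and giving Y90 before the ICI course (B)
beats the reverse order (C) — here with log-rank p = 0.003 for PFS.
ICI monotherapy controls neither lesion for long (median PFS 5.3
months); Y90 monotherapy ablates the targeted lesion but leaves the
non-targeted lesion essentially untreated (100% DM by 3 years).

Other entry points: `examples/01_single_patient_trajectory.py` (the four
compartments over time), `02_dosimetry_and_schedule.py` (activity → Gy
and the decay-weighted fraction schedule), `05_interval_sweep.py` (effect
of the gap between the two modalities). The same machinery is scriptable
from the shell: `y90ici calibrate|simulate|trial|sweep-dose|sweep-interval
[--config cfg.yaml] [--seed N] [--n N] [--outdir DIR]`.

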