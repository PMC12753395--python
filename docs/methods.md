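# Methods

## Model structure

Three mutually exclusive health states — disease-free survival (DFS),
progressed disease (PD), death (D) — on a one-month cycle, horizon 120
cycles (10 years), cohort starting entirely in DFS. Structural zeros: PD
cannot return to DFS; death is absorbing. By the end of the horizon
virtually the whole cohort has been absorbed, so lengthening the horizon
changes totals negligibly.

Transition probabilities are constant over time (no tunnel states, no
age-dependence) and derive from median event times under an exponential
(constant-hazard) assumption: `P = 1 − 0.5^(1/median) = 1 − e^(−R)` with
monthly rate `R = ln2/median`.

Three derivation choices deserve explanation:

- **Post-progression median = median OS − median DFS.** Nothing else is
  identifiable from two printed medians, and it reproduces the published
  PD→D probabilities exactly (22−14=8 → 0.083; 24−15=9 → 0.074).
- **DFS→D uses the OS median directly** (1−0.5^(1/22)=0.031,
  1−0.5^(1/24)=0.028). This replicates the published arithmetic even though
  it slightly overcounts DFS exits (the same death hazard also shortens the
  DFS median). A strict competing-risks split — total DFS exit fixed at
  `1−0.5^(1/median_DFS)`, divided between progression and death in
  proportion to cause-specific rates — is available via
  `competing_risks=True` and is also the required fallback when medians are
  so short that the direct arithmetic would push the DFS exit probabilities
  past 1 (the builder raises in that case).
- **Reporting convention for probability tables.** Published tables of this
  kind round the exit probabilities to 3 decimals and print stay
  probabilities as complements of the *rounded* values, and compute ±20%
  bounds from the rounded baselines (hence an LPD stay probability printed
  as 0.927 where full precision gives 0.9264, and a lower bound of 0.742
  rather than 0.741). `transitions.probability_table` applies exactly this
  convention; the trace itself always uses full precision.

If the post-progression median is under half a cycle the builder warns:
a monthly grid cannot resolve such fast transit (PD→D probability > 0.75).

## Trace, half-cycle correction, accrual

Membership is tracked at cycle boundaries (121 rows for 120 cycles);
`membership[t+1] = membership[t] @ P`. Per-cycle occupancy is the
trapezoid `(membership[t] + membership[t+1])/2` — the standard half-cycle
correction — applied to both cost and QALY accrual (the flag
`half_cycle=False` switches to end-of-cycle accrual). Statements that all
patients eventually enter death are read as describing absorption over the
horizon, not a forced kill switch; forcing absorption would make the
calibrated probabilities meaningless.

QALYs divide per-cycle utility-weighted occupancy by 12 (monthly cycles,
QALYs in years). Discounting is compound annual converted to a monthly
exponent, `d(t) = 1.05^(−t/12)`, applied from cycle 1; the one-time initial
cost at cycle 0 is undiscounted. Death carries utility 0 and cost 0.

A vectorised patient-level microsimulation (`engine.microsim_oracle`)
provides an independent stochastic check: at 200,000 simulated patients the
empirical state fractions agree with the deterministic trace to within
0.005 everywhere (binomial error at that n is ≲ 0.0034 at 3σ).

## Cost accrual and calibration

The published analysis reports per-patient direct hospital costs
(95,994.18 / 100,013.20 RMB) alongside 10-year cumulative discounted costs
(269,164.88 / 282,340.19 RMB) roughly 2.8× larger, without stating the
accrual mechanism. The minimal identifiable structure is a one-time initial
(surgical admission) cost plus a uniform per-cycle "alive" cost; because
the discounted total is exactly linear in the per-cycle cost,
`calibrate_state_costs` solves for it in closed form and re-evaluation
reproduces the target to well under 0.01 RMB. The calibrated values in the
shipped reference case are 9,525.63 (OPD) and 9,190.95 (LPD) RMB/month.

The published cumulative QALY totals (2.190 / 2.254) are **not**
reproducible from the stated parameters by a standard half-cycle-corrected
trace: the trace yields 1.121 / 1.240 QALYs, and no conventional accrual
variant (no half-cycle, per-cycle rather than per-year utilities, etc.)
bridges the ×1.8 gap cleanly. The package therefore treats those totals as
worked-example inputs to the ICER arithmetic — which reproduces the
published increment 13,175.31 RMB, ICER 205,864.22 RMB/QALY (consistent
with the unrounded QALY difference 0.064, not the rounded 0.063 printed
beside it) and the cost-effective decision at WTP 268,074 RMB/QALY — while
all trace-level claims are validated as properties (conservation,
monotonicity, linearity, calibration round-trip) instead.

ICER quadrants follow the usual dominance rules; in the south-west quadrant
(cheaper, less effective) the ratio is savings per QALY forgone and the
comparator is preferred when it *exceeds* WTP, flagged
`reversed_interpretation`. Net monetary benefit `wtp·U − C` gives the
equivalent threshold rule and drives the CEAC.

## Sensitivity analyses

**One-way (tornado).** Every parameter — per-strategy transition
probabilities, utilities, initial and per-cycle costs, and the shared
discount rate — is moved to the ends of its ±20% range (probabilities and
utilities capped at 1) with the others at baseline, and the pipeline is
re-run. Perturbing an exit probability adjusts the same row's
stay-probability to preserve row sums. Entries are sorted by ICER span;
the recorded ICER is the signed ratio Δcost/Δeffect so corners that cross
into dominance appear as sign changes rather than gaps. Under the reference
case the direct-cost parameters produce the widest spans.

**Probabilistic (PSA).** Distributions are not stated in the source
analysis; the default is independent uniform on the same ±20% ranges — the
only dispersion information available — with beta/gamma-style alternatives
expressible by passing explicit `(low, high)` ranges or custom draws. A
draw whose vector is structurally invalid (a matrix entry outside [0,1], a
utility outside [0,1]) is resampled, capped at 100 attempts. The discount
rate is excluded from PSA by default (no published range) but included in
the tornado. 1,000 draws by default; bit-reproducible given a seed. The
CEAC reports, at each WTP on a 0–400,000 RMB grid (10,000 steps), the
exact fraction of draws with positive incremental NMB.

The one-at-a-time and sampled vectors deliberately bypass the
`StrategyParams` constraint `u_pd ≤ u_dfs`: varying one utility by ±20%
can legitimately cross the other, and rejecting such draws would bias the
PSA; only structural validity (probabilities, [0,1] ranges, non-negative
costs) is enforced there.

## Synthetic cohort generator

Emulates a retrospective two-arm surgical cohort: 100 patients per arm by
default, uniform accrual over a 46-month window, administrative censoring
at a single cutoff 87 months after accrual start (no loss to follow-up —
no attrition data exist to calibrate one). Latent DFS is exponential with
the configured median; post-progression survival (PPS) is exponential with
its configured median; OS = DFS + PPS. Direct costs are log-normal
(positive, right-skewed, typical of hospital costs) with configurable mean
and a default coefficient of variation of 0.3, chosen absent any printed
dispersion.

**Dependence choice.** With PPS drawn independently of DFS, the median of
OS = DFS + PPS exceeds the sum of the component medians (≈26.3 months for
medians 14+8), so a generator configured from printed DFS/OS medians could
never reproduce the printed OS median. The default coupling is therefore
comonotone — PPS is the perfectly rank-correlated transform of DFS — under
which every stated marginal still holds (DFS ~ Exp(median 14), PPS ~
Exp(median 8)) and OS is *exactly* Exp(median 22). Perfect rank correlation
is an idealisation (real DFS/PPS correlation is positive but imperfect);
`pps_dependence="independent"` gives the opposite extreme. What passing
recovery tests show is that the estimation pipeline (Kaplan–Meier medians,
cost means) is unbiased for data with the assumed structure — not that real
surgical cohorts have exponential, perfectly-coupled sojourns, proportional
hazards between arms, or the published hazard ratios, none of which the
generator attempts.

Patients are deterministic functions of the config seed; identical
config + seed yields byte-identical cohorts (CSV format:
`arm,t_dfs,dfs_event,t_os,os_event,direct_cost`, times at 4 decimals).

## Problem sizes and numerical choices

Default/test problem sizes, chosen as the package's standard working
scales: 120-cycle traces; 200,000 individuals for the microsimulation
cross-check (binomial error < 0.005); 10,000 patients/arm for parameter
recovery (KM medians within 5%, cost means within 3% at fixed seeds);
1,000 PSA draws. Row-stochasticity is enforced to 1e-12 on construction
and 1e-10 along traces; probabilities are stored at full precision with
3-decimal rounding confined to reporting; currency is rounded to 2 decimals
at output only. Degenerate inputs (dead-start cohorts, zero post-progression
survival, calibration targets below the initial cost, empty cohorts) raise
informative errors rather than propagating NaNs.

## Known limitations

Constant hazards (no cure fraction, no time-varying risk); no tunnel
states; two strategies only; no indirect/hidden costs or price-index
re-adjustment (costs are consumed already expressed in 2023 RMB); PSA
samples parameters independently (no correlation structure); the published
cumulative QALY totals are consumed, not derived, for the reasons above.
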