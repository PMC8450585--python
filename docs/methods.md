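# Methods

## Cohort and horizon

A closed cohort enters at age 30 with active severe lupus nephritis
(classes III/IV, or III/IV + V).  The cycle length is 6 months — the natural
evaluation interval for induction therapy — and the model is run for
6 cycles (3-year horizon) or 60 cycles (lifetime, 30 years, matching the
life expectancy of Chinese LN patients).  The model is scale-free; the
nominal cohort size of 1,000 is used only to convert fractions to counts.

## State space and pathway

Each strategy expands to 17 states:

* six primary induction tunnel states — first-line drug cycles 1–2, the
  other first-line drug cycles 1–2, rituximab cycles 1–2;
* five re-induction tunnel states replaying the same escalation after a
  relapse (initial drug cycle 2, second-line 1–2, rituximab 1–2);
* a relapse entry state (clinically: renal relapse; behaves as re-induction
  cycle 1 with the initial induction drug and carries the relapse utility
  for that cycle);
* one remission (maintenance) state, a terminal no-remission state, and
  dialysis, transplant, death.

Primary induction cycles carry the base induction ESRD/death risks
(0.0080/0.0080 per cycle).  The elevated "no complete remission after
immunosuppressive treatment" risks (ESRD 0.0248, death 0.0283) apply to the
terminal no-remission state, to the relapse cycle, and to every re-induction
cycle: a relapsed patient has, by definition, failed to sustain remission.
Second-line induction and rituximab each get two cycles, mirroring the
explicit first-line rule (6-month course plus 6-month extension).  Patients
who relapse and then exhaust re-induction (including rituximab) enter the
terminal no-remission state.  Dialysis precedes transplantation; there is no
graft-failure return path.  Death is the only absorbing state and is
reachable from every state.  No age-dependent background (non-lupus)
mortality is layered on: the disease-specific hazards are the only death
risks, keeping every input traceable to the published table.

These pathway details are under-specified in the source text (it fixes the
first-line schedule, the switch rule, rituximab rescue and the
relapse-restarts-induction rule, but not the duration of second-line/rescue
courses or which risk set relapsing patients face).  The choices above were
fixed by a systematic comparison of the documented alternatives (risk
placement × course durations × relapse handling) against the source's nine
published clinical projections; the selected structure reproduces seven of
nine within ±2 percentage points and minimises the overall error.  The two
residual discrepancies are discussed under *Limitations*.

## Outcome definitions

* **Complete remission (%)** — occupancy of the remission state at the
  final cycle.  The source labels this column "cumulative incidence", but
  its printed lifetime values are *lower* than its 3-year values, which is
  impossible for a cumulative quantity; point prevalence is the only
  consistent reading.  The genuinely cumulative quantity (ever achieved
  remission, computed by an absorbing-at-remission auxiliary chain) is
  exposed as `cum_cr_incidence`.
* **Renal replacement (%)** — prevalence of the dialysis state at the final
  cycle, for the same reason: cumulative first entry into dialysis under any
  pathway reading exceeds the printed values several-fold (maintenance-phase
  ESRD inflow alone is ≈ 9 pp over 60 cycles for AZA), while dialysis
  prevalence matches them closely.  Both the cumulative first-entry measure
  and prevalence including transplant recipients are also computed.
* **All-cause mortality (%)** — death-state occupancy (deaths are never
  undone, so prevalence and cumulative incidence coincide).

## Economics

QALYs: Σ over cycles of occupancy · utility × 0.5 years, discounted by
(1.015)^(−t) for cycle t (1-based, membership evaluated after each
transition; no half-cycle correction — the source specifies only the
per-cycle rate).  Costs: the same accumulation over per-cycle state costs,
plus the one-time transplant cost applied to the entry flow into the
transplant state at the entry cycle's discount factor.  Undiscounted twins
of both are always reported.

The frontier marks strong dominance (weakly costlier and weakly less
effective than some strategy, strictly on one axis) and extended dominance
(adjacent incremental ratios must strictly increase along the
cost-sorted surviving set; violators are removed iteratively).  ICERs are
kept unrounded internally and rounded to whole dollars for display — this
reconciles printed-table artifacts where ratios of rounded increments differ
by one dollar from ratios of unrounded internals.

Willingness-to-pay: US$10,319 (1× 2019 Chinese GDP per capita, ¥70,892 at
6.87 CNY/USD) and US$30,957 (3×).  All costs are assumed to be expressed in
2019 USD already; the only currency operation is the single CNY→USD helper.

## Synthetic cost and utility tables

The per-state cost and utility inputs of the original analysis live in
supplementary material that is not redistributable, so the packaged defaults
are *synthetic*, generated deterministically (`SyntheticConfig`, default
seed 20190) under every constraint the main text states: utilities in
[0.56, 0.94] with death at 0; remission/relapse utilities lower under CYC
than under AZA/MMF; drug-cost ordering CYC < AZA < MMF (with RTX the
costliest agent); dialysis cycle cost above every drug state; a large
one-time transplant cost with ongoing transplant cost below dialysis; and a
three-way decomposition (direct medical / direct non-medical / indirect
productivity loss).  Costs are drawn on a log scale around anchors chosen
to be realistic for 2019 urban China (e.g. ≈ $250 per half-year of CYC,
≈ $1,600 of MMF, ≈ $7,800 per half-year of hemodialysis, ≈ $13,000 for a
living-donor transplant); sensitivity ranges default to ±25% for costs and
±0.05 for utilities.

Consequences for interpretation: clinical projections are invariant to
these tables (they depend only on the transition matrix — this is tested),
the dominance *machinery* is exact, but absolute costs, QALYs, ICERs and
acceptability percentages are illustrative.  Passing tests therefore show
that the economic pipeline is correct, not that the synthetic tables equal
the unavailable originals; qualitative economic findings (S3 highly
cost-effective vs baseline; MMF maintenance clinically best but pricier)
do reproduce under the defaults.

## Sensitivity analysis

DSA varies one parameter at a time to its published (transitions) or
configured (costs/utilities, discount) bounds, rebuilding both models of a
target pair (default S3 vs S1, as in the source's tornado) and recording the
ICER at each end; output is sorted by spread with a top-12 view.  Under the
packaged defaults the maintenance-phase ESRD risk on AZA ranks among the top
tornado parameters, matching the source's headline sensitivity finding.

PSA families: per source-state Dirichlet for transition rows with
pseudo-counts = 100 × base probabilities (an effective sample size chosen so
marginal SDs roughly span the published ranges; shared parameters such as
the induction ESRD/death pair form their own simplex group so one draw feeds
every row using them); truncated normal on [0, 1] for utilities and
moment-matched gamma for costs, both with SD = (high − low)/(2 × 1.96);
and an equal-probability two-point distribution on {low, high} for the
discount rate — the only tractable reading of a "binomial" on a scalar
rate.  The discount bounds default to 0–3% per cycle (0–6%/year), bracketing
the 1.5% base case; the source does not print them.  Invalid sampled
transition rows (sum > 1) are resampled and counted.  Acceptability at a
WTP value is the fraction of draws with the strictly highest net monetary
benefit, ties split equally, so curves sum to one at every grid point.
The default WTP grid is $0–50,000 in $500 steps plus both GDP thresholds.

## Numerical choices

Row-stochasticity and simplex checks use an absolute tolerance of 1e-10.
"Ever reached state X" quantities use an absorbing-at-X modification of the
chain rather than entry-flow summation, which would double-count re-entries.
The microsimulation cross-check draws per-patient categorical transitions
via row-wise inverse-CDF sampling from a seeded generator; the test suite
requires agreement with the deterministic cohort within three binomial
standard errors at n = 100,000 (and the acceptance-level property suite
re-runs exactly that).  Probability rescaling between annual and per-cycle
uses the constant-hazard form 1 − (1 − p)^t with an exact inverse.

Problem sizes in the shipped tests and scripts: 60-cycle deterministic runs
(instantaneous), DSA over ≈ 65 parameters (< 1 s), PSA at 1,000 draws × 6
strategies (≈ 5 s), microsimulation at 100,000 patients (≈ 1 s).

## Limitations

* Two published projections are not reproducible within ±2 pp from the
  published transition table under any pathway reading we examined: the
  lifetime all-cause mortality of S3 (printed 40.8%, model 37.8%) and the
  10-year mortality of S6 (printed 10.7%, model 13.4%).  The second is
  internally in tension with the inputs: MMF maintenance carries a higher
  per-cycle death risk than AZA (0.43% vs 0.25%), so by year 10 — before
  relapse- and ESRD-mediated channels dominate — S6 cannot fall below S3
  (printed 11.8%) without an additional mechanism the source does not
  describe.  Mechanisms strong enough to raise S3's lifetime mortality
  (continued lupus mortality on dialysis, age-dependent background
  mortality) overshoot both 10-year values or destroy the remission
  projections.  The discrepancies are reported as-is.
* Economic magnitudes rest on synthetic cost/utility tables (above).
* No per-class (III vs IV vs V) heterogeneity, no individual covariates,
  no time-varying transition probabilities, no graft failure after
  transplant, no therapy withdrawal for adverse events, and no
  expected-value-of-perfect-information analysis.
* The acceptability percentages printed by the source (34%/28%/40%) depend
  on its unavailable cost/utility inputs and are treated as directional
  only.
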