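# lncea — cost-effectiveness of severe lupus nephritis treatment strategies

`lncea` is a Markov cohort model for the health economics of severe lupus
nephritis (LN, classes III/IV ± V): it compares six induction → maintenance
immunosuppressant strategies used in Chinese clinical practice —

| label | induction | maintenance |
|-------|-----------|-------------|
| S1 (baseline) | cyclophosphamide (CYC) | CYC |
| S2 | mycophenolate mofetil (MMF) | CYC |
| S3 | CYC | azathioprine (AZA) |
| S4 | MMF | AZA |
| S5 | CYC | MMF |
| S6 | MMF | MMF |

— over a 3-year (6-cycle) and a lifetime 30-year (60-cycle) horizon with
6-month cycles, from a societal perspective.  Rituximab (RTX) is modelled as
rescue therapy after both first-line drugs fail.  It is intended for health
economists and rheumatology researchers who want a transparent, scriptable
re-implementation of this class of analysis.

## The model

Patients start induction at age 30.  Each 6-month induction cycle ends in
complete remission (probability `p_CR(drug)`: CYC 0.4084, MMF 0.3137,
RTX 0.4578), ESRD (0.0080), death (0.0080) or continuation: the same drug is
extended once, then treatment switches to the other first-line drug, then to
RTX; if RTX fails the patient enters a permanent no-remission state with
elevated ESRD/death risks (0.0248/0.0283 per cycle).  Remission carries
maintenance-drug-specific relapse/ESRD/death hazards; relapsed patients
restart the induction sequence with their initial drug, at the elevated
no-remission risks.  ESRD means hemodialysis, with a per-cycle chance of
living-donor kidney transplantation.  The chain is tunnel-expanded
(17 states per strategy) so every duration rule stays memoryless.

Economics: QALY = Σ occupancy × utility × 0.5 y, cost = Σ occupancy ×
state cost (+ one-time transplant cost on entry), both discounted at 1.5%
per cycle (3%/year).  Strategies are ranked on the incremental
cost-effectiveness frontier (strong and extended dominance), with
willingness-to-pay thresholds of 1× and 3× 2019 Chinese GDP per capita
(US$10,319 and US$30,957; 1 USD = 6.87 CNY).  Uncertainty is handled by
one-way deterministic sensitivity analysis (tornado) and probabilistic
sensitivity analysis (Dirichlet transitions, truncated-normal utilities,
gamma costs, two-point discount rate) summarised as cost-effectiveness
acceptability curves.

Transition probabilities ship as a packaged plain-text parameter file.
Per-state cost and utility tables are generated synthetically (see
`lncea.synthetic_data`) under the constraints the published analysis states
— utilities in [0.56, 0.94] with death at 0 and CYC remission/relapse
utilities strictly lowest, CYC the cheapest drug, dialysis costlier than any
drug state, and a large one-time transplant cost — so economic *magnitudes*
are illustrative while clinical projections and all frontier logic are exact.

## Worked example

```sh
lncea run --horizon lifetime --out results/
```

prints (abridged; costs/QALYs depend on the synthetic cost/utility tables):

```
strategy  cumulative_cost_usd  cumulative_qaly  icer_rounded              status  complete_remission_pct  renal_replacement_pct  all_cause_mortality_pct
      S1              70988.            9.687           NaN            frontier                     16.7                    4.7                     72.9
      S2              73377.            9.678           NaN  strongly_dominated                     16.3                    4.8                     73.0
      S3              87530.           13.897         3929.            frontier                     48.1                    6.2                     37.8
      S4              89583.           13.783           NaN  strongly_dominated                     46.7                    6.3                     38.8
      S5              93566.           14.150        23796.            frontier                     56.3                    3.3                     35.7
      S6              94757.           14.064           NaN  strongly_dominated                     55.4                    3.4                     36.3
```

Reading: over a lifetime, CYC→AZA (S3) buys 4.21 extra QALYs over the
baseline at ≈ $3,929 per QALY — far below the 1× GDP threshold, so it is
highly cost-effective — while MMF maintenance (S5/S6) gives the best
clinical profile (lowest ESRD prevalence and mortality) at a much higher
incremental price.  The three clinical columns come from the published
transition probabilities alone and reproduce the published projections
(e.g. S3: 48.1% remission, 6.2% on renal replacement, 37.8% mortality vs
printed 48.9 / 5.8 / 40.8).

Other subcommands: `lncea dsa` (tornado CSVs), `lncea psa --draws 1000
--seed 7` (CE-plane + CEAC CSVs), `lncea synth` (write a complete parameter
file with synthetic cost/utility tables).  Every output directory contains
a `manifest.json` sufficient to reproduce the run.

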