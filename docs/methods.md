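# Methods

## Model structure

`gistcea` implements an annual-cycle Markov cohort model comparing two
strategies for rectal GIST patients who completed one year of neoadjuvant
imatinib (400 mg daily) without progression and whose resection would
require an abdominoperineal resection (APR).  A hypothetical cohort enters
at age 60 and is followed for 20 one-year cycles from a healthcare-payer
perspective; outcomes are total discounted cost (2017 SGD) and
quality-adjusted life years, both discounted at 3% a year.

Twelve reporting health states are used.  The UAPR arm passes through
`UAPR_Yr1`, `UAPR_Yr2` (surgery plus two adjuvant-imatinib years, for three
total years of perioperative imatinib) and `UAPR_Yr3+` (surveillance).
Progression during the adjuvant years signals imatinib failure and moves
directly to `mets 1st PD` regardless of site.  From surveillance, a local
recurrence is treated with salvage surgery plus three further years of
adjuvant imatinib; a distant recurrence starts first-line palliative
imatinib (`1st DR`).  The CIUP arm stays on imatinib until progression:
local progression is resected (APR, no further imatinib; a subsequent local
recurrence receives salvage surgery only), while distant progression — and
any recurrence after the salvage — enters `mets 1st PD` directly, since
standard-dose imatinib has already failed.  The shared palliative chain is
`1st DR` → `mets 1st PD` (escalated-dose imatinib) → `mets 2nd PD`
(sunitinib) → `mets 3rd PD` (regorafenib) → `Dead`.

Salvage surgery may happen only once per pathway.  Because a Markov chain
is memoryless, the salvage reporting states are expanded into *tunnel*
states (one per adjuvant year plus a terminal surveillance state); each
expanded state maps back to its reporting label in exports.

## Transitions, mortality and rewards

Transition rows are built from annual event probabilities.  In every state
the per-cycle death probability is `max(disease-specific mortality,
background mortality at current age)`; surviving mass is allocated to the
disease events and the stay-put transition proportionally, so each row sums
to one (checked to 1e-12 at every build, and cohort mass conservation to
1e-10 at every cycle).  Disease-specific mortality appears only in
`mets 3rd PD` (annual probability 0.405 after regorafenib failure); in all
other states death occurs at the background rate.  Whether intermediate
metastatic states should carry additional disease mortality is not
identifiable from the published inputs; we keep them background-only and
note that this choice mostly affects scenario extrapolations far from the
base case (see Limitations).

One-time rewards attach to *entry* into the three surgical states (upfront
APR, APR after local progression on CIUP, salvage surgery): a surgery cost
of SGD 38,000 and an operative mortality of 0.5%.  Entry costs are charged
to everyone undergoing the operation (including operative deaths); deaths
are moved to `Dead` before the next cycle's rewards accrue.  Annual state
rewards combine the drug cost (imatinib 400 mg on adjuvant/continued
therapy and at `1st DR`; escalated-dose imatinib at `mets 1st PD`;
sunitinib at `2nd PD`; regorafenib at `3rd PD`), the SGD 3,000 annual
surveillance cost in every alive state, and the state utility
(post-APR 0.830, on-imatinib 0.935, recurrence/salvage 0.748, metastatic
progression 0.712).

Two conventions deserve emphasis:

* **Half-cycle correction (default on).**  Annual rewards use the
  trapezoid rule — half weight on the cycle-0 and cycle-20 boundaries —
  the standard convention of the decision-analytic software this class of
  model is typically built in.  With start-of-cycle crediting instead
  (`half_cycle_correction=False`) both arms' totals rise by roughly 4-8%.
  We verified that the corrected convention reproduces the published
  base-case QALYs to within 0.6% (UAPR) and 2.4% (CIUP), and keep the
  toggle public.
* **Escalated-dose imatinib cost (default = the 400 mg cost).**  The
  published cost table lists a single imatinib price and no separate
  800 mg row, and reusing that price in `mets 1st PD` reproduces the
  published base-case costs to within 0.1% (UAPR) and 1.8% (CIUP), whereas
  a dose-proportional doubling overshoots both arms by 13-19%.
  `imatinib800_multiplier` (default 1.0) makes the dose-proportional
  scenario a one-line change.

Discounting is `(1 + r)^-t` with cycle 0 undiscounted; one-time rewards
earned during the transition from cycle *t* to *t+1* are discounted at
*t+1*.

## Parameters

All inputs live in a `ParameterSet` whose defaults are the published base
case: six transition probabilities, four utilities, six costs, the 0.5%
operative mortality, and the structural settings (start age 60, 20 annual
cycles, 3% discount, WTP SGD 50,000).  Each uncertain parameter carries its
deterministic sensitivity range and PSA family (beta for probabilities and
utilities, gamma for costs, uniform for the conditional local-recurrence
probability).  Configurations round-trip through a flat YAML dialect
(`gistcea fixtures config`), and `validate_parameters` reports every bound
or ordering violation as data rather than exceptions.

Two quantities the published inputs do not pin down are exposed as explicit
parameters:

* `p_prog_ciup` — the annual progression probability on continued
  imatinib.  No figure specific to unresected-but-responding rectal GIST
  exists; we default to 0.370, the first-line metastatic progression
  probability, as the only standard-dose-imatinib failure rate available.
  This likely overstates progression for minimal-residual disease, which
  would bias *against* CIUP; users can lower it independently.
* `p_local_given_prog_ciup` — the local fraction of CIUP progressions,
  defaulting to the post-APR conditional local probability 0.135.

Derived quantities (`derive_secondary`) split total recurrence into local
and distant parts by the conditional local probability — the split
conserves probability mass exactly — and compute the escalated-dose
imatinib cost from the multiplier.

## Background mortality

The analysis needs an age-specific all-cause mortality schedule; national
tables are not redistributable here, so `gistcea.fixtures` generates a
synthetic Gompertz hazard `q(age) = a·exp(b·age)` with `a = 2.3e-5`,
`b = 0.09/year`, giving q(60) ≈ 0.005 and q(80) ≈ 0.031 — plausible
all-population values for a high-income country.  Over the modelled ages
this stays an order of magnitude below the end-stage disease mortality, so
the max-of-mortalities rule binds only in `mets 3rd PD`, as intended.  Any
two-column CSV (`age,qx`) can be supplied instead.  Because results are
driven by disease dynamics, totals are insensitive to plausible
perturbations of this table; exact replication of a specific national
schedule is out of scope.

## Distribution fitting and PSA

Sensitivity ranges are read as central 95% intervals: the target standard
deviation is `(high − low)/3.92` and the target mean the base value.  Beta
and gamma shapes follow by moment matching in closed form (the fitted mean
reproduces the base value to 1e-9; infeasible matches raise with the
parameter name).  The uniform family takes the range bounds directly, so
its mean is the range midpoint rather than the base value — a property of
the published inputs, not a fitting error.

The PSA draws every parameter with a tabulated distribution independently
(no correlation structure is published).  `p_prog_ciup` and
`p_local_given_prog_ciup` are aliases of tabulated rows rather than
independent evidence, so each tracks its parent's draw whenever the user
has left the base values equal; decoupling the base values freezes them.
The escalated-dose cost tracks the sampled imatinib cost through the
multiplier.  Operative mortality and all structural settings are fixed.
Draw *i* uses the counter-derived stream `default_rng([seed, i])`, so runs
are bit-reproducible and draw *i* is invariant to the total number of
draws.  Acceptability curves report, per WTP on a 0-100,000 grid in steps
of 2,500, the fraction of draws in which each strategy has the strictly
higher net monetary benefit, ties going to the cheaper strategy.

## Deterministic sensitivity machinery

One-way sweeps default to 101 points over the tabulated range; scenario
grids may extend beyond it and are clamped only at the hard [0, 1] domain
bounds.  When the post-APR recurrence probability is swept, the
local/distant *conditional* split stays fixed, and the same variable drives
every place the quantity appears (adjuvant-year progression, post-salvage
and post-APR-on-CIUP recurrence), mirroring a single named model variable.
Thresholds are located by bisection on any boolean predicate of the
comparison (named predicates cover cheaper/more-effective/cost-effective
for either strategy) to 1e-4 absolute by default; the published thresholds
carry 2-3 significant figures.  The two-way surface evaluates the NMB
winner over a grid of two parameters; because the NMB difference is
monotone in the post-APR utility, the "UAPR wins at every utility" bound
equals the threshold at the lowest utility considered, which is how the
acceptance script computes it.

## Problem sizes and numerical choices

Every cohort run is a 20-cycle iteration over at most 12 expanded states,
so the full deterministic suite (thresholds to 1e-5, 6×36 two-way grid)
completes in seconds and the 10,000-draw PSA in well under a minute on one
CPU; these are the sizes used throughout the tests and the acceptance
script.  Ties in NMB comparisons resolve to the cheaper strategy;
degenerate (single-point) sweep grids and surfaces are allowed; a
degenerate PSA (all families `fixed`) collapses exactly to the base case.

## What the synthetic inputs do and do not show

The synthetic life table emulates the *shape* of an all-population
mortality schedule, not any specific country's rates, and the toy chains
used in testing exercise the engine against closed-form matrix-power sums.
Passing tests therefore demonstrate that the implementation computes the
specified model correctly and reproduces the published analysis within the
documented bands — not that the model's clinical inputs generalise beyond
their sources.

## Known limitations

* The exact wiring of the original decision-analytic software is not
  published.  Base-case totals and six of the seven published thresholds
  reproduce within 2.4% / 3 pp; the extreme-scenario QALY-crossing on the
  recurrence probability computes to ≈ 39% against a published 47%, the
  one quantity sensitive to conventions (e.g. extra mortality in
  intermediate metastatic states) that the published inputs do not
  identify.
* At a willingness to pay of exactly 0 the acceptability probability for
  UAPR is ≈ 0.949 — at WTP 0 this is simply the probability UAPR is
  cheaper — slightly below the ≥ 95% the published acceptability curve
  shows across its plotted range.
* No indirect (societal) costs, no toxicity utilities or costs, no
  mutational or clinicopathologic stratification, no currency conversion:
  all deliberate scope matches to the source analysis.
* Cohort expectation only; no individual-level microsimulation.
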