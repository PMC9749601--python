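# Methods

## Scope and accounting framework

`nutricost` computes the incremental financial and economic cost of a
multisectoral agriculture–nutrition programme delivered through an
existing microcredit platform, over a 40-month implementation window
(months 0–39, starting October 2016; the first six months are the
start-up phase). Costs incremental to the platform are included from the
payer and societal perspectives: implementer expenditures, frontline
workers' unreimbursed time and out-of-pocket (OOP) outlays, and
beneficiaries' participation time. Third-party research costs and
cost-effectiveness analysis are out of scope.

Every valued cost cell is keyed by five closed code sets:

- **activity** — 15 standardized programme activities (planning,
  installation, awareness raising, training, materials development,
  management, M&E, procurement, input distribution, site supervision,
  nutrition/gender home visits, agricultural home visits, community
  events, integration/coordination, indirect overhead);
- **input** — 10 resource categories (hired personnel, beneficiary
  personnel, supplies, equipment, agricultural supplies/equipment,
  contracted services, fuel/maintenance, travel/per-diem, overhead);
- **stage** — start-up vs recurrent. A cost is start-up iff it falls in
  months 0–5 *and* belongs to a one-time launch activity (planning,
  installation, materials development, initial training); recurring work
  in the early months stays recurrent;
- **nature** — financial (expenditure-based) vs economic
  (opportunity-cost) valuation;
- **arm** — treatment arms 2–4 of the additive trial design (arm 2
  nutrition counselling; arm 3 adds agricultural extension; arm 4 adds
  gender sensitisation; the control platform carries no incremental
  cost).

Cost cells additionally carry weights over the three nutrition-sensitive
value-chain pathways (supply, demand, enabling environment).

## Valuation

**Currency and price base.** Nominal BDT amounts divide by 84.77 BDT/USD;
an annual index relative to 2019 (identity by default, configurable)
reprices to 2019 USD. The index is applied after currency conversion.

**Capital.** Durable goods with a unit price above USD 100 and useful
life beyond one year are annuitized: equivalent annual cost =
price / *A*(r, n) with *A*(r, n) = (1 − (1+r)<sup>−n</sup>)/r, r = 3%/yr,
default n = 10 yr; the programme is charged the annual cost times
40/12 years. Cheaper or shorter-lived purchases are expensed. One-time
start-up operating costs are *not* additionally annuitized — the start-up
margin carries full value.

**Taxes.** Financial valuation keeps taxes. Economic valuation excludes
the tax component of durable goods; small supplies keep tax in both
(value-added tax embedded in commodity prices).

**Worker economic costs.** Unpaid time = workers × (extra-work hours +
travel hours per month) × months × an hourly rate; a single rate covers
work and travel hours (configurable assumption). The rate is conceptually
the contracted monthly salary spread over the 36-hour week
(salary/(36·52/12)); since the salary level is not part of the published
summary, the calibrated configuration solves the implied rate from the
hired-personnel economic margin (≈ $0.25/h for 80 workers). OOP outlays
use monthly means per stipend period — months 0–16 (no stipend), 17–32
(200 BDT stipend), 33–39 (500 BDT stipend) — treated as already net of
stipends, summed over the months each period overlaps the window.

**Beneficiary opportunity costs.** Participation hours per person-month
by gender (survey moments: men 0.96 ± 1.22 h, women 1.8 ± 1.66 h) priced
at mean daily agricultural wages over an 8-hour workday. The packaged
synthetic wages are 300 BDT/day (men) and 250 BDT/day (women) — declared
stand-ins, since the survey wage table is not published — with a recorded
`wage_scale` factor (≈ 1.037) solved so the beneficiary cost margin is
met. Counts: one index woman per household plus her spouse from the
index-pair roster.

## Allocation rules

- **Coding.** Line items resolve to an activity via (1) explicit hint,
  (2) cadre flag → personnel time-share allocation, (3) description
  keyword rules, (4) per-input defaults; anything unresolved is rejected
  by entry id, never silently defaulted. The ruleset ships as editable
  config with a version field.
- **Personnel time shares.** Cadre profiles (from implementer
  interviews): nutrition frontline workers 80% nutrition home visits /
  10% training / 5% planning / 5% coordination at full FTE; district
  managers 30% FTE, all supervision; field organisers split extension /
  supervision / events. Part-time staff's non-programme share is excluded
  from the cube.
- **Shared costs** split proportionally by configured weights using a
  largest-remainder cent partition: outputs are whole cents, conserve the
  input exactly (sub-cent residue on the final key), and the rule is
  homogeneous up to rounding.
- **Arms.** Component scope fixes the eligible arm set (nutrition and
  platform-wide → {2,3,4}, agriculture → {3,4}, gender → {4});
  within it, costs split proportionally to household counts (1,260 per
  arm). The published summary never states its arm-allocation rule; this
  rule is this package's declared assumption, chosen because it
  reproduces the additive, monotone arm cost gradient. Component-specific
  activities keep their scope (agricultural visits and input distribution
  → agriculture; combined nutrition/gender home visits split 0.8/0.2 by a
  config parameter, standing in for an unpublished split); the scope
  shares of all remaining shared costs are *solved* so the reported
  annual per-household arm series (36.62 / 65.18 / 87.50 USD) is
  reproduced — arm-level results are matched by construction, not
  independently derived.
- **Economic streams → activities.** The three streams map to inputs
  (unpaid time → hired personnel; OOP → travel; beneficiary time →
  beneficiary personnel). Their activity allocation is solved
  deterministically under the constraints that staff-only activities
  (planning, M&E, coordination) receive only staff time and that
  beneficiary time flows only to field-facing activities (training, home
  visits, community events), meeting the economic activity margin
  exactly.
- **Typology.** Agricultural extension and input distribution are
  supply-side; awareness raising demand-side; nutrition/gender home
  visits split demand/enabling by the 0.8/0.2 sub-split; every shared
  activity receives the programme-level component weights, default
  supply 0.20 / demand 0.35 / enabling 0.45 (chosen once so the pooled
  typology profile lands near the reported ≈ 23/47/30 split; config).

## Unit costs

Unit cost = total cost / denominator count; annualization divides by
40/12 years. The 40/12 divisor (not "3.5") is used because the published
per-beneficiary values are arithmetically consistent only with 40/12.
Four denominators: households (3,780), index woman + spouse (7,090),
index adults + children (3 × 3,703), all members (3 × 5,884). The
published pooled counts for the last two (11,110 and 17,653) exceed the
sum of their per-arm counts by one person each; the package uses the
per-arm counts (pooled = sum over arms), which rounds to the same unit
costs. Two published arm series exist (annual per household
36.62/65.18/87.50 vs abstract 65.37/114.15/157.11 with an unstated
definition); this package reports the first and notes that the second
numerically equals whole-period arm totals divided by index-pair counts.

## Uncertainty analysis

Seven parameters carry uncertainty: worker extra-work hours
(4.24 ± 2.34), travel hours (19.65 ± 10.28), OOP per month in three
stipend periods (6.55 ± 3.02, 4.31 ± 2.78, 1.45 ± 2.00 USD), and
beneficiary hours by gender. Each gets a gamma distribution by moment
matching (shape = (μ/σ)², scale = σ²/μ; hours and costs are
nonnegative). The Monte Carlo run (default 5,000 simulations, seeded
`numpy` Generator, parameters independent — no correlation structure is
published) propagates draws through the deterministic cost model; the
financial total is held at base case since only micro-costed inputs are
uncertain. Reported limits are the 2.5th/97.5th percentiles of the
simulated outcome (the published table's "lower/upper limit" are
undefined; this is the declared definition). The published simulation
table's base case is internally inconsistent with the cost table and is
not a calibration target; only its structure is reproduced. The tornado
moves one parameter at a time to its 10th/90th distribution percentile
(config-overridable) and ranks by swing in total incremental cost.

## Synthetic data

The generator's defaults are the study conditions: financial margins by
activity, input and stage; economic margins by activity and stream; the
beneficiary roster; survey moments; 80 frontline workers. The ledger is
built from a rank-one activity × input table (the outer product of the
two margins reproduces both exactly), stage-split by greedy assignment of
the start-up total to one-time activities (installation, then materials,
then planning, then training), with a $60,000 frontline-salary pool
carved out and re-emitted as uncoded cadre-tagged lines so the pipeline's
time-share allocation is exercised on the default fixture. Each cell is
split into 1–3 log-normally jittered line items rescaled exactly to the
cell, with months, descriptions, a below-threshold durable
(agricultural equipment) and taxed supplies for realism. Everything is a
pure function of (config, seed); different seeds change line items but
not coded margins.

What the synthetic data does *not* emulate: real ledgers' coding
ambiguity (the fixture's hints always resolve), arm-specific variation in
participation time (only pooled moments are published), seasonal cost
patterns, within-cadre salary dispersion, and any correlation between
uncertain inputs. Passing tests therefore demonstrate that the accounting
machinery is exact and the published summary structure is internally
recoverable — not that the pipeline is robust to messy real-world coding.

## Numerical choices

- Money is `float64`; partitions round to whole cents by largest
  remainder (ties by key order) and conserve totals exactly; the economic
  stream → activity split is exact-float so margin cells hold to ± $0.01
  after the downstream scope and arm partitions.
- Share sums are validated to 1 ± 1e-9 (1e-6 for serialized configs);
  the annuity factor switches to the straight-line limit below r = 1e-9
  to avoid cancellation.
- Percent reporting rounds half-up to whole percent.
- Degenerate inputs fail loudly: empty weight maps, zero-total profiles,
  unresolvable entries, missing arms and infeasible margin targets all
  raise typed errors naming the offender.
- Problem sizes in the test suite: the default fixture (~700 line items),
  5,000-simulation sensitivity runs, and 10⁵-draw distributional checks —
  sizes chosen to match the study's own scales.

## Known limitations

- Arm-level and typology results are reproduced by construction
  (calibrated scope shares and component weights), because the underlying
  allocation tables are unpublished; they validate the machinery, not the
  unpublished data.
- The economic model is linear in its uncertain inputs, so tornado
  rankings follow directly from calibrated stream sizes and distribution
  spreads.
- No cost-effectiveness: outcomes of the companion impact evaluation are
  not modelled, and no purchasing-power-parity or differential
  discounting is applied.
- The inflation index defaults to identity; users repricing multi-year
  ledgers should supply a real deflator series.
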