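# Methods

## Model structure and assumptions

The pipeline projects the population of a region living with Alzheimer's
disease (AD) and the direct costs of caring for it over a multi-decade
horizon, at yearly resolution.

The population model is a deterministic multi-state cohort simulation.
States are *disease-free*, *Mild*, *Moderate*, *Severe* and *Death*; the
disease states are defined by cognitive-screening (MMSE) bands in the data
the cost tables derive from.  Counts are propagated as expected values
(count × probability), not by individual-level sampling: the quantities of
interest are regional totals in the thousands, where Monte-Carlo noise
would only obscure the arithmetic, and determinism makes every run exactly
reproducible.

Within a simulated year the update order is fixed:

1. every AD cohort ages one year; the aggregated 95+ bin absorbs its own
   survivors;
2. the 4×4 stage transition matrix is applied; the death column removes
   people from the system;
3. the disease-free pool is set to the official projection count minus the
   simulated AD count, floored at zero;
4. incident cases move from the disease-free pool into Mild.

This order makes the calibration step (below) a closed-form solve and keeps
death and incidence non-overlapping within a year.

Two assumptions deserve emphasis:

- **The transition matrix's death column is all-cause mortality of AD
  patients.**  AD cases leave the simulation only through that column, so
  it must include background old-age mortality, not just disease-attributed
  deaths.  Supplying disease-specific death rates (e.g. 5%/year for mild
  AD, below general-population mortality at age 80+) makes AD patients
  out-survive the demographic tail of the projection and pushes the
  calibration against its clamps at the top age bin.
- **Disease-free demography is implicit.**  Mortality and migration of the
  disease-free group are never modelled; the official projection already
  embeds them, and the disease-free pool is simply its residual.  The
  projection is therefore authoritative for totals; the model only
  allocates them between the AD and non-AD groups.

Ages below 65 carry zero prevalence and incidence.  The top cohort is the
aggregated 95+ bin; two cohorts age into it each year while its target is a
single prevalence value, which is the model's known end-of-range artifact
(see *Limitations*).

## Incidence back-calculation

Age-specific prevalence is a far better-measured quantity than incidence,
so the model takes a prevalence curve `p(a)` (ages 65–95+) as the
calibration target and derives incidence.  For the step into year `t+1`,
after ageing and transitions:

    required(a) = p(a) · N(a, t+1) − survivors(a)
    i(a, t)     = required(a) / healthy(a),   clamped to [0, 1]

where `N` is the projection count and `healthy` the post-ageing
disease-free pool.  Because one simulated year is linear in `i`, this exact
one-step inversion replaces any iterative root-finding, and re-simulating
with the derived incidence reproduces `p(a) · N(a, t)` at every age and
year to machine precision — the pipeline's core internal oracle, asserted
at 1e-6 relative error in the acceptance suite.

Incidence is solved per year (one curve per simulated step).  Clamping
events — a negative requirement (survivors already exceed the target) or a
requirement above the pool — are recorded on the returned curve, logged,
and surfaced in the run manifest.  The round-trip identity holds exactly
on clamp-free scenarios and is not claimed elsewhere.

Incidence curves are labelled by the **destination age**: `i(a)` applies to
the disease-free pool at age `a` in the arrival year.  With zero incidence
below 65 this is the only labelling under which the age-65 target is
reachable in every year.

## Stage initialisation

The split of prevalent cases into Mild/Moderate/Severe at the start year is
not an input; it is determined by convergence, in two steps.

1. **Limit split.**  A stage-proportion vector is pushed through the
   survivor-restricted stage chain (the 3×3 sub-matrix of the transition
   matrix, renormalised over survivors each year) for the full horizon;
   the end proportions seed the next run, until successive runs agree in
   sup-norm (default 1e-8, max 200 runs).  This converges to the dominant
   left eigenvector of the survivor chain — the quasi-stationary stage
   distribution — and is validated against an independent power-iteration /
   eigendecomposition oracle.  The iteration is ill-conditioned when the
   two largest stay probabilities tie (the limit is then degenerate); the
   synthetic generator keeps a gap of at least 0.02 between them.
2. **Age-resolved refinement.**  The uniform limit split is not a fixed
   point of the full model: the age-65 bin is 100% newly incident Mild
   cases, and older bins mix cohorts of different disease durations.  The
   pipeline therefore feeds end-state *per-age* stage proportions back
   through full calibrated runs until they converge (default 1e-9
   sup-norm).  The fixed point is the model's own steady-state composition
   by age; under a stationary scenario (constant projection and
   prevalence) it renders the whole trajectory — including stage-weighted
   costs — constant to machine precision, which the acceptance suite
   asserts at 1e-6.

## Cost model

Medical and social-care costs are computed from separate data systems that
cannot be linked at patient level; the model keeps them additive.

**Medical costs** use per-treated-patient unit costs by stage × age band
(65–69, 70–79, 80–89, 90+) × six care categories (outpatient point-system
procedures, other outpatient services, medicines, inpatient point-system,
acute inpatient care, other inpatient care).  A constant treated share per
stage converts AD head-counts into treated counts.  Costs are exactly
linear in counts, shares and unit prices.

**Non-medical costs** price the social-service inventory: residential
capacity in beds × AD-utilisation share × EUR per bed per day × 365, and
non-residential capacity in full-time employees × AD share × EUR per FTE
per month × 12.  The annualisation constants are the only ones consistent
with the unit definitions.  Capacity is assumed to grow with the AD
population: the base-year inventory cost is multiplied by the growth index
`g(t) = AD(t) / AD(base)` (base year defaults to the first simulated
year), with unit prices held at constant base-year levels and no
discounting.  The index uses the total AD population, not per-stage counts,
matching the stage-flat per-person social costs below.

**Per-person figures** divide stage medical costs by stage head-counts;
non-medical costs divide by the total AD head-count and are identical
across stages, because social-care records carry no health-state
information.  A stage-split cost view allocates non-medical costs
proportionally to stage head-counts — a presentation convention, not a
data claim.

Internal arithmetic is full precision; reports round to whole EUR
(per person) and thousandths of millions (totals), with row totals computed
from the rounded components so every written row is additively exact.

## Packaged fixtures

The published cost-side tables for the two Czech study regions are
machine-readable and are packaged verbatim under `src/adburden/data/`:
medical unit costs (2017 price base), residential and non-residential
service inventories (2019–2020 price base), and the reference yearly and
per-person cost summaries used by the worked examples.  The two price
bases are left mixed, as in the source inventories.  One reference cell
(VYS 2020 total, 38.484 vs component sum 38.485 MEUR) is display-rounding
inconsistent and is excluded from exact-equality checks; the VYS
stage-agnostic per-person total follows the additive value (4733 EUR).

Treated shares are not published; the generator's defaults (mild 0.25,
moderate 0.40, severe 0.55) reflect that treatment contact rises with
severity while many mild cases remain undiagnosed or untreated.

## Synthetic data generation

The remaining inputs exist only as figures or non-public files, so the
generator emulates their structure rather than their values:

- **Population projection**: a stationary age pyramid under a Gompertz
  mortality hazard (`μ(a) = 5e-5 · e^{0.09a}`), closed with a geometric
  95+ tail, scaled by 6000 births/year to a region of roughly half a
  million inhabitants.  The 65+ segment drifts upward (default 1.5%/year)
  while the total population declines late in the horizon (default
  0.8%/year from year 35), emulating an ageing, eventually shrinking
  region; a seeded 2% lognormal jitter roughens the pyramid without
  breaking cross-year stationarity when drifts are zero.
- **Prevalence**: `p(a) = min(cap, base · e^{rate (a − 65)})` with defaults
  1% at 65 doubling per ~6 years of age (≈31% at 95+), the magnitudes
  European AD prevalence studies report.
- **Transition matrix**: progressive structure built by complement
  arithmetic from per-stage progression (0.20, 0.22) and all-cause death
  (0.10, 0.18, 0.40) probabilities — annual all-cause mortality magnitudes
  for mild/moderate/severe AD cohorts with median age above 80.
- **Cost tables**: every cell drawn uniformly within ±30% of the `khk`
  fixture magnitudes, or the fixtures verbatim in `khk`/`vys` mode.

A single seeded generator drives all draws; one seed reproduces the entire
bundle byte-for-byte.  The randomised scenario sweep (`random_spec`)
additionally screens its draws for calibration feasibility — scenarios
whose demographic tail cannot absorb surviving AD stock at the 95+ bin are
redrawn — because the incidence inversion, and every property stated about
it, is defined on clamp-free scenarios.

What the generator does **not** emulate: real Czech cohort-component
demography (migration waves, cohort effects), uncertainty in any input
(the source publishes none), age-dependent transition probabilities, or
regional prevalence differences.  Passing tests therefore demonstrate the
pipeline's internal correctness — calibration, conservation, linearity,
determinism — on structurally realistic inputs, not agreement with any
real region's future.

## Numerical choices

- Transition rows must sum to 1 within 1e-12; Death is absorbing exactly.
- Calibration tolerance 1e-6 relative (round-trip oracle); limit-split
  tolerance 1e-8 sup-norm; composition-refinement tolerance 1e-9; both
  iterations cap at 200 with a diagnostic error carrying the last iterates.
- Incidence clamps to [0, 1]; a positive requirement on an empty pool pins
  the rate at 1 and flags the year/age as infeasible (defensively — it is
  unreachable for any prevalence ≤ 1); a negative requirement on an empty
  pool records the overshoot.
- Ties in stay probabilities make the limit split degenerate; generated
  matrices keep a ≥0.02 gap.
- Growth index with a zero AD base year raises rather than returning
  infinities; per-person figures with empty stages raise, except in the
  report layer where a zero-AD run writes all-zero tables.
- CSV output uses full-precision floats (reports round as stated above),
  decimal points and UTF-8 throughout.

## Problem sizes

Default runs simulate 96 age cohorts over 51 years (2020–2070); the
property sweeps use 20 seeded scenarios of 31 years and 10 random
transition matrices.  The full test suite and the acceptance script each
complete in a few seconds on one CPU.

## Limitations

- The aggregated 95+ bin receives two ageing cohorts against a single
  prevalence target; with low AD mortality or steep demographic decline
  the target is unreachable from above and the calibration clamps (the
  end-of-range artifact).  Clamps are always surfaced, never silent.
- Indirect costs (productivity losses of patients and informal caregivers)
  and the MCI prodrome are out of scope; no discounting or price-level
  harmonisation between the 2017 medical and 2019–2020 social price bases
  is attempted.
- Monotonicity of derived incidence in the prevalence target holds under
  scalar scaling of the whole curve, and is tested in that form; raising
  prevalence at a single age can lower the required incidence at the next
  age (more survivors, same target), so general pointwise dominance does
  not imply pointwise-larger incidence.
- Transition probabilities are age-uniform; the same 4×4 matrix applies at
  67 and at 94, which overstates progression-free survival at the oldest
  ages relative to age-resolved clinical data.
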