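# adburden

Regional projection of the Alzheimer's disease (AD) population and of the
direct medical and social-care costs of caring for it, built as a two-pillar
pipeline:

1. **Population pillar** — an age-cohort multi-state simulation of the 65+
   population split into disease-free and AD groups, with AD staged
   *Mild → Moderate → Severe → Death* (Death absorbing, no reverse or skip
   transitions).  Age-specific incidence is not an input: it is
   back-calculated so that the simulation reproduces a target age-prevalence
   curve against an official population projection.
2. **Cost pillar** — annual direct costs attached to the simulated
   trajectory: *medical* costs as treated head-counts × per-treated-patient
   unit costs (by stage, age band and care category), and *non-medical*
   (social-care) costs as the AD share of residential bed-day and
   non-residential FTE-month capacity, scaled with the growth of the AD
   population at constant unit prices.

The package targets health-economics and long-term-care planning use: it
ships transcriptions of published cost inventories for two Czech regions
(Kralovehradecky kraj, `khk`, and Kraj Vysocina, `vys`) as worked-example
fixtures, and a synthetic-data generator that replaces the non-public
regional inputs (population projection, prevalence curve, transition
probabilities, treated shares) with internally consistent stand-ins.

## Model

For each calendar year, cohort ages `a = 65 … 95+` and stages
`s ∈ {mild, moderate, severe}`:

- **Ageing** — every AD cohort moves up one year of age; the aggregated
  95+ bin absorbs its own survivors.
- **Transitions** — the 4×4 one-year matrix `P` is applied as expected
  counts; the death column is *all-cause* mortality of AD patients, the only
  exit from the AD group.
- **Residual demography** — the disease-free pool is the official
  projection count minus the simulated AD count (background mortality and
  migration are implicit in the projection).
- **Incidence** — new cases enter Mild: `new(a) = healthy(a) · i(a)`.

Calibration inverts this one year at a time.  Because a simulated year is
linear in `i`, the solve is closed-form:

    i(a, t) = (prevalence(a) · N(a, t+1) − survivors(a, t+1)) / healthy(a, t+1)

clamped to [0, 1] with every clamp logged.  The initial stage split is the
limit distribution of the survivor-restricted stage chain (the dominant left
eigenvector of the 3×3 sub-matrix of `P`, found by iterated simulation
runs), refined into an age-resolved composition by end-state feedback.

Costs per year `t` with growth index `g(t) = AD(t) / AD(base)`:

    medical(t)     = Σ_{s,b}  count(s, b, t) · share(s) · unit(s, b)
    non-medical(t) = g(t) · [ Σ_r beds_r · adshare_r · eur_bed_day_r · 365
                            + Σ_n fte_n · adshare_n · eur_fte_month_n · 12 ]

All prices are held constant (no discounting); per-person figures divide by
stage head-counts (medical) or the total AD head-count (non-medical, which
cannot be stage-resolved in social-care data).

## Worked example

The numbered drivers under `analysis/` run the whole study on a synthetic
region and on the packaged fixtures, writing their tables under `results/`:

```bash
python analysis/01_generate_inputs.py
python analysis/02_simulate_population.py
python analysis/03_project_costs.py
python analysis/04_worked_example.py
```

which prints, among other lines:

```
region 'synth', 2020-2070: 467,238 inhabitants, 88,693 aged 65+ (19.0%) at baseline
AD population: 4,685 -> 8,744 (1.87x)
limit stage split (mild/moderate/severe): [0.135 0.27  0.595]
  2020: medical 1.795 MEUR + non-medical 18.078 MEUR = 19.873 MEUR
  2070: medical 3.350 MEUR + non-medical 33.739 MEUR = 37.089 MEUR
khk: total direct costs 25.636 MEUR (2020) -> 69.018 MEUR (2070), 2.69x; non-medical/medical >= 4.87
vys: total direct costs 38.485 MEUR (2020) -> 107.983 MEUR (2070), 2.81x; non-medical/medical >= 8.48
  khk (stage-agnostic): 482 medical + 2330 non-medical = 2812 EUR per person with AD per year
```

The synthetic region's AD population grows 1.87× by 2070 and, since social
care dominates the bill and its capacity tracks the AD head-count, total
direct costs grow by the same factor.  On the published Czech inventories,
non-medical costs exceed medical costs at least 4.9-fold (`khk`) and
8.5-fold (`vys`), and the per-person totals decompose additively into their
medical and social components.

The same pipeline is scriptable via the CLI:

```bash
adburden synth --out inputs --seed 1          # write a synthetic bundle
adburden simulate --config inputs/scenario.yaml --out run
adburden costs --config inputs/scenario.yaml --trajectory run/trajectory.csv --out report
adburden report --run report
```

Exit codes: 0 success, 2 schema/validation error, 3 convergence or
calibration failure.

## Layout

- `src/adburden/population.py` — multi-state simulator, incidence
  back-calculation, limit-distribution initialisation
- `src/adburden/costs.py` — medical and social-care cost streams,
  growth index, per-person figures
- `src/adburden/synthetic.py` — seeded generator for all inputs
- `src/adburden/io.py` — CSV/YAML schemas, validation, run manifest, report
- `src/adburden/cli.py` — `adburden` command-line interface
- `src/adburden/data/` — packaged fixtures: published `khk`/`vys` unit-cost
  tables, service inventories and reference cost summaries
- `analysis/` — numbered study drivers; `docs/methods.md` — methods note
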