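# hosplan

Where should a country's hospitals treat what?  `hosplan` allocates hospital
care — split into 30 diagnosis groups, from neoplasms to COPD — over candidate
hospital locations by solving a mixed-integer program that trades off three
things in euros:

* **Quality.** Concentrating a diagnosis group on fewer locations raises each
  site's annual volume, and higher volume improves outcomes.  The
  volume-outcome relation is modeled as a (piecewise-)linear function of the
  number of locations `NL_d` treating group *d*, measured in QALYs per patient
  and monetized at a rate `EQ` (€/QALY):
  `Quality_d = EQ · NP_d · (a_d · NL_d + b_d)`.
* **Accessibility.** Concentration makes patients travel.  Travel is costed
  per hour (`ET`) over round trips and all visits:
  `Travel_d = 2 · ET · NV_d · Σ_{p,q} NPD_{p,d} · Y_{p,q,d} · TT_{p,q}`,
  and each group has a hard one-way cap (45 min for acute care, 120 min
  otherwise).
* **Efficiency.** Operating rooms, wards and intensive-care units at a
  location must reach minimum annual utilization (1248 OR-hours, 3504
  ward-bed-days, 2190 ICU-bed-days) to count as efficiently run.

The solver opens sites (`X_q`), offers groups at sites (`Z_{q,d}`) and assigns
each zip area's demand per group to one site (`Y_{p,q,d}`), maximizing
`Σ_d Quality_d − Travel_d`.  The package is aimed at health-services
researchers who want to run this kind of landscape analysis — and its
what-if variants — without access to the proprietary national inputs: a
seeded synthetic-instance generator emulates the demography, drive times and
registry resource use, while the printed 30-group table ships as package
data.

## Worked example

```python
from hosplan import (GeneratorConfig, make_instance, solve_with_refinement,
                     travel_report, validate_solution)
from hosplan.instance_gen import scaled_extent_km
from hosplan.optimizer import SolveOptions

cfg = GeneratorConfig(n_zips=100, n_sites=20,
                      n_sites_from_population_centers=12,
                      region_extent_km=scaled_extent_km(20), seed=1)
inst = make_instance(cfg)                        # 30 groups, synthetic country
sol, trace = solve_with_refinement(inst, options=SolveOptions(mip_gap=1e-4))

assert validate_solution(inst, sol) == []       # independent feasibility check
for d, g in enumerate(inst.groups):
    if g.vo_category.value in ("high", "none"):
        print(g.vo_category.value, g.name[:30], int(sol.n_locations[d]))
print(travel_report(inst, sol).to_frame().round(2))
```

On this seed the strong volume-outcome groups concentrate onto 1–4 of the 20
candidate sites (e.g. `high Neoplasms 2`, `high Specialized trauma care 1`)
while every zero-slope chronic group (`none Diabetes`, `none Chronic
obstructive pulmonary...`) is offered at all 20 — concentrated complex care,
dispersed chronic care.  The travel report prints patient-visit-weighted
one-way minutes per care class against the everything-open baseline, e.g.

```
          mean_minutes  baseline_minutes  visit_weight
acute            17.50              4.60     1021276.0
chronic          13.31              4.60     8728856.0
elective         15.44              4.60     4268637.0
mixed            16.64              4.60      255320.0
overall          14.30              4.60    14274089.0
```

so chronic patients stay close to home while complex-care patients travel
for quality.

A command-line interface wraps the same pipeline:

```bash
hosplan generate --n-zips 100 --n-sites 20 --seed 1 --out bundle/
hosplan solve  --instance bundle/ --eq 50000 --out solution.json
hosplan sweep  --instance bundle/ --eq 20000,50000,100000 --out sweep/
hosplan report --solution solution.json --instance bundle/
```

## Layout

| module | contents |
| --- | --- |
| `hosplan.domain` | validated model types and the solver-independent feasibility validator |
| `hosplan.calibration` | volume-outcome slopes and piecewise quality functions |
| `hosplan.instance_gen` | synthetic geography/demand/usage generator + packaged group table |
| `hosplan.optimizer` | MILP construction, HiGHS backend, piecewise refinement loop |
| `hosplan.oracle` | exhaustive-enumeration reference for micro instances |
| `hosplan.scenarios` | €/QALY sweeps, travel reports, scenario comparison |
| `hosplan.io` / `hosplan.cli` | CSV/JSON bundle round trips and the CLI |

See `docs/methods.md` for the model, its assumptions and the design choices.
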