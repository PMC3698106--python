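# Methods

## The allocation model

`hosplan` solves a facility-location mixed-integer program over three index
sets: demand zip areas *p*, candidate hospital sites *q*, and diagnosis
groups *d*.  Binary decisions: `X_q` (site open), `Z_{q,d}` (group *d*
offered at *q*) and `Y_{p,q,d}` (zip *p*'s demand for *d* served at *q*).
The objective, in euros per year,

```
max  Σ_d [ EQ · NP_d · (a_d · NL_d + b_d)
           − rt · ET · NV_d · Σ_{p,q} NPD_{p,d} · Y_{p,q,d} · TT_{p,q} / 60 ]
```

with `NL_d = Σ_q Z_{q,d}`, balances monetized volume-outcome quality against
round-trip travel cost.  Constraints:

* **Completeness** — `Σ_q Y_{p,q,d} = 1` for every (p, d): each zip's demand
  for each group is served at exactly one location.  `Y` is binary because
  all of a patient's visits, follow-up included, happen at one location; we
  extend that to whole zips, which keeps the model linear and mirrors how
  demand data are available (zip aggregates, not individuals).
* **Linking** — `Y ≤ Z ≤ X`.  The default formulation links per pair; an
  aggregated big-M variant (`Σ_p Y_{p,q,d} ≤ M·Z_{q,d}`, `Σ_d Z_{q,d} ≤
  M·X_q`, M = 10⁶) describes the same feasible set with a much weaker LP
  relaxation and is kept for formulation-fidelity experiments
  (`linking_mode="big_m"`).
* **Travel caps** — assignments with `TT_{p,q} > maxt_d` are excluded by
  never creating the variable, which both enforces the cap and shrinks the
  model.  If some (p, d) has no admissible site at all, the model reports
  the uncovered pairs *before* any solve.
* **Minimum utilization** — see below.
* **Co-location** — `Z_{q,21} = Z_{q,23}` ties gynecology to obstetric care
  at every site.

A solution certifier (`validate_solution`) re-checks every constraint from
the raw `X/Z/Y` arrays without consulting the solver, and the quality/travel
components stored on a `Solution` are always recomputed from the assignment
by the package's own formulas.

### Utilization semantics

Read literally, "every open site reaches the minimum utilization for every
facility" forces each open hospital to run an efficient operating theatre,
ward *and* ICU — which would forbid the small chronic-care outposts the
model is supposed to discover.  The default mode `conditional` therefore
introduces a facility-present binary `W_{q,f}`:

```
usage_{q,f} ≥ minu_f · W_{q,f}        usage_{q,f} ≤ cap_f · W_{q,f}
```

a facility is either absent (no patient using it may be assigned there) or
efficiently used.  The `literal` mode implements the strict reading and is
exposed for side-by-side comparison; it is a restriction of `conditional`,
so its optimum is never better.  Default minima come from benchmark
operating parameters: OR 65% of 48 wk × 5 d × 8 h = 1248 h/yr; ward 80% of
12 beds × 365 d = 3504 bed-days/yr; ICU 6 beds × 365 d = 2190 bed-days/yr.
Facilities are shared across groups at a site and otherwise uncapacitated.

### Volume-outcome calibration

Quality per patient is a function of how many locations share a group's
national caseload.  The calibration anchors on the best-quantified case in
the literature: concentrating breast-cancer care from 94 hospitals to 15
dedicated centers gains on average 0.5 QALY per patient.  That fixes the
high-category slope at −0.5/79 ≈ −0.00633 QALY/patient per location; the
other categories scale it by fixed ratios (intermediate 50%, low 5%, none
0%).  Intercepts are normalized so quality is zero at the 94-location status
quo — a constant shift that never moves the optimum but makes every quality
figure a gain-versus-today.

Real volume-outcome curves are convex (the first concentration steps gain
most), so the quality function is piecewise linear with default knots at
{1, 15, 40, 94, max_sites}; the knots bracket the location-count range where
optima land.  The default build puts the same slope on every segment; an
optional convex build multiplies the slope of segments at or below the
15-location knee by a configurable factor (default 2) while keeping the
function continuous and anchored at zero.

Because each solve is linear in `NL_d`, the piecewise function is handled by
an outer refinement loop: solve with one active segment per group, check
whether each realized `NL_d` falls inside its active interval, switch to the
containing segment and re-solve otherwise.  The loop stops at a fixed point,
detects revisited segment combinations (cycles), and under a cycle or the
iteration cap (default 10) returns the visited solution with the best *true*
piecewise objective rather than raising.  Segments that share a line with
the previous active segment are treated as converged without a re-solve.

### Solver

Models are emitted as a solver-agnostic `ModelSpec` (objective vector,
sparse equality/inequality blocks, all-binary integrality); the bundled
backend solves it with HiGHS via `scipy.optimize.milp`.  Any MILP engine
that accepts the spec is pluggable.  Defaults: relative MIP gap 10⁻⁶
(10⁻⁹ in optimality-comparison tests, 10⁻⁴ in the landscape experiment,
where the compared quantities are integer location counts far apart).

## Economic parameters

| symbol | meaning | default | rationale |
| --- | --- | --- | --- |
| EQ | euros per QALY | 50 000 | conservative monetization; sweeps use 20k/50k/100k |
| ET | travel cost per hour | 172 | taxi 2.20 €/km at 60 km/h (patient + companion share the cab) + two persons' lost income at 32 000 € / 1600 h each |
| rt | round-trip factor | 2 | out-and-back travel; the companion is folded into ET, not a second multiplier |
| maxt_d | travel cap | 45 / 120 min | legal emergency norm for acute groups; stated willingness-to-travel for the rest |

Travel times are minutes everywhere; the single minutes→hours conversion
happens inside the travel-cost formula.

## The synthetic-instance generator

The real inputs — zip demographics, the national drive-time matrix, registry
resource use — are proprietary, so the generator emulates their statistical
shape, not their geography:

* **Zips.** A clustered spatial process: a few urban cores (default 5)
  attract 75% of zips with 12 km Gaussian scatter, the rest fall uniformly;
  populations are lognormal (σ = 1) rescaled to a 16.5 M national total.
* **Candidate sites.** The first block (default 88 of 150) sits at the
  highest-population zips, standing in for existing hospitals.  The rest
  minimize population-weighted travel (greedy p-median + single-swap local
  search, deterministic tie-breaks).  Because real candidate networks are
  planned under the 45-minute emergency norm, selection is coverage-aware:
  a greedy covered-population phase first guarantees every zip a site within
  `coverage_minutes` (default 45, with a 5-σ noise margin), and the swap
  search only accepts coverage-preserving swaps.
* **Travel times.** Euclidean distance × road detour factor 1.3 at 60 km/h,
  plus truncated-at-zero Gaussian noise (σ = 1.5 min).  Symmetric by
  construction; the model never uses the reverse direction.
* **Demand.** Each group's national caseload is spread over zips
  proportionally to population with largest-remainder rounding, so column
  sums match the admission counts exactly.
* **Resource usage.** Per-patient OR-hours, ward and ICU bed-days drawn from
  uniform ranges conditioned on care class (chronic groups: no OR, no ICU;
  acute groups the largest ICU fractions).  Visits per patient default to
  chronic 8, elective 3, acute 2, mixed 5 — the chronic-care visit burden is
  what makes dispersion pay.
* **Scaling rule.** Scaled-down instances keep the national *site density*
  (~440 km² per candidate site), not the national extent:
  `region_extent_km = sqrt(n_sites × 440)`.  A 20-site desk instance spans
  ~73 km.  Preserving density keeps travel statistics and the 45-minute
  norm comparable across scales.

Everything is deterministic under the config seed.

What the generator does **not** emulate: real road networks and asymmetric
drive times, coastal/border geometry, within-zip heterogeneity of demand,
correlation between group prevalence and demography, and hospital-level case
mix.  Tests passing on synthetic instances therefore validate the
*optimization machinery and its qualitative behavior* (concentration of
high-relation groups, dispersion of chronic care, monotone response to the
QALY price), not the numerical location counts of any real country.

## Desk-scale experiment sizes

The exhaustive oracle cross-checks use micro instances (≤ 8 zips, ≤ 5 sites,
≤ 3 groups) where brute-force enumeration is exact; utilization minima for
those are drawn as 5–35% of total generated usage so they bind without
being trivially infeasible.  The landscape experiment uses 100 zips, 20
candidate sites and the full 30-group table — small enough to solve to a
10⁻⁴ gap in about a minute on one core, large enough for the
concentration/dispersion pattern to emerge.  Micro sensitivity instances use
a 0.02-QALY anchor gain so the quality-travel knee falls inside the swept
EQ range at desk scale (at national demand volumes, any realistic slope
dwarfs travel and the sweep would be flat).

## Numerical choices

* Demand conservation tolerance: 1 patient per group (absorbs integer
  rounding when spreading demand).
* Quality-function continuity at knots: 10⁻⁹ QALY/patient.
* Feasibility certification: utilization tolerance 10⁻⁶ relative; objective
  bookkeeping 10⁻⁶ relative.
* Ties among equidistant sites break toward the lowest site id; the oracle
  breaks objective ties by lexicographic (Z, Y) encoding.  Both make every
  reported solution reproducible bit-for-bit under a fixed seed.
* Degenerate inputs: a single-site instance still builds (one-point quality
  domain); coincident zips trigger site deduplication with a warning; an
  anchor with zero span (94→94) is rejected as degenerate.

## Known limitations

* The zero-slope groups make the offering variables degenerate: any
  superset of the sites actually used is equally optimal, so their reported
  location counts are whatever the solver returns among ties (in practice,
  all sites that reduce travel).
* The refinement loop is a heuristic for the piecewise objective: a fixed
  point is locally consistent but not certified globally optimal across
  segments: the oracle cross-checks therefore use single-segment quality
  functions.
* No economies of scale or scope, no competition/price effects, no
  patient-level choice heterogeneity — the model answers a system-design
  question, not a market-forecast one.
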