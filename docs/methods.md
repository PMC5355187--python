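# Methods

## The model

The central quantity is the credit of ecological interactions of a focal
area with respect to one animal species: the count of plant species present
in the area that are documented interaction partners of that animal. The
package treats an interaction as a binary animal-species × plant-species
link; interaction *richness* is the number of distinct partner species with
at least one realized link, so for a single reintroduced animal species the
cashed credit equals the partner richness observed so far. Rewiring is
permanent: the framework is accumulation-only, links are never removed.
Interaction strengths, network metrics (connectance, nestedness) and
multi-species simultaneous releases are out of scope; run the machinery
once per animal species instead.

## The simulator

The simulator asks how the credit is cashed as a released population grows.
It factors the process into three drivers — population spread, partner
commonness, and the animal's degree (generalist vs. specialist) — and keeps
each as simple as it can be while still producing the expected asymptotic
accumulation:

- **Arena.** A `width × height` grid; each cell independently contains each
  plant species with probability equal to the species' occupancy weight.
  Occupancy, not individual counts, is the representation of abundance:
  what matters to an expanding population is whether a species occurs where
  the population now is. Any species that lands nowhere is force-seeded
  into one uniformly chosen cell, so the realized arena always carries the
  whole pool and the full credit is cashable in every replicate (this makes
  the endpoint deterministic: final richness always equals the partner-set
  degree). Cells hold species sets, so arenas of any size — including a
  single cell — can host the whole pool.
- **Occupancy weights.** Default `lognormal_rank`: weights
  `clip(0.3·exp(1.5·Z), 0.005, 1]` sorted descending, giving a long-tailed
  common/rare structure typical of plant communities (a few near-ubiquitous
  species, many sparse ones). The uniform model is kept as the degenerate
  control (`p = 1` puts every species in every cell).
- **Expansion.** Deterministic von Neumann frontier growth: one ring of
  4-adjacent cells per step from a single release cell (default: arena
  centre), clipped to bounds, idempotent at full occupancy. All
  stochasticity lives in arena composition; expansion geometry is shared by
  every replicate, which makes nested-partner-set comparisons exact (the
  generalist dominates its nested specialist at every step of every
  replicate, not just on average). An optional `lag_steps` holds the
  population at the release cell to mimic slow establishment (Allee
  effects, supplementary feeding); it is a delay, not a demographic model.
- **Rewiring rule.** A partner species is rewired at the first step at
  which any occupied cell contains it.
- **Replication.** Replicate `r` of a run with master seed `s` uses the
  counter-based seed `SeedSequence([s, r])`, so replicates are reproducible
  independently and in any order, and arena composition is independent of
  the partner set under comparison.

Default experiment: 50×50 arena, 1000-species pool, a degree-100 generalist
and a degree-25 specialist nested within it, 100 replicates. Nested
sampling (`nested_within`) guarantees the specialist's partners are a
subset of the generalist's; specialist partner sets carry no bias toward
rare species — whether specialists reach rare partners faster is left as an
empirical question, not baked into the sampling.

Summaries report the per-step mean and the min–max envelope across
replicates (the full range, a "100% band"). The credit ledger derived from
a trajectory enforces conservation (`cashed + remaining = credit0` at every
step) by construction, and the rewiring time is the first step with zero
remaining credit, reported per replicate with its min/median/max (a `None`
sentinel marks replicates that never finish, which can only happen when
`credit0` exceeds the partner-set degree).

## Empirical accounting

- **Credit estimation** is a set intersection after identifier
  canonicalization (trim, collapse internal whitespace, case-fold — applied
  at every ingestion boundary, so spelling-case and spacing variants of a
  species name merge). An empty intersection is a valid, actionable answer
  (little credit: restore the plant community first) and is logged, not
  raised.
- **Accumulation curves** bin first-observation times into fixed-width
  time bins (months since release; default width 1). A species is rewired
  at its first observation of any admitted evidence type
  (`fruit_consumption`, `seed_burial`, `other`); evidence types are
  retained for reporting, and an optional filter restricts which types are
  admitted. Every event is accounted for: eligible-first + repeats +
  unexpected (non-eligible species) + beyond-horizon + evidence-filtered =
  total, with no silent drops. Observed richness is a lower bound on true
  rewiring; no detection-probability correction is applied (no
  occupancy/detection modelling, no rarefaction or Chao-type estimators).
- **Asymptotic fits** are descriptive extrapolations, not inference. Two
  forms: Michaelis–Menten (Clench) `R(t) = a·t/(b+t)` and negative
  exponential `R(t) = a·(1−e^{−kt})`, least-squares on bin midpoints with
  both parameters bounded positive (initial values: `a₀` at the observed
  maximum, time scale at the half-richness time). Degenerate curves (fewer
  than three non-zero bins, or constant) and non-convergence return a
  `NoFit` sentinel with the reason; they never raise. `time_to_fraction(q)`
  inverts the fitted curve; both models attain their asymptote only in the
  limit, so `q = 1` returns `None` rather than a number.
- **Success criterion**: the reintroduction is successful when observed
  cumulative richness reaches an a-priori proportion `p` of the credit.
  Because richness is integer, fractional thresholds round up
  (`ceil(p·C₀)`). A zero credit makes the assessment undefined (nothing to
  cash); the report says so explicitly instead of raising or guessing.

## The synthetic generator

The generator emulates the statistical structure the accounting assumes,
with known truth, so every stage is testable without field data. Eligible
species `i` receives a rank-skewed weight `w_i` (the same lognormal-rank
machinery as the pools module — a single source of truth for common vs.
rare) and is first observed at `onset_i + Exp(λ_i)` with
`λ_i = base_rate · w_i · detection_prob`; repeat observations follow as a
Poisson process at `λ_i`, and unexpected (non-eligible) events arrive at a
small background rate to exercise the eligibility filter. Independent
exponential first-hit times are the simplest process whose expected
distinct-species curve, `Σ_i (1 − e^{−λ_i t})`, is asymptotic.

Default scenario: 300 flora species, 100 reference species, overlap 65,
skew `σ = 1.5`, full detection, 36-month horizon, 23/65 of eligible species
flagged large-seeded. The encounter scale `base_rate = 0.08`/month was set
analytically so that the expected richness at month 15 under these defaults
is ≈ 23 of 65 — the pace of the agouti reintroduction the scenario
emulates, where roughly a third of the credit was cashed in the first 15
months. What the generator does **not** emulate: spatially explicit
telemetry, seasonally varying (non-exponential) encounter hazards,
observer-effort variation, and learning effects in captive-born animals —
so passing tests show the accounting is correct under the assumed encounter
process, not that real monitoring data satisfies those assumptions.

## Numerical and interface choices

- Time is decimal months since release; no date parsing (conversion is the
  caller's job). A bin covers `(start, end]`; an observation exactly at the
  horizon is kept in the last bin.
- Fits use `scipy.optimize.curve_fit` with positive bounds and tight
  default tolerances; noiseless model-generated curves are recovered to
  1e-6.
- File schemas are header-rowed delimited text (comma default,
  configurable); `#` comment lines carry a provenance header (version,
  seed, config hash) in all outputs. Input files are never mutated.
- Problem sizes in the test suite are chosen to keep the whole suite fast
  while leaving Monte-Carlo tolerances at ≥ 4–6 standard errors of the
  corresponding estimator: the distributional redraw oracle uses 2×10⁵
  variates against weights pooled over ten seeds, uniform-draw frequencies
  use 2×10⁴ seeds, and the exponential first-observation oracle uses 300
  seeds with the exact `Exp(1)` normalization `(t − onset)·λ`.

## Known limitations

- Expansion is purely geometric; no births/deaths, home ranges or movement
  beyond frontier growth, so simulated "steps" are population expansions,
  not calendar time, and cannot be compared across arena sizes.
- The empirical curve inherits every bias of the monitoring design
  (effort, detectability, phenology); the package reports observed richness
  as a minimum and leaves corrections to the user.
- The asymptotic fit can exceed the known credit when the curve is far from
  saturation; that is a property of extrapolation, and the credit itself —
  not the fitted asymptote — is the authoritative ceiling.
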