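# Methods

## Model structure and assumptions

The community of three platform-nesting raptor species is modelled as a
single aggregate pool: the species share nest sites, exchange platforms over
the years, and have similar territory sizes, so no per-species or
per-territory structure is kept.  The state is two continuous stocks —
total nests `tn` and occupied nests `on` (= breeding pairs) — and both are
real-valued; integers appear only at the reporting layer.  There is no
demographic structure (survival, fecundity, dispersal) and no spatial nest
placement: habitat enters only as the area of mature forest, and
nest-protection buffers enter only as a scalar reduction of clearcut nest
loss.

Carrying capacity is `moc = mfa / mfap`.  The settlement flow
`onir = anr · or · (tn − on) · cr` encodes three assumptions: settlement
requires unoccupied nests (`tn − on`), is facilitated by established pairs
(conspecific attraction, `or = on/moc`), and saturates as capacity fills
(`anr = (moc − on)/moc`).  The abandonment flow `onar = (on − moc) · cr`
removes surplus pairs when management reduces capacity below occupancy.
Nest construction is proportional to pairs (`nb = on · nbr`), decay is
first-order with mean lifetime `nlf` (`ndr = tn / nlf`), and clearcuts
destroy nests in proportion to the mature area removed (`nlfc = tn · mfcr`,
as an instantaneous pulse).

Two regularisations make these flows well-posed across the whole state
space, not just near the usual operating region:

* The two ratio factors in the settlement flow are evaluated clamped to
  [0, 1].  They are saturating fractions, and without the clamp a state with
  `on > moc` (which every managed scenario starts in) turns the product
  `anr · or` into a large negative number and settlement into an explosive
  sink, crashing the occupancy stock within a single step.  Above capacity,
  settlement is simply zero and relaxation is the abandonment flow's job.
  The `tn − on` factor keeps its sign, so occupancy is still pulled down
  when destruction leaves fewer nests than pairs (while below capacity).
* Abandonment is clamped at zero below capacity; the raw expression would
  otherwise act as a spurious growth term toward `moc` regardless of nest
  availability.
* With no mature forest (`moc = 0`) the occupied and available ratios are
  undefined; settlement is defined as 0 and abandonment as `on · cr` — no
  habitat means no settlement and full abandonment pressure.

Consequences worth knowing: extinction is absorbing (`on = 0` implies
`onir = 0` forever, and `tn` then decays geometrically), occupancy in an
unmanaged run started at or below capacity never exceeds `moc`, and
`on = moc` is a semi-stable point — once at capacity with a mature-forest
surplus, occupancy stays there while any nest deficit persists.  Because
abandonment relaxes occupancy toward capacity on the 1-yr `cr` timescale
while post-disturbance recovery is nest-limited and typically takes 1–3 yr,
window-mean occupancy in the managed scenarios sits close to window-mean
capacity, and *above* it for windows that include the initial above-capacity
transient: the capacity-gap metric is then negative (see the sweep table in
the README).  A strongly positive capacity gap would require settlement much
slower than these flows produce.

The closed-form equilibrium used for initialisation and as an analytic
oracle is `on* = moc`, `tn* = moc · nbr · nlf` (building balances decay at
capacity).  The occupancy stock reaches it quickly; `tn` relaxes on the
20.68-yr nest lifetime, so a colonisation run started from one pair in 1890
is still ≈ 5 % below `tn*` at 2018 — the closed form is the asymptote, not
the 2018 value.

## Parameters

| symbol | meaning | default | units |
|---|---|---|---|
| `nbr` | nest building ratio per pair | 0.14 | 1/yr |
| `nlf` | mean nest life expectancy | 20.68 | yr |
| `mfa` | mature forest area (unmanaged runs) | 10,000 | ha |
| `mfap` | mature forest per breeding pair | 300 | ha/pair |
| `cr` | change ratio (flow relaxation rate) | 1 | 1/yr |
| `protection_factor` | clearcut nest loss avoided under protection | 0.9 | — |
| `maturity_age` | minimum nesting tree age | 34 | yr |

The habitat defaults describe a ~10,000-ha mature Aleppo-pine landscape
supporting ≈ 33 pairs; the turnover parameters come from long-term nest
monitoring of the three species.  None are fitted to simulated output.

## Forest submodel

Forest area is tracked per one-year tree-age class; aging conserves area
exactly (to 1e−6 ha, tested), and mature area is the sum over classes at or
above `maturity_age`.  Two cutting modes:

* **cohort-pulse** (default): every `cut_interval` (10) years, all area at
  or above the rotation age is clearcut in one pulse and replanted at age 0.
  The long-term state is `rotation/interval` even-aged blocks; capacity
  follows a sawtooth (e.g. rotation 70: 3 mature blocks for 4 yr, 4 for
  6 yr, one block cut per decade, `mfcr = 0.25`).  The event's `mfcr` is the
  mature area removed over the mature area before the cut.  Rotation ages
  not divisible by the interval are rejected rather than approximated.
* **smoothed-annual**: an idealised perfectly staggered rotation — each year
  the single oldest cohort (`total/rotation` ha) is cut.  Mature area is
  constant at `total · (rotation − maturity + 1)/rotation` (rotation 40:
  1,750 ha ⇒ 5.8 pairs; rotation 70: 5,286 ha ⇒ 17.6 pairs, 47 % below the
  unmanaged 33.3).

The two modes bracket the plausible mechanics of a decadal cutting schedule.
They differ materially for the rotation-40 scenarios: in pulse mode the
post-cut state has *no* mature forest for 4 years of each decade and every
mature block is cut whole (`mfcr = 1`), so without protection the nest stock
is annihilated and the community goes extinct, while 90 % protection
preserves enough nests for fast recolonisation of each mature window.  In
smoothed mode capacity never reaches zero and the clamped settlement flow
holds occupancy at the (low) capacity, so the extinction outcome does not
occur there.  Cohort-pulse is the default because the pulse dynamics —
sawtooth capacity, post-cut troughs, extinction at rotation 40 and its
rescue by nest protection — are the behaviour the scenario set exists to
study.

Managed scenarios start in 2010 from the rotation's long-term (post-cut)
age structure with the first pulse cut in 2020, occupancy at the unmanaged
capacity (33.33 pairs) and nests at the analytic equilibrium (96.51); both
the first-cut year and the initial distribution are configurable.

## Scenarios

Eleven built-ins: the 1890–2018 colonisation base run (whole area mature,
one pair, one nest); the 1910–2018 reforestation validation run (20,000 ha
all age 1 in 1910, one pair seeded the first year mature forest appears,
1943 by default — the seeding year and amount are configurable, since how
the first pair arrives is outside the model); the 2010–2050 unmanaged
reference started at capacity; and the rotation {40, 50, 60, 70} ×
{protection, no protection} grid.  Scenario configs serialise to YAML/JSON
and a run's JSON snapshot re-produces its trajectory byte-for-byte (the
model has no randomness anywhere).

## Numerics

Explicit Euler with `1/dt` substeps per year; capacity is held constant
within each year at that year's mature area, and cut pulses apply at year
boundaries between continuous steps.  Stocks are clamped at zero with an
instability guard: a negative overshoot beyond 1e−6 of the stock raises an
error advising a smaller `dt` rather than silently hiding stiffness.

The default `dt = 1/256` yr was chosen by a Richardson criterion: halving
`dt` must move no annual value of any built-in scenario by more than 0.1 %
of the trajectory's scale (its maximum occupancy).  The binding case is the
zero-capacity abandonment phase of the rotation-40 scenarios, where annual
decay is `(1 − dt)^(1/dt)` against the exact `e^(−1)`; the discrepancy is
first-order in `dt` and reaches ~0.08 % of scale at `dt = 1/256` (~0.15 %
at 1/128).  The tolerance is measured relative to the trajectory scale, not
each annual value, because during absorbing exponential decay the values
themselves become arbitrarily small and a per-value relative bound would
demand `dt < 1e−3` for no scientific gain.  All runs complete in well under
a second at the default step.

Tie-breaks and degenerate inputs: `carrying_capacity(0, mfap) = 0`;
`mfcr = 0` when no mature area existed before a cut; `time_to_capacity`
skips zero-capacity years (reaching 99 % of nothing is not recovery); the
extinction threshold is 0.5 pairs at the final year — the deterministic
model never reaches exactly zero from a positive state, so "extinct" means
"rounds to zero pairs".  Period means (capacity gap, scenario table) use the
inclusive annual year-start samples of the window (41 samples for
2010–2050); reported standard deviations are across years of the
deterministic series, not across replicates.

## Synthetic observed series

`generate_synthetic_observed` produces integer annual occupied-nest counts:
a logistic rise (or any supplied mean series, e.g. a simulated trajectory)
plus seeded Gaussian jitter, rounded and clipped at zero.  It emulates the
sampling noise of annual territory surveys for exercising the
trajectory-comparison utilities (`compare_to_observed`: RMSE and mean bias
over ≥ 3 overlapping years).  It does not emulate real survey features such
as imperfect detection, observer turnover, or autocorrelated environmental
effects — tests passing against it show the comparison plumbing is correct,
not that the model fits any particular field dataset.

## Known limitations

* The community-pool abstraction ignores interspecific competition beyond
  shared capacity, and all demographic detail.
* Clearcutting is assumed not to alter habitat quality, only mature area;
  protection is a scalar loss reduction with no buffer geometry.
* No stochastic disturbances (storms, fire, disease) — heavy snowfall, for
  instance, is known to destroy platforms in these forests.
* The settlement clamp makes `on = moc` semi-stable, so smoothed-annual
  runs cannot lose occupancy through nest starvation alone while at
  capacity; conclusions about marginal persistence should use the
  cohort-pulse mode.
* Whole-window means are sensitive to the above-capacity initial transient
  of the managed scenarios; compare windows starting after the first cut if
  that transient is not of interest.
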