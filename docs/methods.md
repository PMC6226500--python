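# Methods

## The problem

Large-scale latitudinal richness gradients are assembled by overlapping the
recorded geographic ranges of many species. When sampling effort is uneven
across latitude, the absence of a species from a poorly sampled band may be an
artefact rather than a true absence, and the assembled gradient inherits that
bias. `latgaps` quantifies this for marine occurrence data on a single
latitudinal axis: it detects *spatial gaps* — bands lying strictly inside a
species' recorded latitudinal extent that contain no record of that species —
and tallies them per band as *missing species richness*, alongside sampling
effort and two inventory-completeness estimates.

The central assumption is **range contiguity**: at the scale of latitudinal
bands, a species' true latitudinal distribution is taken to be a single
interval. Under that assumption an interior unoccupied band flags an
artefactual absence. The assumption is conservative in one direction — the
statistic never extrapolates beyond the recorded extremes, so absences at or
beyond a species' recorded range edges are invisible to it ("edge
truncation"). The synthetic-data recovery report quantifies, rather than
corrects, that blind spot.

## Quality control

Occurrence tables (Darwin-Core-like columns) pass through a fixed, audited
filter order: (1) drop records without coordinates; (2) drop coordinates equal
to (0, 0); (3) drop on-land records via a pluggable land-mask predicate (a
buffered coastline is not bundled; without a mask the step is skipped and
logged); (4) round coordinates to two decimals, half away from zero — rounding
precedes deduplication so that near-identical coordinates collapse into a
single sampling event; (5) keep only species- and subspecies-rank records,
collapsing subspecies to the binomial; (6) resolve names against a
user-supplied status table (synonyms mapped to accepted names;
invalid/fossil/non-marine dropped; unknown names dropped under their own
rule); (7) drop latitudes outside [−80°, 85°] (bounds inclusive — the
exclusions are the Antarctic continent and the Arctic ice cap beyond them);
(8) deduplicate on (species, latitude, longitude, date), keeping undated
records only when their (species, latitude, longitude) is otherwise unique.
Every removal is counted in a report satisfying
`n_input − Σ removed = n_output`, and the whole procedure is idempotent.
Negative sample depths are set to missing (warned, not dropped).

## Binning and effort

Latitude is discretised into equal-width bands, half-open `[low, high)` with
the topmost band closed, defaulting to 5° bands from −80° to 85° (33 bands).
A *sampling event* is a distinct (latitude, longitude, date) triple among the
band's records; undated records form one event key per coordinate pair —
quality control guarantees at most one undated record per (species, lat, lon),
and merging undated with dated keys would undercount effort.

## Gap statistic

For each species, presence per band is derived from record counts; the gaps
are the unoccupied bands strictly between the lowest and highest occupied
bands. Per band, `observed[b]` counts species present and `missing[b]` counts
species whose extent spans `b` without occupying it. Species observed in a
single band contribute no gaps. The implementation (a vectorised
forward/backward cumulative-maximum) is tested for exact agreement with
brute-force enumeration over all occupancy vectors up to length 12.

## Inventory completeness

**Sample coverage** uses the record count `n` and singleton/doubleton counts
`f1`, `f2` within a band:

    Ĉ = 1 − (f1/n) · ( (n−1) f1 / ( (n−1) f1 + 2 f2 ) )

with Ĉ = 1 when `f1 = 0`, Ĉ = 0 when `n = 1`, undefined when `n = 0`.
Records are treated as individuals (occurrence rows are the only specimen
proxy); an incidence-frequency variant using events as sampling units would
also be defensible, and the choice is isolated in `BandIncidence`.

**SAC curvilinearity** builds the expected species accumulation curve over
random orderings of the band's sampling events (Monte-Carlo, default 100
permutations, mandatory seed, bit-for-bit reproducible; an exhaustive mode
covers ≤ 8 events and serves as the convergence reference). Completeness is
`1 − slope` of the final 10% of the curve, clamped to [0, 1]: a saturated
curve scores 1, a curve still gaining one species per event scores 0. The
mapping is a stated convention — the tail slope of an expected curve near
saturation naturally lies in [0, 1] species/event. Because only the final 10%
is used, the estimate is computed only for bands with **more than 40
sampling events**; elsewhere it is NaN, and NaN propagates through
aggregation rather than being coerced to zero.

## Depth strata

Records are partitioned into euphotic (0–200 m), bathyal (200–2000 m) and
abyssal (2000–6500 m) strata; printed interval ends are touching, so boundary
ownership had to be chosen: boundaries belong to the deeper stratum, the
abyssal top is closed, and deeper-than-6500 m or unresolvable depths are
`unassigned`. Records lacking a sample depth fall back to the seafloor depth
at their coordinates (nearest node of a user-supplied bathymetry grid) when
the species is benthic; pelagic species stay unassigned because their
sampling depth need not reflect the bottom. The per-stratum pipeline recomputes
gap profiles from each stratum's own records, so a species contiguous overall
may legitimately be disjunct within one stratum.

## Synthetic worlds

The generator realises the null world under which every detected gap is an
artefact: per-species true ranges are single latitude intervals (midpoints
uniform over [−70°, 75°], or normal around the equator, sd 25°, for a
unimodal-tropical richness shape; widths lognormal with median 20°, log-sd
0.6), clipped to the grid. Sampling draws Poisson numbers of events per band
from an effort profile (uniform, or a bimodal preset with mid-latitude peaks
— the northern roughly twice the southern — and an equatorial trough), places
each event uniformly within its band with longitude in [−170°, 170°) and a
uniform date in 1950–2015, and records each truly present species at each
event with detection probability 0.1 (per-species probabilities are
supported). Species are benthic with probability 0.7 and carry log-uniform
depth intervals; record depths are missing at rate 0.2. Noise injection
appends the five quality-control violation classes (zero coordinates,
out-of-bounds latitudes, rows on a toy continent at lon ≥ 170°, exact
duplicates, date-stripped duplicates) at 1% each by default.

What the generator does **not** emulate: longitudinal range structure,
species-abundance heterogeneity (detection is exchangeable across species
unless per-species probabilities are given), temporal trends in effort, and
spatially autocorrelated event placement. Passing recovery tests therefore
show that the pipeline is unbiased under the contiguity-plus-uniform-detection
model, not that real OBIS data meet those conditions.

A small boundary effect is accepted as realistic: coordinate rounding to two
decimals can move a record across a band edge (≤ 0.005° ≈ 0.1% of a 5° band),
so observed richness can exceed true richness by a species or two per band.
Recovery comparisons therefore use the observed-vs-true deficit per belt
rather than raw between-belt observed richness, which is also dominated by
each realised world's stochastic between-belt richness differences.

## Virtual-ecologist studies

Two canned experiments (used by the test suite and the acceptance script)
fix the study conditions:

* **Null world** — 500 species, uniform richness shape, uniform effort of
  1350 events/band, detection 0.1. Missing richness should be a negligible
  fraction of true richness in every band.
* **Tropical undersampling** — the same worlds with effort divided by 30
  across the tropical belt (the ten bands spanning −25° to 25°), leaving ~45
  events per tropical band. This level keeps the SAC estimate defined there
  (> 40 events) while giving each present species a ~1% chance of going
  unrecorded per band, so the artefactual pattern — observed-richness
  deficit, missing-richness peak, depressed completeness by both estimators —
  appears at a measurable rate. A shallower cut starting from 500 events/band
  would push tropical bands below the SAC threshold and make the completeness
  comparison vacuous.

Both experiments run the full pipeline (simulation → quality control →
binning → gaps → completeness), not shortcuts around it.

## Aggregation

Per-group curves are standardised by their own maximum to [0, 1] (all-zero
curves are returned unchanged with a warning) and averaged across groups with
a population (denominator *n*) standard deviation; the n/n−1 choice is fixed
here for reproducibility. Bands where a metric is undefined for a group are
excluded from that band's mean. The resolution sweep re-runs the completeness
pipeline at several band widths; each width must divide the grid span exactly
(so 10° is invalid on the default 165° span, while 5°, 15°, 33° and 55° are
valid), and on synthetic data mean completeness at 15° is at least that at 5°,
since coarser bands pool effort.

## Numerical choices

* Coordinate rounding: half away from zero, deterministic across platforms.
* Band assignment by `searchsorted` on exact edges: no floating-point epsilon,
  `[low, high)` convention, top band closed.
* Per-band Monte-Carlo seeds are spawned from a single seed via
  `numpy.random.SeedSequence`, so band results are independent and the whole
  table is reproducible from one integer.
* Undefined values are NaN throughout, never 0 or sentinel numbers.
* Degenerate inputs: empty record sets yield all-zero effort and empty
  occupancy; all-false presence rows are rejected by the per-species profile
  but tolerated (as "no extent") in matrix-level statistics aligned to a
  ground-truth species list.

## Problem sizes

Default test and acceptance runs use 500-species worlds (~350k records per
simulated dataset), 50 seeds per study in the test suite and 20 in the
acceptance script, and 100 SAC permutations per band; these sizes give stable
pass-rate estimates while a full run of the simulation studies completes in a
few minutes on one core.

## Known limitations

* Gaps are latitudinal only; a longitudinally disjunct species with a
  contiguous latitudinal span shows no gap.
* Edge truncation: absences outside the recorded extremes are not counted,
  so missing richness is a lower bound under contiguity.
* Completeness at coarse band widths is optimistic; the sweep quantifies the
  resolution dependence but cannot remove it.
* The name-resolution step only applies a user-supplied table; no fuzzy
  matching or live registry lookup.
* The seafloor-depth fallback assumes benthic records were collected at the
  bottom and a nearest-node bathymetry lookup; steep slopes between grid
  nodes will misassign some records.
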