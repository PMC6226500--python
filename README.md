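# latgaps

Latitudinal gap detection and inventory completeness for marine species
occurrence records.

## What it does, and for whom

Latitudinal richness gradients are built by stacking the recorded ranges of
thousands of species, so uneven sampling effort across latitude leaks
directly into the gradient: a species absent from a poorly sampled band may
simply not have been looked for there. `latgaps` is for macroecologists and
biodiversity-informatics practitioners working with occurrence tables
(OBIS/GBIF-style Darwin Core exports) who want to ask: *how much of the
latitudinal pattern is signal, and how much is missing data?*

The package cleans occurrence records, bins them into latitudinal bands, and
computes three families of quantities per band:

* **Observed and missing species richness.** Assuming each species' true
  latitudinal range is contiguous, any band lying strictly between a
  species' lowest and highest recorded bands that holds no record of it is a
  *spatial gap* — an artefactual absence. `missing[b]` counts the species
  with a gap at band `b`.
* **Sampling effort**: the number of sampling events, i.e. distinct
  (latitude, longitude, date) combinations.
* **Inventory completeness**, by two estimators in [0, 1]: *sample
  coverage*, from the record count *n* and singleton/doubleton counts
  *f₁*, *f₂*,

      Ĉ = 1 − (f₁/n) · ( (n−1) f₁ / ( (n−1) f₁ + 2 f₂ ) ),

  and *SAC curvilinearity*, 1 minus the mean slope of the final 10% of the
  expected species accumulation curve over random event orderings (only for
  bands with more than 40 events).

A depth module repeats the analysis within euphotic (0–200 m), bathyal
(200–2000 m) and abyssal (2000–6500 m) strata, with a seafloor-depth
fallback for benthic species. A synthetic-data module generates worlds with
known contiguous ranges and a configurable latitudinal effort profile, so
the whole pipeline can be validated against ground truth — including the
central causal question: does an equatorial effort trough alone manufacture
a tropical dip in observed richness and a matching peak of missing species?

See `docs/methods.md` for the model, assumptions and numerical choices.

## Worked example

Simulate a 300-species world with contiguous ranges, uniform effort of 1350
events per 5° band cut 30-fold across the tropics, 1% noise of each
quality-control violation class, then run the pipeline:

```python
from latgaps import *

world = make_world(WorldConfig(n_species=300, seed=42))
effort = EffortProfile.uniform(1350, world.grid).with_equatorial_trough(30)
records = simulate_records(world, effort, DetectionModel(p=0.1),
                           seed=43, noise=NoiseConfig())
clean, report = apply_qc(records, NameStatusTable.accept_all(world.species),
                         land_mask=toy_land_mask)
print(report)
```

```
QC report: 162555 records in, 154815 out
  missing_coordinates      -0
  zero_coordinates         -1548
  on_land                  -1548
  rank_above_species       -0
  name_unresolved          -0
  name_invalid             -0
  latitude_out_of_bounds   -1548
  duplicate_records        -3096
```

Each injected violation class is removed by its own rule (the date-stripped
and exact duplicates both land in deduplication), and the counts reconcile:
162 555 − 7740 = 154 815.

```python
grid = world.grid
occ = build_occupancy(clean, grid)
vec = richness_vectors(occ)
n_gap, frac = gap_species_summary(occ)
print(f"{n_gap} of {occ.n_species} species ({100*frac:.2f}%) show a latitudinal gap")
eq = grid.band_index(2.5)
print("equatorial band observed/missing:", vec.observed[eq], vec.missing[eq])
```

```
9 of 300 species (3.00%) show a latitudinal gap
equatorial band observed/missing: 56 2
```

Every one of those gaps is artefactual — the generator built contiguous
ranges — and they cluster in the undersampled tropics. Completeness shows
the same signature (the equatorial band here drew only 40 events, so its SAC
estimate is undefined by the > 40-event rule):

```python
comp = completeness_table(clean, grid, n_perm=100, seed=44)
print(comp.loc[[15, 16, 17, 26],
               ["lat_low", "lat_high", "n_events", "f1", "f2", "coverage", "sac"]])
```

```
 lat_low  lat_high  n_events  f1  f2  coverage    sac
    -5.0       0.0        42   2   7  0.991871 0.9325
     0.0       5.0        40   5  10  0.978357    NaN
     5.0      10.0        43   3   7  0.988492 0.8925
    50.0      55.0      1394   0   0  1.000000 1.0000
```

Because the world is synthetic, recovery against ground truth is available:

```python
rep = recovery_report(world, build_occupancy(clean, grid, species=world.species))
print("capture fraction:", round(rep.capture_fraction, 3))
```

```
capture fraction: 0.818
```

— 82% of the truly-present-but-unrecorded (species, band) pairs are flagged
by the gap statistic; the remainder sit at range edges, where the statistic
is blind by design.

The same pipeline is available as a CLI (`latgaps qc | bin | gaps |
completeness | strata | simulate | aggregate | sweep`); every subcommand
writes CSV outputs plus a `manifest.json` recording parameters and seeds.

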