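# dispersalkit

How fast do free-living microbes move into surface soil, and how far do they
travel?  `dispersalkit` answers both questions from glass-slide "microbial
trap" experiments laid out along transects spanning two adjacent ecosystems
(a shrubland and a grassland):

* **Rate.** Sterile slides open to dispersal accumulate cells; slides
  inoculated with a known community and closed to dispersal lose them.
  Under the immigration–death model

  dN/dt = I − δN,  N(0) = 0  ⇒  N(t) = (I/δ)(1 − e^(−δt)),

  the closed slides give the community death rate δ (the negated OLS slope
  of ln cells vs. day), and with δ fixed the open-slide counts give the
  immigration rate *I* in cells · cm⁻² · day⁻¹ in closed form, since
  ln N(t) = ln I + ln[(1 − e^(−δt))/δ] + ε.  An ANCOVA tests whether death
  slopes differ between ecosystems.

* **Distance.** The composition of microbes landing in each trap is compared
  (Bray–Curtis) against the plant composition within circles of increasing
  radius around the trap, computed from a labelled polygon map plus an
  average grass composition for unmapped ground.  A partial Mantel test
  (controlling for geographic distance) at each of 11 radii from 0.1 to 4 m
  locates the spatial scale of dispersal limitation: the radius with the
  strongest correlation.  PERMANOVA and PERMDISP (implemented from first
  principles on the distance matrix, with exhaustive-enumeration modes for
  small designs) compare trap communities between ecosystems.

A synthetic-data module generates landscapes, trap communities, and
cell-count series with known ground truth (true *I*, δ, and influence
radius), so every estimator has a recovery test.

## Worked example

```python
import dispersalkit as dk

# --- rate: death from closed slides, immigration from open slides --------
closed = dk.simulate_cell_counts(
    dk.KineticsSimConfig(noise_cv=0.5, slides_per_timepoint=9, seed=21), "closed")
death = dk.fit_death_rate(closed)
print(death.summary())

open_s = dk.simulate_cell_counts(dk.KineticsSimConfig(noise_cv=0.5, seed=22), "open")
imm = dk.fit_immigration_rate(open_s, delta=death.delta_per_day)
print(imm.summary())
print(dk.immigration_fraction_of_source(imm.immigration_I, 2.8e6), "% of litter")
```

```
Death-rate regression: ln(cells/cm2) ~ day  [closed slides]
  group            : all ecosystems pooled
  n points         : 36
  slope (1/day)    : -0.02799 (SE 0.00444)
  delta (1/day)    : 0.02799
  % dying per day  : 2.76
  ...
Immigration-death fit: N(t) = (I/delta)(1 - exp(-delta t))  [open slides]
  n points            : 96
  delta (fixed, 1/day): 0.02799
  I (cells/cm2/day)   : 1117.1 (SE 59.5)
  plateau I/delta     : 39911 cells/cm2
  ...
0.04 % of litter
```

About 2.8% of cells on the surface die per day; roughly a thousand cells
arrive per cm² per day — only ~0.04% of the density a cm² of leaf litter
holds, far too few for immigration to homogenise the community (no mass
effects).

```python
# --- distance: where does vegetation predict the arriving community? -----
pmap, locs = dk.generate_landscape(dk.LandscapeConfig(seed=23))
profiles = dk.default_source_profiles(
    pmap.categories + pmap.grass_background.categories, seed=24)
table = dk.simulate_trap_communities(
    pmap, locs, profiles, dk.TrapSimConfig(influence_radius_m=1.0, seed=25))
dm = dk.bray_curtis(dk.relative_abundance(table))
scan = dk.radius_scan(pmap, locs, dm, permutations=199, seed=28)
print(scan.to_frame().round(3))
print("argmax radius:", round(scan.argmax_radius_m, 3), "m")
```

```
 radius_m     r  p_value
    0.100 0.651    0.005
    ...
    0.632 0.801    0.005
    0.915 0.856    0.005
    1.323 0.723    0.005
    1.913 0.344    0.005
    ...
argmax radius: 0.915 m
```

The traps were simulated with a true influence radius of 1 m; the partial
Mantel correlation peaks at the 0.915 m grid point — the scan recovers a
meter-scale signature of dispersal limitation.

## Command line

```sh
dispersalkit simulate --outdir demo --seed 1
dispersalkit fit-kinetics --counts demo/cell_counts.tsv --out demo/kinetics.json
dispersalkit permanova --table demo/trap_taxa.tsv --meta demo/sample_metadata.tsv \
    --group ecosystem --permutations 999 --seed 1
dispersalkit scale-scan --map demo/landscape.geojson --meta demo/sample_metadata.tsv \
    --distances demo/bray_curtis.tsv --radii 0.1:4:11 --out demo/scan.tsv
dispersalkit run --outdir demo_run --seed 1   # full pipeline + manifest.json
```

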