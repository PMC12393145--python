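# Methods

## Immigration–death kinetics

Cells land on a trap at rate *I* (cells · cm⁻² · day⁻¹) and die at
per-capita rate δ (day⁻¹); the traps provide no nutrients, so growth is
ignored.  The density on an initially sterile open slide follows

    dN/dt = I − δN,  N(0) = 0  ⇒  N(t) = (I/δ)(1 − e^(−δt)),

which rises monotonically to the plateau I/δ and degenerates to N = I·t as
δ → 0.  Closed slides carry an inoculum N₀ and receive no immigrants, so
N(t) = N₀·e^(−δt).

**Death rate.**  δ is the negated slope of an ordinary least-squares fit of
ln(cells) on day across all closed slides pooled — the landscape-average
death rate; per-ecosystem fits exist but are used only for the homogeneity
test.  The ln scale matches the multiplicative (lognormal) measurement
error of cell counting.  δ is reported both as a rate constant and as the
discrete-time fraction dying per day, d = (1 − e^(−δ))·100 %, whose inverse
reproduces δ exactly.

**Slope homogeneity (ANCOVA).**  `ln(cells) ~ day + group + day:group` is
fitted by least squares and the interaction is F-tested against the
additive model.  If the additive model already fits to numerical precision
(zero residual sum of squares up to rounding), the interaction F is
reported as 0 with p = 1 rather than a 0/0 artefact.

**Immigration rate.**  With δ fixed from the closed slides, the open-slide
model is linear in *I* on the ln scale:

    ln N(t) = ln I + ln[(1 − e^(−δt))/δ] + ε,

so ln *I* is estimated as the mean offset, and Î = exp(mean).  Its standard
error is the delta-method transform Î · se(ln Î), with se(ln Î) the
standard error of the mean offset; this choice is recorded in the output
metadata.  Day-0 records are excluded (the model value is 0 and its log
undefined).  A property test verifies the closed form against a grid-search
least-squares minimiser over *I*.

## Community comparisons

Bray–Curtis dissimilarity BC(x, y) = Σ|xᵢ − yᵢ| / Σ(xᵢ + yᵢ) is computed
on relative abundances (no rarefaction by default; a seeded `rarefy` is
available).  Distance matrices are scikit-bio `DistanceMatrix` objects.

**PERMANOVA** computes the pseudo-F directly from the distance matrix:
SS_total = Σ_{i<j} d²ᵢⱼ / n, SS_within = Σ_groups Σ_{i<j∈g} d²ᵢⱼ / n_g,
F = (SS_between/(a−1)) / (SS_within/(n−a)).  This Gower-centred form is
valid for arbitrary, possibly semimetric, dissimilarities.  The reported
variance explained is SS_between/SS_total.

**PERMDISP** embeds the samples by principal coordinates (double-centring
−½D², eigendecomposition), keeps only positive-eigenvalue axes (negative
eigenvalues from semimetric input are reported, never silently dropped, but
excluded from centroid geometry — the simplest defensible convention,
recorded here), measures each sample's Euclidean distance to its group
centroid, and F-tests the group effect on those distances.  The null
permutes group labels over the fixed distances.

**Permutation conventions.**  Labels are shuffled with a seeded NumPy
generator; p = (1 + #{F* ≥ F}) / (1 + n_perm), so p is never exactly 0 and
never below 1/(n_perm+1); default n_perm = 999.  For tiny designs,
`permutations="exhaustive"` enumerates every distinct label arrangement
(identity included) and returns the exact fraction — the mode the test
suite checks against brute-force enumeration oracles.

## Plant composition and the radius scan

The landscape is a rectangle split by a vertical ecosystem boundary, with
labelled patches (shrub, forb, bare soil) and grass as the implicit
background of unmapped ground, described by a fixed average grass
composition.  Plant composition within radius ρ of a point is the vector of
patch-category intersection areas with the circle (clipped to the domain),
normalised by the circle-within-domain area, with the unmapped residual
split across grass categories by the average grass composition.  Circles
are 256-vertex polygons, so every intersection is an exact polygonal area;
the relative area error is below 1e-4.  Compositions are exactly invariant
under rigid translation of map and point together; under rotation they
agree only to the discretisation accuracy (~1e-4 relative), because the
circle polygon is rebuilt axis-anchored — tests check 1e-9 for translation
and 1e-3 for rotation.

**Mantel machinery.**  Mantel r is the Pearson correlation of the
strictly-lower-triangle entries of two aligned distance matrices; the
partial variant correlates the OLS residuals of each triangle on the
control (geographic) triangle (residual method).  The null permutes the
focal (microbial) matrix's rows and columns jointly and re-residualises;
p-values are one-sided for positive association with the add-one rule.
Degenerate control: the residualising design falls back to mean-centring
when the control triangle is constant (partial r then equals simple r), and
if a residual vector is numerically constant — e.g. the focal matrix equals
the control — the partial r is defined as 0 rather than raising, matching
the self-control limit.

**Radius scan.**  Default grid: 11 log-spaced radii from 0.1 to 4 m (the
spacing is a package choice; the range and count follow the transect design
scale).  For each radius the scan builds the plant Bray–Curtis matrix and
runs the partial Mantel test against the microbial matrix controlling for
trap geography; per-radius permutation streams are spawned independently
from the scan seed, so the scan is reproducible and radii are independent.
A radius where every trap sees an identical plant composition is flagged
degenerate and excluded from the argmax (not fatal).  Raw per-radius
p-values are reported; a Holm step-down adjuster is available for
family-wise control across the grid.

## Synthetic data: what it emulates, and what it does not

The generator mirrors the emulated field design: a 40 × 30 m domain,
boundary at x = 20 m, three transects, traps at ±1, ±3, ±7, ±15 m from the
boundary (24 traps), collections at days 7, 14, 28, 56; 24 open slides per
collection (96 total) and 9 closed slides per collection at ±7 m (36, close
to the deployed 35); immigration 1060 cells · cm⁻² · day⁻¹ and death rate
0.02799 day⁻¹ (2.76 %/day) as generating truth; lognormal count noise with
unit median and CV 0.5 — a realistic error level for field flow-cytometry
counts.  The closed-slide inoculum N₀ (default 5 × 10⁴ cells/cm²) is a free
parameter, as litter-extract densities are protocol-dependent.

Landscape patches are gamma-radius discs (shape 6, mean 1 m for shrubs,
scaled 0.3×/0.5× for forbs/bare) placed by Poisson processes — shrubs only
west of the boundary (density 0.12 m⁻², ≈40 % cover, shrubland-like),
forbs and bare soil on both sides — each clipped to its half and against
earlier patches.  Trap communities mix per-category Dirichlet source
profiles (60 taxa, concentration 0.3 — sparse, low-overlap sources) by the
plant cover within the true influence radius (default 1 m), plus a 30 %
ambient background; counts are multinomial at 10,000 reads with mild
Dirichlet overdispersion (concentration 200), a typical post-QC amplicon
depth and noise level.

Not emulated: physical transport (wind/rain) mechanics — the
influence-radius mixture is phenomenological; taxon-specific death or
immigration rates; temporal turnover of sources; sequencing artefacts
(chimeras, contamination).  Passing recovery tests therefore show the
estimators are correct for data generated by this model, not that field
data meet its assumptions (e.g. time-invariant *I* and δ, lognormal errors,
a single well-defined influence radius).

## Numerical and design choices

* Fits and simulations use `numpy.random.default_rng`; one top-level seed
  spawns per-stage substreams (`SeedSequence`), all below 2³¹.
* Exhaustive permutation modes are guarded to small n (n ≤ 8–9) where
  enumeration is exact and cheap.
* Simulation-based tests use replicate counts (100–500) and permutation
  counts (199) chosen to keep Monte-Carlo error well inside the asserted
  bands; the acceptance script averages 100 kinetics replicates and 20
  scan replicates, enough for the means and median to stabilise.
* PERMANOVA/PERMDISP with a perfectly separated, zero-within-variance
  design report F = ∞ and the minimal attainable p over arrangements.
* TSV is the single tabular dialect (UTF-8, "." decimal), GeoJSON the
  single geometry dialect; writers emit deterministic column orders so
  equal seeds give byte-identical artifacts.

## Known limitations

* The immigration SE reflects ln-scale regression error only; it does not
  propagate uncertainty in the plugged-in δ.
* PERMDISP uses centroids, not spatial medians, and drops
  negative-eigenvalue axes from centroid distances; with strongly
  non-Euclidean dissimilarities this can differ from median-based
  implementations.
* The partial Mantel permutation scheme is the common residual/raw-focal
  relabelling; alternative schemes (e.g. residual permutation of the
  control) are out of scope.
* Planar coordinates only — appropriate for study extents of tens of
  meters, not geographic scales.
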