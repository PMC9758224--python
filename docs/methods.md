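# Methods

## Model and assumptions

The package couples three components: (i) an Arrhenius–Boltzmann model
of routine metabolic rate, (ii) a climatological description of coastal
sea-surface temperature with additive delta-method downscaling of
climate-model futures, and (iii) a stay/relocate habitat projection
driven by the metabolic rate range (MRR).

**Metabolic rate.** `B = b0 · M^a · exp(−E/(K·T))` with mass exponent
`a = 3/4`, Boltzmann constant `K = 8.617×10⁻⁵ eV/K` and temperature in
kelvin (`T = T_°C + 273.15` everywhere). `b0` is a multiplicative
normalization; its units fix the rate units, which the package treats
as opaque and reports as log10 for display. The central modelling
assumption is that the activation energy `E` is *not* a taxonomic
constant: it varies between species, between subpopulations, and with
the thermal envelope a population is acclimated to, which is what lets
a population compensate for warming by adjusting `E`.

**E estimation.** Ordinary least squares (model I) of `ln(rate)` on
`1/T_K`; `E = −slope·K`. The two-parameter line is solved in closed
form from the normal equations; the slope's two-sided p-value uses the
t distribution with `n−2` degrees of freedom. Fits need ≥ 3
measurements at ≥ 2 distinct temperatures and are reported regardless
of significance — survey tables legitimately retain non-significant
entries. `scipy.stats.linregress` serves as an independent cross-check
in the test suite, never as the implementation.

**MRR.** `MRR = B(T_max) − B(T_min)` at a fixed reference mass
(default 10 g), where `T_min`/`T_max` are a cell's climatological
monthly extremes. MRR is used as a proxy for aerobic scope because no
established closed form predicts maximum metabolic rate as a function
of temperature. MRR computed over consecutive equal-width temperature
windows grows with temperature whenever `B` is convex in `T`, i.e. when
`E > 2KT`; on 0–40 °C this holds for all `E ≥ 0.1 eV` and fails at
`E = 0.01 eV`, which is the documented exception to the monotonicity
property.

**Thermal envelopes.** A cell's extremes are snapped to the 5 °C
acclimation lattice: each endpoint rounds to the nearest multiple of 5
(ties upward) and clamps to [5, 30]; a degenerate pair widens downward
one step (upward at the floor) so cells with tiny seasonal range remain
modellable. Envelope subsetting of the acclimation data is inclusive of
endpoints. Measurements taken at the 33 °C end of the acclimation array
are folded into envelopes capped at 30 °C (configurable off): the warm
assay belongs to the warmest envelope and discarding it would waste the
only above-30° information. The north/south subpopulation cline
defaults to 40° N (cells at the cline count as north) and is a
parameter so the 39–41° N hybrid-zone sensitivity can be probed.

## Climate fields

Monthly climatologies pool all days of a calendar month across years
into one arithmetic mean (both Gregorian and 365-day calendars
acceptable; membership is by calendar month). Masked cells carry NaN in
every month — never a silent zero — and no operation ever unmasks a
cell. Coarsening takes cos(latitude)-weighted block means, ignoring
masked children; a coarse cell is masked only when all children are.
The habitat depth band is the closed interval [0, 10] m on
positive-down bathymetry; land (depth ≤ 0) is never habitat.

**Downscaling.** Per month, the coarse-model delta (future − historical
climatology) is interpolated to the baseline cell centers with an exact
thin-plate spline (`r²·log r` kernel plus affine polynomial, zero
smoothing — interpolation, not smoothing, is wanted) and added to the
baseline. Exactness gives two useful invariants used throughout the
tests: a zero delta returns the baseline bit-for-bit (within 1e-12) and
any affine delta is reproduced exactly at all fine centers. A smoothing
parameter is exposed but off by default. Spline coordinates are plain
(lat, lon) degrees; over a coastal domain a few degrees wide the
anisotropy of a degree of longitude is absorbed by the spline fit
itself. Collinear node configurations are rejected up front by a rank
check on the affine design matrix.

## Habitat projection

Conditions are evaluated in order; all boundary equalities
(`T_max,fut = 32 °C`, `MRR_fut = MRR_now`) resolve in favor of staying —
the stay rules use ≤/≥ comparisons, the move rule strict ones. The
three conditions are jointly exhaustive (verified by case analysis and
an internal consistency error). Relocation compares a candidate
refuge's *future* MRR against the mover's *contemporary* MRR — the
population seeks a habitat no more metabolically demanding than the one
it is currently adapted to — and additionally requires the refuge's
future T_max to be at or below the break; the alternative reading
(compare against the mover's future MRR) is available behind
`PIBCMConfig.refuge_reference`. Distance is haversine on a 6371 km
sphere between cell centers, ties broken toward lower latitude then
lower longitude. Refuge candidates are the cells with defined
physiological state (the contemporary habitat mask), not arbitrary
ocean cells.

Movers are processed in deterministic (lat, lon) ascending order.
Probability is conserved exactly through the transfer step (input total
minus stranded mass, asserted to 1e-12); the cap at 1 is applied once
after all transfers, never cascaded, and the discarded overflow is
recorded per cell. Stranded populations (no qualifying refuge) are
zeroed and reported — the model offers no basis for keeping a
population in a cell it has classified uninhabitable.

## RES baseline

The comparison model is a single-variable trapezoidal suitability in
SST: 0 at/outside the absolute envelope, 1 inside the preferred
envelope, linear ramps between; a zero-width ramp takes the preferred
value at the shared point. The packaged killifish envelope is
(5.63, 7.74, 21.97, 27.05) °C. The multi-variable geometric-mean
machinery of full AquaMaps (salinity, ice, productivity, distance to
coast) is out of scope; SST is the single driver. Suitability is
evaluated on the annual mean of the 12 monthly layers.

## Synthetic data

The generator produces every external input the pipeline reads, with
the structure the method assumes rather than oceanographic realism:

* **Rates**: `ln(rate) = ln_A0 − E/(K·T) + ε`, `ε ~ N(0, σ²)` —
  multiplicative lognormal noise is additive on the fitted log scale,
  so noise-free recovery is exact and noisy recovery unbiased.
* **SST**: mean falling 0.74 °C per degree of latitude (the observed
  coastal gradient magnitude), a cosine seasonal cycle peaking in
  mid-August whose amplitude grows 0.5 °C per degree of latitude
  (mid-latitude estuaries see the widest ranges), an optional linear
  warming trend, and one interannual N(0, 0.3²) offset per year.
* **Bathymetry**: a land strip on the west, then a linear shelf
  dropping to 30 m over 3°, giving a realistic-width 0–10 m habitat
  band after coarsening.
* **Habitat probabilities**: a smooth sinusoid of latitude in
  [0.2, 0.8], restricted to the depth band.
* **Model pairs**: the analytic seasonal climatology on a coarse grid
  plus a known constant/affine/Gaussian-bump delta, returned alongside
  so tests can compare against the constructed truth.

Default problem sizes are chosen for a desk-scale demonstration: a
2.5° × 2.5° strip at 0.05° resolution over two years, coarsening to a
5 × 5 half-degree grid. These defaults exercise every code path at full
fidelity; the generators accept arbitrary domains when larger studies
are wanted. What passing tests on these fields shows is that the
*method* is implemented correctly (exact identities, oracle
equivalence, conservation); they say nothing about real coastlines,
tides, fronts, upwelling, or the skill of any particular climate model.

All generators are pure functions of (spec, seed); identical seeds give
byte-identical outputs.

## Numerical choices

* Boltzmann constant fixed at 8.617×10⁻⁵ eV/K; `b0` defaults to 14.47
  (the taxon-level normalization used in the sensitivity analysis) and
  is configurable; the mass exponent defaults to 3/4.
* Constant-rate data legitimately fit `E = 0`; a zero-residual fit
  reports `p = 0` for a nonzero slope and `p = 1` for a zero slope.
* A constant yearly-E series reports variance exactly 0 (guarding
  against summation round-off); the annual variance is scaled ×10³ for
  display, matching the conventional presentation of these small
  numbers.
* NetCDF I/O uses xarray's scipy backend (NetCDF3, CF-style coords and
  units); CSV schemas are fixed and validated on read.
* The strict config schema rejects unknown keys so a typo cannot
  silently fall back to a default.

## Known limitations

* No dispersal kinetics, multi-generation dynamics, density dependence,
  food availability or fishing pressure — relocation is instantaneous
  and cost-free.
* A hard subpopulation cline; no hybrid-zone gradient.
* Only additive (delta) bias correction; no variance scaling.
* Regular lat/lon model grids only; curvilinear/rotated-pole grids must
  be regridded upstream.
* The sensitivity analysis treats `E` and mass as independent dials;
  covariation between them in real populations is not modelled.
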