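# pibcm — physiology-integrated bioclimate modelling

`pibcm` projects how a coastal ectotherm's habitat shifts under ocean
warming by putting a physiological quantity — not just an environmental
envelope — at the center of the species distribution model. It was built
around the Atlantic killifish (*Fundulus heteroclitus*) parameterization
but every constant is configurable.

## The model

Whole-organism metabolic rate follows the metabolic theory of ecology:

    B = b0 · M^(3/4) · exp(−E / (K·T))

with body mass `M` (g), absolute temperature `T` (K), Boltzmann's
constant `K = 8.617×10⁻⁵ eV/K`, and the averaged enzyme activation
energy `E` (eV). `E` is treated as species-, population- and
thermal-history-specific: it is estimated by ordinary least squares of
`ln(rate)` on `1/T`, whose slope is `−E/K`.

The **metabolic rate range** (MRR) of a habitat cell is the difference
between `B` evaluated at the cell's climatological maximum and minimum
SST — a proxy for the aerobic scope a locally adapted population
maintains. Cells carry thermal envelopes: their SST extremes snapped to
the 5 °C acclimation lattice (5–30 °C), which selects the acclimation
measurements entering each envelope-specific `E` fit. Populations north
of a 40° N cline use northern acclimation data, southern ones southern.

Future SSTs come from additive **delta-method downscaling**: the
(future − historical) climate-model climatology is regridded to the
half-degree baseline with an exact thin-plate spline and added to the
observed baseline climatology.

The projection itself applies three conditions per occupied cell
(`T_b = 32 °C` break temperature):

1. **stay** — future T_max ≤ T_b, the habitat warms, but future MRR ≤
   contemporary MRR (the population compensates via `E`);
2. **stay** — future T_max ≤ T_b and either the habitat does not warm or
   the MRR does not grow;
3. **move** — future T_max > T_b, or both T_max and MRR increase: the
   population relocates to the nearest cell (haversine distance) whose
   future MRR is at most its contemporary MRR and whose future T_max is
   below the break. Receiving cells are capped at probability 1
   (overflow recorded); populations with no qualifying refuge are
   stranded and reported.

A single-variable trapezoidal RES (relative environmental suitability)
envelope model is included as the conventional baseline for comparison.

## Worked example

```python
import numpy as np
from pibcm import (fold_change, fit_arrhenius, gen_arrhenius_measurements,
                   metabolic_rate_range, MTEParameters, snap_to_envelope)

data = gen_arrhenius_measurements(
    E_true=0.6, ln_A0=20.0, temps_C=[5, 10, 15, 20, 25, 30, 33],
    noise_sd=0.05, n_reps=4, seed=1,
)
fit = fit_arrhenius(data)
print(f"fitted E = {fit.E_eV:.3f} eV (R^2 = {fit.r_squared:.3f}, "
      f"p = {fit.p_value:.2e}, n = {fit.n})")

env = snap_to_envelope(8.2, 27.6)
print(f"thermal envelope for extremes (8.2, 27.6) degC: {env}")

mrr = metabolic_rate_range(10.0, 8.2, 27.6, fit.E_eV, MTEParameters())
print(f"MRR for a 10 g fish over that range: {mrr:.3e} rate units "
      f"({np.log10(mrr):.2f} log10)")

print(f"0.1 eV shift at  0 degC: {fold_change(0.1, 0.0):.1f}-fold")
print(f"0.1 eV shift at 40 degC: {fold_change(0.1, 40.0):.1f}-fold")
```

prints

```
fitted E = 0.590 eV (R^2 = 0.997, p = 8.82e-35, n = 28)
thermal envelope for extremes (8.2, 27.6) degC: 10-30
MRR for a 10 g fish over that range: 8.390e-09 rate units (-8.08 log10)
0.1 eV shift at  0 degC: 70.0-fold
0.1 eV shift at 40 degC: 40.7-fold
```

The fitted activation energy recovers the 0.6 eV used to simulate the
acclimation experiment (5 % multiplicative noise); the snapped envelope
and MRR are the per-cell quantities that drive the projection; and the
two fold-change numbers show why `E` matters: shifting it by just
0.1 eV rescales metabolic rate ~70-fold in cold water and ~40-fold in
warm water.

## Command-line pipeline

```sh
pibcm simulate   --seed 5 --out demo        # synthetic input bundle
pibcm fit-e      --config run.yaml          # Arrhenius E fits -> CSV
pibcm climatology --config run.yaml         # half-degree monthly climatology
pibcm downscale  --config run.yaml          # delta-method future climatology
pibcm project    --config run.yaml          # future habitat map + diagnostics
pibcm res        --config run.yaml          # trapezoidal RES baseline map
```

`run.yaml` holds paths and parameters (strict schema — unknown keys are
rejected); every run records its seed and config hash next to its
outputs.

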