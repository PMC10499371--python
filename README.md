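# mrdmdcc — equitable air-quality sensor placement

Deciding where to put a limited number of fine-particle (PM2.5) monitors in
a city is an optimization problem with a social dimension: networks driven
purely by pollution signal tend to track regional haze and meteorology,
while crowdsourced low-cost networks cluster in wealthier, predominantly
White neighborhoods.  `mrdmdcc` implements a data-driven placement method
that captures pollution variability across timescales *and* lets the
designer shift monitors toward majority-nonwhite or low-income
neighborhoods in a controlled way.  It is aimed at researchers and
practitioners designing urban monitoring networks from gridded daily
concentration fields and gridded census surfaces.

## Method

**Multiresolution dynamic mode decomposition (mrDMD).**  A daily pollutant
field on `n` grid cells is flattened to a matrix and decomposed over a
dyadic ladder of time windows: level 1 spans the full training window of
`M` snapshots, and each level halves the window, so level `l` has
`2^(l-1)` windows.  At every window an exact (SVD-based) DMD is run on the
residual left by coarser levels; modes completing at most one oscillation
per window (frequency `f <= 1/(m dt)` for an `m`-snapshot window) are
retained as that window's *slow* set and subtracted before recursing.
With `M = 4096` days and 10 levels, the ladder resolves timescales from
11.2 years down to 8 days, so long-term background, seasonality, and
short transient pollution episodes each land at their own level.

**Modal library and QR pivoting.**  All retained modes are stacked into a
real tailored basis `psi_r` (n cells x r modes; a complex-conjugate pair
contributes its real and imaginary parts).  Classical column-pivoted QR on
`psi_r^T` greedily selects the location whose residual column — after
orthogonalization against already-selected locations — has the largest
2-norm: the next sensor always adds the most unexplained modal energy.

**Equity cost constraint.**  Census surfaces are rescaled to a per-cell
metric `s` in [0, 1] (1 = most nonwhite, or lowest income after
inversion), from which a penalty vector `eta` is built that is *low* inside
target communities (default: a step function, `eta = 0` where `s >= 0.5`).
The cost-constrained pivot maximizes

    l = || residual column ||_2  -  gamma * eta_i

over unselected locations `i`.  At `gamma = 0` this is exactly classical
pivoting; increasing `gamma` (useful range 0–0.5 on a unit-normalized
library) shifts sensors into penalized-free cells.  Greedy sequences nest,
so the top-k network is a prefix of any larger network — changing the
sensor count requires no new decomposition.

Because the real inputs (multi-year 1-km PM2.5 reanalyses, census tract
surfaces) are large external datasets, the package ships a synthetic-city
generator — seasonal + trending background, urban-core enhancement,
localized transient events on dyadic timescales, Gaussian noise, and
spatially segregated demographic surfaces — so the whole method is
testable end to end with known ground truth.

## Worked example

```python
import mrdmdcc as m

config = m.CityConfig(
    n_rows=16, n_cols=16, n_days=512, noise_sigma=1.0, seed=42,
    events=(
        m.EventSpec(center=(4, 4), sigma=1.5, start=120, duration=8, amplitude=30.0),
        m.EventSpec(center=(12, 10), sigma=2.0, start=300, duration=32, amplitude=20.0),
    ),
)
city = m.generate_city(config)
dconfig = m.DecompositionConfig(levels=7, training_window=512)
tree = m.mrdmd_decompose(city.field, dconfig)
library = m.build_library(tree, dconfig, city.geometry)
print(f"library: {library.n_cells} cells x {library.r_total} modes")

cost = m.build_penalty(city.s_race, mode="step", threshold=0.5, metric_name="race")
for gamma in (0.0, 0.2):
    placement = m.cc_pivot_select(library, cost, m.PlacementConfig(k=40, gamma=gamma))
    summary = m.network_summary(placement, city.s_race, city.geometry,
                                income=city.income, field=city.field)
    coverage = m.coverage_of_events(placement, city.ground_truth, city.geometry, radius=2)
    print(f"gamma={gamma}: mean s = {summary.mean_s:.3f}, "
          f"majority fraction = {summary.majority_fraction:.2f}, "
          f"median income = ${summary.median_income:,.0f}, "
          f"mean PM2.5 = {summary.mean_field:.2f} ug/m3, "
          f"event coverage = {coverage:.2f}")
```

prints

```
library: 256 cells x 247 modes
gamma=0.0: mean s = 0.322, majority fraction = 0.30, median income = $122,834, mean PM2.5 = 11.57 ug/m3, event coverage = 1.00
gamma=0.2: mean s = 0.801, majority fraction = 0.95, median income = $35,334, mean PM2.5 = 10.81 ug/m3, event coverage = 1.00
```

The unconstrained network (`gamma = 0`) chases modal variability: it finds
every planted transient event (coverage 1.00) but places only 30% of its
sensors in majority-nonwhite cells.  At `gamma = 0.2` the network keeps
full event coverage and a similar mean long-term concentration while 95%
of sensors move into majority-nonwhite cells and the network's median
income drops accordingly — the trade the cost constraint is designed to
make explicit.

The same pipeline is available from the shell:

```sh
mrdmdcc simulate  --config city.yaml --out city.nc --truth truth.csv --surfaces-prefix surf
mrdmdcc decompose --field city.nc --levels 10 --training-window 4096 --library lib.csv
mrdmdcc place     --library lib.csv --cost surf_s_race.csv --gamma 0.2 --n-sensors 250 --out sensors.csv
mrdmdcc sweep-gamma --library lib.csv --cost surf_s_race.csv --grid 0:0.5:0.05 --n-sensors 250 --out-dir sweep/
mrdmdcc evaluate  --sensors sensors.csv --surfaces surf_s_race.csv --field city.nc --truth truth.csv --out report.csv
mrdmdcc run       --config run.yaml --out-dir results/
```

## Documentation

`docs/methods.md` describes the model, its assumptions, the numerical
choices, what the synthetic city does and does not emulate, and known
limitations.
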