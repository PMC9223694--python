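# Methods

## The model

The package implements a four-variable kinetic model of the heat-shock
response (HSR) in a single adherent cell. The state is

- `theta` — the cell-environment temperature (°C),
- `[MFP]` — misfolded protein (µM),
- `[HSP]` — the generic 70-kDa chaperone pool (µM),
- `[mHSP]` — HSP mRNA (µM),

with dynamics

```
tau_temp  d(theta)/dt = theta_c - theta
tau_mfp   d[MFP]/dt   = kappa(theta) - [MFP]^2/([HSP]+[MFP]) - k_r [MFP][HSP]/([HSP]+[MFP])
tau_hsp   d[HSP]/dt   = beta * HSPfree/(H0 + HSPfree) * [mHSP] - [HSP]
tau_mhsp  d[mHSP]/dt  = mu + lam * HSF1free^3/(S0^3 + HSF1free^3) - [mHSP]
```

where `HSPfree = [HSP]/([HSP]+[MFP])` is the fraction of chaperone not
engaged with misfolded substrate and
`HSF1free = [HSF1]tot/([HSF1]tot + [HSP]*HSPfree)` the fraction of HSF1
not sequestered by free chaperone. Temperature enters only through the
denaturation rate

```
kappa(theta) = k_d (1 - 0.4 e^(37-theta)) 1.4^(theta-37)
```

clamped at zero (the raw expression goes negative below ~34.7 °C, which
would be an unphysical negative denaturation flux; protocols never go
there). The experimental readout is the fraction `F` of HSF1:eGFP
fluorescence in nuclear stress bodies, modelled as

```
F = (HSF1free)^3
```

The cubic reflects HSF1 trimerisation: foci appear only once a
substantial fraction of HSF1 escapes sequestration, which gives the
hypersensitive, switch-like activation that drives the response
continuum. `S0` and `H0` threshold the *fractions* `HSF1free` and
`HSPfree` and are treated as dimensionless.

Reference parameters (the calibrated HeLa set): `k_d = 1.76 µM`,
`k_r = 17.7`, `mu = 1.47e-3 µM`, `lam = 0.78 µM`, `S0 = 0.18`,
`beta = 10`, `H0 = 0.32`, `[HSF1]tot = 0.04 µM`, `tau_temp = 1/15 h`,
`tau_mfp = 0.5 h`, `tau_mhsp = 1 h`, `tau_hsp = 10 h`. They are fixed
throughout; the package never re-estimates them. With these values the
normothermic fixed point is `[MFP] = 0.0671`, `[HSP] = 0.5066`,
`[mHSP] = 0.0690` µM and `F = 0.055 %` — an unstressed cell shows no
detectable foci (detection limit 1 %).

## Initial conditions and integration

Because the 3 h stress is much shorter than the 10 h HSP lifetime, a
cell's chaperone content is an *initial condition*, not a dynamical
outcome: each cell is parameterised by `(hsf1_tot, hsp0)`. At `t0` the
fast variables are slaved to `hsp0`: `[MFP]` sits on its nullcline (the
positive root of `MFP^2 + (k_r hsp0 - kappa) MFP - kappa hsp0 = 0` at
37 °C) and `[mHSP]` on the mRNA nullcline given the resulting
`HSF1free`. At `hsp0` equal to the steady-state level this construction
reproduces the fixed point exactly.

Integration uses LSODA (stiffness switching; the incubator time constant
`tau_temp = 4 min` is two decades below `tau_hsp`) with `rtol = 1e-8`,
`atol = 1e-10`, piecewise over the protocol segments so setpoint steps
never cross an integration interval. Halving the tolerances moves `F(t)`
by less than `1e-6` sup-norm. The steady-state finder relaxes over 20
HSP lifetimes at `rtol = 1e-12` and doubles the horizon until every
component of the vector field is below `1e-8`.

Degenerate inputs: the titration ratios at `[HSP] = [MFP] = 0` are
evaluated as 0 (the continuous extension along `[HSP] -> 0`); tiny
negative concentration excursions from roundoff are clipped at 0 inside
the right-hand side.

## Synthetic populations

`hsr.population` emulates the time-lapse design: a 37 °C baseline, a 3 h
hyperthermia step at 41–44 °C (the incubator setpoint steps; the cell
temperature relaxes with `tau_temp`), one pre-stress sample at −10 min,
10-minute sampling to 1 h after stress end, and 500 cells per condition
by default. Cell-to-cell variability is log-normal in both `hsp0` and
`hsf1_tot`, parameterised by median and coefficient of variation:
`X = median * exp(sigma Z)` with `sigma = sqrt(ln(1 + cv^2))`, so the
sample median and CV equal the nominal values. Defaults: the `hsp0`
median is the normothermic steady-state HSP level (resolved at
generation time), `hsf1` median 0.04 µM, both CVs 0.4 — values that put
43 °C in a partial-responder regime. The two levels are uncorrelated by
default; a log-scale correlation coefficient is exposed. A collagen
(col+) condition is modelled as a multiplicative shift of the `hsp0`
median with everything else unchanged (`condition_shift`).

**Measurement model.** The imaging pipeline can only detect foci holding
at least 1 % of a cell's fluorescence, and measures `F` with an error of
about 2 % (absolute). The generator therefore records a sample as
`F = 0` whenever the true model `F` is below the 1 % detection limit
(foci invisible to blob detection), and adds Gaussian noise
(`sigma = 0.02`, clipped to [0, 1]) to detected samples. Without the
detection step, additive noise on every 10-minute sample would push
essentially every cell over the 1 % responder threshold at some time
point and the responder fraction would saturate at 1 regardless of
temperature; the detection-limit model keeps responder statistics
faithful to what foci detection can see. Setting
`apply_detection_limit=False` yields raw model output plus plain
additive noise. Total fluorescence is reported as
`hsf1_tot * fluorescence_scale`, optionally with multiplicative
log-normal noise (off by default).

What the generator does **not** emulate: cell-cycle structure, movie
attrition and tracking errors, focus drift, the distinction between the
two HSP70 family members (the model carries one generic pool), or any
real correlation between chaperone and HSF1 expression (unknown; config
only). Passing tests therefore validate the pipeline's internal
consistency on data with the assumed statistical structure, not the
biology of any particular cell line.

## Response statistics

- **Responder call**: positive iff `max F` over the hyperthermia window
  strictly exceeds 1 %. The call is made once per cell and held fixed;
  averaging dynamics over per-time-point thresholding would bias low-F
  time points upward.
- **Hill summary** of responder fraction vs. temperature:
  `frac(T) = plateau (T-37)^h / ((T50-37)^h + (T-37)^h)`, plateau left
  free, bounded least squares. An eye guide, not an inference.
- **Amplitude summaries**: percentiles 9/25/50/75/91 of `F` over
  responders at 1 h and 3 h, nearest-sample matched within 5 min
  (half the sampling interval); percentiles by linear interpolation
  between order statistics.
- **Relaxation index** `eta = F(3 h)/F(1 h)`, undefined (cell excluded,
  logged) when `F(1 h) = 0`; histogrammed into four contiguous
  half-open regimes `[0, 0.25)`, `[0.25, 0.75)`, `[0.75, 1.25)`,
  `[1.25, inf)`: adaptation, imperfect adaptation, plateau, continuing
  increase.
- **Activation function**: quartiles of `F` binned by the
  chaperone-to-HSF1 ratio in log-spaced classes (8 per decade across the
  observed range — expression is log-normal, so log spacing gives
  comparable occupancy); classes with 30 cells or fewer are suppressed;
  non-positive expression values are excluded and logged.

## Chaperone inference

Per cell, `hsf1_tot` is fixed by fluorescence renormalization — a
proportionality between HSF1:eGFP fluorescence and concentration whose
factor makes the population mean equal the 0.04 µM reference — and is
never fitted. The initial chaperone level `hsp0` is then the single free
parameter. The fit evaluates every candidate on a 60-point log grid
spanning `[0.1x, 100x]` the normothermic steady-state HSP level (the
upper factor covers the high-level range that flat traces cannot
distinguish) by simulating the model and scoring the mean absolute
deviation in `F` over all time points; exhaustive evaluation is chosen
over a local optimiser because the likelihood step needs the whole
error profile anyway and the profile can be flat. RMSE is available as
an option. A fit is satisfactory when its average error is below the
2 % measurement error of `F`.

The error profile converts to a likelihood under a Gaussian measurement
model with independent time points:
`w_j ∝ exp(-e_j^2 n_t / (2 sigma^2))`, `sigma = 0.02`, normalised over
the grid. Responders give localised peaks; non-responders give plateaus
over the upper grid (any sufficiently high chaperone level explains a
flat trace). The population expression distribution is the normalised
sum of per-cell likelihoods; no smoothing is applied.

The with/without-heterogeneity comparison fixes the control arm's
`hsp0` at the population steady-state value; the control value is
inserted into the grid, so the free arm nests the control and its best
error can never be larger (checked per cell).

## Known limitations

- Non-responding cells only bound their chaperone level from below.
  Where they dominate (e.g. a strongly overexpressing condition at
  43 °C), the summed distribution's upper tail is a plateau artefact
  and its median overestimates the generating median; the distribution
  is then informative about the responding subpopulation and the
  *fraction* at high levels, not the precise high-level shape. The
  grid's upper cutoff (100x) truncates this plateau arbitrarily.
- No estimation error is attached to the inferred distribution.
- The relaxation index needs `F(1 h) > 0`; late responders are excluded
  from shape statistics.
- The Hill summary can be poorly conditioned when all fractions are
  near 0 or 1 (flagged degenerate when there is no variation at all).

## Problem sizes

The test suite runs populations of 30–250 cells and the recovery
experiment at 200 cells with measurement noise; the analysis drivers use
150 cells per condition and 60-point fitting grids. These sizes keep
every statistic well away from small-sample artefacts (binomial slack is
accounted for where fractions are compared) while a full driver run
completes in a few minutes on one core.
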