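# hsr — single-cell heat-shock-response kinetics and chaperone inference

Mammalian cells answer proteotoxic stress with the heat-shock response
(HSR): misfolded proteins titrate HSP70-family chaperones away from the
transcription factor HSF1, freed HSF1 trimerises, concentrates in
nuclear stress bodies (visible as fluorescent foci in HSF1:eGFP cells)
and drives chaperone expression. Because activation is switch-like,
modest cell-to-cell differences in chaperone and HSF1 expression produce
a striking continuum of single-cell responses to one and the same
stress — from no foci at all to adaptation, plateau, or continuing rise.

This package is for quantitative biologists studying that heterogeneity
in time-lapse data. It provides:

- **`hsr.model`** — the four-variable kinetic model (temperature
  `theta`, misfolded protein `[MFP]`, chaperone `[HSP]`, message
  `[mHSP]`), driven by a temperature protocol through the denaturation
  rate `kappa(theta) = k_d (1 - 0.4 e^(37-theta)) 1.4^(theta-37)`, with
  the foci readout `F = (HSF1_free)^3`,
  `HSF1_free = [HSF1]tot / ([HSF1]tot + [HSP] [HSP]/([HSP]+[MFP]))`.
- **`hsr.population`** — a synthetic single-cell experiment generator:
  log-normal expression heterogeneity, 10-minute sampling, a 3 h
  hyperthermia step at 41–44 °C, foci detection limit and 2 %
  measurement noise, with ground truth emitted alongside.
- **`hsr.statistics`** — responder fractions with a Hill summary curve,
  responder-restricted mean foci dynamics, amplitude percentile
  summaries, relaxation-index (`eta = F(3h)/F(1h)`) histograms, and the
  ratio-binned activation function of `F` vs. chaperone/HSF1 expression.
- **`hsr.inference`** — the model-based reconstruction of chaperone
  expression: per cell, HSF1 is pinned by fluorescence renormalization
  and the initial chaperone level `[HSP](t=0)` is the single free
  parameter, fitted by exhaustive search on a log grid, gated at the 2 %
  measurement error, converted to a likelihood, and summed over cells
  into a population expression distribution.

See `docs/methods.md` for model equations, parameter meanings, the
measurement model and numerical choices.

## Worked example

The numbered drivers under `analysis/` run the whole study on synthetic
data (tables land under `results/`):

```
python analysis/01_simulate_populations.py
python analysis/02_response_statistics.py
python analysis/03_infer_chaperone.py
```

`02_response_statistics.py` prints, per condition (150 cells each):

```
41C_colm: responder fraction 0.413 (150 cells)
  relaxation regimes (adapt/imperfect/plateau/rise): (41, 0, 0, 0)
42C_colm: responder fraction 0.707 (150 cells)
  relaxation regimes (adapt/imperfect/plateau/rise): (92, 0, 0, 0)
43C_colm: responder fraction 0.867 (150 cells)
  relaxation regimes (adapt/imperfect/plateau/rise): (72, 51, 1, 0)
44C_colm: responder fraction 0.967 (150 cells)
  relaxation regimes (adapt/imperfect/plateau/rise): (12, 44, 83, 5)
43C_colp: responder fraction 0.533 (150 cells)
  relaxation regimes (adapt/imperfect/plateau/rise): (59, 17, 0, 0)

Hill summary (col-): half-activation 41.36 degC, exponent 5.0, plateau 1.05
43 degC responder fraction col- vs col+: 0.867 vs 0.533 (chaperone overexpression smooths the response)
```

The responder fraction climbs monotonically with stress temperature, and
the response *shape* shifts from clean adaptation at 41 °C to plateau
and continuing rise at 44 °C, where repair cannot keep up. The `colp`
condition — chaperone median shifted 1.5× to mimic collagen-induced
overexpression — responds less and adapts more, purely through the
expression shift.

`03_infer_chaperone.py` then inverts the dynamics back into expression:

```
43C_colm: 150 cells, 100.0% satisfactory fits; inferred median 0.527 uM (generating median 0.507 uM)
  fit success with chaperone heterogeneity 100.0% vs control 45.0%
```

Every trace is fit within the 2 % gate once chaperone heterogeneity is
allowed (against 45 % with HSF1 heterogeneity alone), and the inferred
population distribution's median lands within 4 % of the level that
generated the data. For the overexpressing condition the inference
recovers the direction of the shift but overestimates its size, because
cells without foci only bound their chaperone level from below — see the
limitations section of `docs/methods.md`.

The same operations are scriptable on any trajectory CSV via the CLI:

```
hsr simulate-population --config cfg.yaml --seed 1 --out data/
hsr analyze --traj data/trajectories.csv --out stats/
hsr infer --traj data/trajectories.csv --out inference/
```

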