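# ricephen

Degree-day phenology of three rice planthopper species — *Nilaparvata
lugens*, *Sogatella furcifera* and *Laodelphax striatellus* — driven by
temperatures measured (or simulated) at several heights inside and above
the paddy rice canopy.

Planthopper generations are conventionally forecast from air temperature
at a 2.0 m reference height, but the insects live inside the canopy,
which is 1–2 °C cooler on a daily-mean basis. `ricephen` implements the
full analysis needed to quantify what that difference does to forecast
accuracy: a stage-structured linear degree-day model integrated hourly,
extraction of observed generation periods from survey peak dates, and
per-height evaluation with RMSE, MAE and the RMSE skill score — plus a
seeded synthetic-data module (canopy microclimate and sticky-board count
series) so the whole pipeline is testable without field data.

## Model

The development rate `R` (day⁻¹) of each life stage is piecewise linear
in temperature `T`:

    R = (T − T_min) / K            T_min ≤ T < T_upper
      = (T_upper − T_min) / K      T_upper ≤ T < T_stop
      = 0                          otherwise

where `T_min` is the lower developmental threshold, `T_upper` the
plateau onset, `T_stop` the critical thermal maximum and `K` the thermal
constant in degree-days. A stage completes when the hourly integral of
`R` reaches 1 (each hour contributes `R(T_h)/24`, with sub-hour linear
interpolation at the crossing). A generation chains preoviposition →
egg → nymph, each stage starting at the previous completion instant; the
generation period is the total elapsed fractional days. Laboratory
parameter values for all nine species × stage combinations ship as the
default registry.

Prediction accuracy at a sensor height `h` is scored against the 2.0 m
reference with the RMSE skill score `RMSE_ss = 1 − RMSE_h / RMSE_ref`.

## Worked example

```python
>>> import ricephen as rp
>>> model = rp.get_species_model("N_lugens")
>>> series = rp.TemperatureSeries.constant(25.0, n_hours=24 * 45)
>>> round(rp.predict_generation_period(series, model, "2021-07-30"), 2)
25.76
>>> round(rp.closed_form_constant_period(25.0, model), 2)
25.76
```

At a constant 25 °C a *N. lugens* generation takes 25.76 days
(preoviposition 35.9/13.6 + egg 109.4/12.3 + nymph 194.9/13.7
degree-day quotients); the hourly engine and the analytic closed form
agree.

The packaged 2021 field-survey peak-date table reproduces the published
generation-period summaries:

```
$ ricephen reproduce-table
Observed generation periods (packaged 2021 survey table):
  N_lugens       normal  n=10  mean=29.00 d
  N_lugens       low     n=9   mean=31.44 d
  S_furcifera    normal  n=12  mean=27.92 d
  S_furcifera    low     n=10  mean=27.80 d
  L_striatellus  normal  n=9   mean=28.33 d
  L_striatellus  low     n=8   mean=28.50 d
RMSE skill scores at 0.25 m vs the 2.0 m reference:
  N_lugens       normal=0.31 low=0.56
  S_furcifera    normal=0.24 low=0.31
  L_striatellus  normal=0.20 low=0.29
```

Positive skill scores at 0.25 m mean canopy-bottom temperatures predict
development better than the reference height at every species/plot, most
strongly for *N. lugens* — the species that actually lives at the canopy
bottom — in the cool-water plot.

Other CLI commands: `simulate-microclimate`, `simulate-population`,
`predict`, `extract-periods`, `evaluate`, `height-recovery` (see
`ricephen --help`).

## Layout

- `src/ricephen/params.py` — stage/species thermal parameters, YAML registry
- `src/ricephen/phenology.py` — rate function, hourly engine, closed form
- `src/ricephen/observed.py` — peak tables, period extraction, peak detection
- `src/ricephen/evaluation.py` — RMSE/MAE/skill score, per-height evaluation
- `src/ricephen/synthetic.py` — seeded microclimate and count generators
- `src/ricephen/pipeline.py` — end-to-end height-recovery experiment
- `src/ricephen/io.py`, `cli.py` — CSV/JSON formats and the `ricephen` CLI
- `docs/methods.md` — modelling and design notes
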