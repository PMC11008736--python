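# Methods

## Development model

Each life stage (egg, nymph, preoviposition) of the three planthopper
species follows the effective-accumulated-temperature linear model with
an upper plateau and a lethal cutoff: the development rate is
`(T − T_min)/K` per day between the lower threshold `T_min` and the
plateau onset `T_upper`, constant at `(T_upper − T_min)/K` between
`T_upper` and the critical maximum `T_stop`, and zero outside. The rate
is continuous at `T_upper` and discontinuous only at `T_stop`. The
packaged registry carries the nine laboratory-derived parameter sets
(temperatures in °C, thermal constants `K` in degree-days); any
registry with the same YAML layout can be substituted.

Development is integrated hourly: hour `h` contributes `R(T_h)/24` to
the cumulative fraction, and a stage completes at the first instant the
cumulative fraction reaches 1. Two numerical choices matter:

- **Sub-hour completion.** The crossing is interpolated linearly inside
  the crossing hour, making durations fractional days. This removes a
  ±1 h quantization and lets the engine match the constant-temperature
  closed form `K/(min(T, T_upper) − T_min)` essentially exactly (the
  test tolerance of one hourly step, 1/24 day, is conservative).
- **Stage chaining order.** Observed generation intervals run from an
  adult arrival (or adult peak) to the next adult peak, so a generation
  is chained preoviposition → egg → nymph: the arriving adults first
  mature eggs, then their offspring develop. On slowly varying seasonal
  series the alternative order egg → nymph → preoviposition changes the
  total by well under a day (asserted in tests), so the choice is not
  load-bearing.
- **Start convention.** Arrival/release dates carry no time of day;
  predictions start at 00:00 local on the start date. Timestamps are
  timezone-naive local time (the study region has no DST).

Incomplete development (temperature series ends before the chain
finishes) is a distinct condition from invalid input: the former is
flagged (`SeriesExhaustedError` from the chain predictor, an
incomplete-marked `StageResult` from the single-stage accumulator), the
latter raises `ValueError`.

## Observed periods

A cohort row of event dates (start, peak 1, peak 2, …) yields one
development period per successive pair, by plain calendar-day
subtraction (30 July → 27 Aug = 28 days, no inclusive +1). All
successive pairs are used; the folk rule that planthopper generations
appear "20–30 days" apart is treated as descriptive, not as a filter —
the packaged 2021 table's intervals actually span 21–38 days. On that
table this convention reproduces five of the six published plot means
exactly (31.44, 27.92, 27.80, 28.33, 28.50 days) and all six sample
sizes (10/9, 12/10, 9/8). The *N. lugens* normal-plot mean computes to
29.00 days where 29.11 was published; no successive-interval inclusion
rule reproduces 29.11 from the tabulated dates, so the package reports
its own value rather than forcing agreement.

Peak detection in count series marks survey dates whose count is at
least both neighbours (ties resolve to the earlier date), then thins
candidates so kept peaks are separated by a minimum window (default
14 days; the taller peak wins inside a window). Terminal survey dates
are not peaks unless explicitly enabled, since a rising edge at the
series end cannot be confirmed. An optional count floor suppresses
noise maxima in near-zero stretches.

## Evaluation

For each sensor height, every observed period is re-predicted from its
own start date and paired with the observed integer days; predictions
stay fractional (rounding would add quantization bias). RMSE and MAE
summarise each height; the skill score `1 − RMSE_h/RMSE_ref` scores a
height against the 2.0 m reference (0 at the reference, positive iff
strictly better). Periods whose prediction is incomplete at *any*
height are excluded at all heights, keeping one n per species/plot;
exclusions are logged. Reporting rounds to 2 decimals.

## Synthetic data

The microclimate generator is phenomenological, not an energy-balance
model — it exists to exercise the analysis, not to simulate canopy
physics. Hourly temperature at height `h` is

    base_mean + trend·(d − d_ref) + offset(h) + A·damp(h)·sin(diurnal)
    ± inversion/2 (day/night, canopy only) + weather(d) + ε

with defaults: 25.8 °C base mean at 2.0 m; −0.06 °C/day seasonal trend
centred on 30 August so the 30 July–30 September window mean stays at
the base; 4.5 °C diurnal half-amplitude, damped to 40–65% inside the
canopy; daily-mean offsets of 0/−0.7/−1.2/−1.3/−1.4 °C (normal plot)
and 0/−1.0/−1.5/−1.9/−2.2 °C (low-water plot) at 2.0/1.0/0.75/0.5/0.25
m, matching the daily-mean profile observed in the 2021 paddy study; a
mean-preserving 1 °C day/night inversion term giving the canopy its
relatively deeper nighttime deficit; a day-to-day weather anomaly
(sd 1.5 °C, shared across heights, mean-zero over the season — the
norm is carried by the base and trend) resembling the ~1.8 °C
daily-mean scatter of the field data; and 0.3 °C hourly sensor noise.
Water temperature (0.0 m) is a further-damped (35%), 3 h-lagged cycle
at −0.8 °C (normal) or −2.9 °C (low) from the reference, reproducing
the ~2.1 °C between-plot water difference. Everything is a pure
function of (params, seed); the default seed 20210730 is the *N.
lugens* release date.

The population generator places one Gaussian density pulse (default
peak 20 adults/hill, sd 5 days) per generation at the instants the
degree-day model itself predicts by iteration from a start date, samples
the sum at twice-weekly survey dates, and applies mean-preserving
lognormal noise per sticky board (CV 30%) averaged over 3 replicate
boards, mirroring the field protocol. The ground-truth peak instants
are returned alongside the counts, so recovery can be scored exactly.

What the generator does **not** emulate: canopy growth through the
season (offsets are fixed), immigration pulses and inter-species
competition, overlap between broods beyond additive pulses, and any
feedback of density on development. Passing synthetic tests therefore
demonstrates that the analysis machinery is correct and well-powered
under clean conditions, not that field data of this shape would yield
the same accuracy ranking.

With twice-weekly surveys, pulses of this width and board-level noise,
the detected peak date occasionally slips to the survey adjacent to the
nearest one; Monte-Carlo over 200 seeded replicates puts detected
generation spacings within one survey interval of the model-predicted
spacing in ~84% of replicates, and the regression test asserts that
rate with a margin for seed variation (≥ 75%).

## Height-recovery experiment

The end-to-end check generates a low-water plot's six temperature
series, drives populations with the 0.25 m series for four cohort start
dates (30 July, 3, 10, 14 August; two generations each) in each of
three replicate fields — the survey pooled three transplant fields per
plot, and pooling is what gives RMSE ranking its power — detects peaks
(20-day minimum separation: planthopper generations cannot complete
faster at paddy temperatures), extracts observed periods, and evaluates
all six heights. Success means 0.25 m ranks in the RMSE top two: the
0.5 m series differs by only 0.3 °C in daily mean (< 1 day of predicted
development), so demanding outright rank 1 would test noise, not
correctness. Across 100-replicate seeded batches the rate is
consistently ≥ 0.97.

## Limitations

- The piecewise-linear model ignores diurnal-fluctuation rate
  corrections and any decline in rate between `T_upper` and `T_stop`.
- Observed periods are integer calendar days at survey resolution
  (3–4 days); individual predictions are only as comparable as that
  quantization allows.
- The published per-height RMSE/MAE table ships as data for skill-score
  recomputation; recomputing those RMSEs themselves would require the
  original field temperature records, which are not distributable.
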