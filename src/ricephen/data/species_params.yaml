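# Thermal-response parameters of the piecewise-linear development model for
# three rice planthopper species, per life stage.  Units: temperatures in
# degrees Celsius, thermal constant k in degree-days.  Values are the
# laboratory-derived constants used by the packaged default registry.
N_lugens:
  egg:            {t_min: 12.7, t_upper: 28.5, t_stop: 35.0, k: 109.4}
  nymph:          {t_min: 11.3, t_upper: 28.5, t_stop: 34.9, k: 194.9}
  preoviposition: {t_min: 11.4, t_upper: 30.0, t_stop: 37.0, k: 35.9}
S_furcifera:
  egg:            {t_min: 12.6, t_upper: 28.5, t_stop: 37.8, k: 78.0}
  nymph:          {t_min: 11.2, t_upper: 28.5, t_stop: 35.0, k: 178.9}
  preoviposition: {t_min: 10.7, t_upper: 30.0, t_stop: 37.8, k: 65.2}
L_striatellus:
  egg:            {t_min: 11.7, t_upper: 29.0, t_stop: 40.0, k: 114.0}
  nymph:          {t_min: 10.8, t_upper: 29.0, t_stop: 40.0, k: 212.1}
  preoviposition: {t_min: 11.2, t_upper: 29.0, t_stop: 40.0, k: 54.3}
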