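# Per-unit linear calibrations against a collocated FDMS TEOM:
#   reference_pm25 = intercept + slope * cf1
# Units marked default_woodsmoke were never individually collocated and
# use the generic woodsmoke conversion (0.53, 0.55).
calibrations:
  DPE:    {intercept: 0.53, slope: 0.55, source: default_woodsmoke}
  ARC2:   {intercept: 1.41, slope: 0.524, source: fitted_2018}
  ARC1:   {intercept: 1.15, slope: 0.516, source: fitted_2018}
  ARC02:  {intercept: 0.53, slope: 0.55, source: default_woodsmoke}
  ARC17:  {intercept: 1.66, slope: 0.523, source: fitted_2018}
  Arm1:   {intercept: 0.53, slope: 0.580, source: fitted_2018}
  Arm2:   {intercept: 0.53, slope: 0.510, source: fitted_2018}
  Arm3:   {intercept: 0.53, slope: 0.596, source: fitted_2018}
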