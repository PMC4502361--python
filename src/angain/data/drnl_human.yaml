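# Human DRNL filterbank coefficients, version 1.
#
# Per-channel parameters are generated from log-linear regressions on the
# channel characteristic frequency:  log10(param) = p0 + m * log10(cf).
# The linear-path gain uses the sign-corrected slope parameter g0:
#   log10(lin_gain) = p0_lin_gain - g0 * log10(cf),  g0 = +0.48.
version: 1
g0: 0.48
regressions:
  cf_lin:   {p0: -0.06762, m: 1.01679}
  bw_lin:   {p0: 0.03728,  m: 0.78563}
  lp_lin:   {p0: -0.06762, m: 1.01679}
  lin_gain: {p0: 4.20405}
  cf_nl:    {p0: -0.05252, m: 1.01650}
  bw_nl:    {p0: -0.03193, m: 0.77426}
  lp_nl:    {p0: -0.05252, m: 1.01650}
  a:        {p0: 1.40298,  m: 0.81916}
  b:        {p0: 1.61912,  m: -0.81867}
  c:        {p0: -0.60206, m: 0.0}
structure:
  # gammatone / low-pass cascade lengths: three first-order gammatones
  # before and after the broken-stick non-linearity.
  n_gt_lin: 2
  n_lp_lin: 4
  n_gt_nl: 3
  n_lp_nl: 3
  lp_order: 2
# Validity range of the regressions (Hz); channels outside trigger a warning.
valid_cf_range: [40.0, 13000.0]
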