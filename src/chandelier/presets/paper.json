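{
  "n_cells": 113,
  "depth_density_slope": -0.019,
  "npot_log_intercept": 1.91,
  "fcon_intercept": -0.55,
  "fcon_size_coef": 1.4,
  "fcon_inhib_coef": 1.3,
  "geometric_p": 0.44,
  "bifan_bias": 1.0,
  "seed": 0
}
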