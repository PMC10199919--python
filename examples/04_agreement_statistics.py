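"""Method-agreement statistics for paired pressure measurements.

Two 'methods' measure the same arterial pressures; their differences are
drawn N(0.19, 2.8^2) mmHg over 243 paired readings — the scale of a
two-transducer comparison.  The agreement battery recovers the generating
parameters.
"""

import numpy as np

from acuheight import agreement

rng = np.random.default_rng(7)
n = 243
reference = rng.normal(85.0, 12.0, n)     # clinical transducer MAP, mmHg
estimate = reference + rng.normal(0.19, 2.8, n)

rep = agreement(estimate, reference)
print(f"n                 = {rep.n}")
print(f"bias              = {rep.bias:+.2f} mmHg   (generator: +0.19)")
print(f"sd of differences = {rep.sd:.2f} mmHg    (generator: 2.80)")
print(f"median |diff|     = {rep.median_abs:.2f} mmHg")
print(f"ICC(2,1)          = {rep.icc:.3f}")
print(f"linear fit        = {rep.fit_slope:.3f} x + {rep.fit_intercept:.2f}")
q90 = rep.cdf_abs[np.searchsorted(rep.cdf_q, 0.9)]
print(f"90% of |diff|    <= {q90:.2f} mmHg")
print()
print("ICC(2,1) is the two-way random-effects absolute-agreement single-")
print("measure intraclass correlation, the standard method-agreement index.")
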