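"""Fit the nCSF model to one noisy synthetic voxel, coarse-to-fine.

A ground-truth model generates a noiseless prediction; scaled Gaussian
noise is added; the grid stage scans 5760 parameter combinations (solving
amplitude and baseline in closed form at each), and the iterative stage
refines the winner with a bounded local search. Printed numbers compare
the recovered parameters with the truth.
"""
import numpy as np

from ncsf import (CrfParams, CsfParams, NcsfParams, build_design, grid_fit,
                  iterative_fit, predict_timeseries)

rng = np.random.default_rng(2)
truth = NcsfParams(csf=CsfParams(cs_p=150, sf_p=1.0, width_r=1.3),
                   crf=CrfParams(slope_crf=3.0, amplitude=1.0))
design = build_design()
clean = predict_timeseries(truth, design).values
clean /= clean.std()
data = clean + 0.4 * rng.standard_normal(len(clean))

coarse = grid_fit(data, design)
fine = iterative_fit(data, design, init=coarse)

print(f"{'':>12}{'truth':>8}{'grid':>8}{'refined':>9}")
rows = [("sf_p (c/deg)", truth.csf.sf_p, coarse.params.csf.sf_p,
         fine.params.csf.sf_p),
        ("cs_p", truth.csf.cs_p, coarse.params.csf.cs_p,
         fine.params.csf.cs_p),
        ("width_r", truth.csf.width_r, coarse.params.csf.width_r,
         fine.params.csf.width_r),
        ("slope_crf", truth.crf.slope_crf, coarse.params.crf.slope_crf,
         fine.params.crf.slope_crf)]
for name, t, g, f in rows:
    print(f"{name:>12}{t:>8.2f}{g:>8.2f}{f:>9.2f}")
print(f"\nvariance explained: grid {coarse.r2:.1f}% -> "
      f"refined {fine.r2:.1f}%")
print("(the refined fit can never be worse than its grid initialization)")
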