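"""Predict a BOLD time series from a known nCSF model.

The per-volume neural drive is the Naka-Rushton response to each volume's
(spatial frequency, contrast) condition, with the semisaturation contrast
taken from the CSF; the drive is convolved with the two-gamma HRF
(canonical + temporal derivative) and shifted by the baseline.
"""
import numpy as np

from ncsf import (CrfParams, CsfParams, NcsfParams, build_design,
                  predict_timeseries)

truth = NcsfParams(csf=CsfParams(cs_p=150, sf_p=1.0, width_r=1.3),
                   crf=CrfParams(slope_crf=3.0, amplitude=1.2),
                   baseline=0.1)
design = build_design()
pred = predict_timeseries(truth, design)

v = pred.values
print(f"{len(v)} volumes; range [{v.min():.3f}, {v.max():.3f}] "
      f"(% signal change)")
first_stim = int(np.argmax(design.contrast_seq > 0))
print(f"first stimulus volume: {first_stim} "
      f"(t = {first_stim * design.tr:g} s)")
print("initial blank period stays at baseline:",
      np.allclose(v[:first_stim + 1], truth.baseline, atol=1e-3))
peak_vol = int(np.argmax(v))
print(f"peak response {v[peak_vol]:.3f} at volume {peak_vol} "
      f"(block {design.block_labels[peak_vol]})")
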