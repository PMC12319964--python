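"""Forward model: nCSF parameters + stimulus design -> predicted BOLD series.

Each volume's neural drive is the nCSF response to that volume's
(spatial frequency, contrast) condition; the drive is convolved with the
HRF kernel (linear, causal, zero-padded history, truncated to the run
length) and the baseline offset is added.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.typing import NDArray
from scipy.signal import fftconvolve

from .csf import NcsfParams, ncsf_response
from .design import StimulusDesign
from .hrf import HrfSpec, hrf_kernel

__all__ = ["PredictedSeries", "predict_timeseries", "neural_drive",
           "convolve_drive"]


@dataclass
class PredictedSeries:
    """Predicted per-volume percent-signal-change series with provenance."""

    values: NDArray
    provenance: dict[str, Any] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.values)


def neural_drive(params: NcsfParams, design: StimulusDesign) -> NDArray:
    """Per-volume pre-HRF response; exactly 0 on blank volumes."""
    drive = np.zeros(design.n_volumes)
    stim = design.contrast_seq > 0
    drive[stim] = ncsf_response(params, design.sf_seq[stim],
                                design.contrast_seq[stim])
    return drive


def convolve_drive(drive: NDArray, kernel: NDArray) -> NDArray:
    """Causal linear convolution truncated to the drive length.

    Accepts a single series or a (units, time) matrix; history before the
    run is zero-padded.
    """
    drive = np.asarray(drive, dtype=float)
    full = fftconvolve(np.atleast_2d(drive), kernel[None, :], axes=1)
    out = full[:, :drive.shape[-1]]
    return out if drive.ndim == 2 else out[0]


def predict_timeseries(params: NcsfParams, design: StimulusDesign,
                       hrf: HrfSpec | None = None) -> PredictedSeries:
    """Predicted BOLD series for one set of nCSF parameters."""
    hrf = hrf or HrfSpec()
    kernel = hrf_kernel(hrf, design.tr)
    values = convolve_drive(neural_drive(params, design), kernel)
    values = values + params.baseline
    return PredictedSeries(values=values, provenance={
        "params": params, "hrf": hrf,
        "design_n_volumes": design.n_volumes, "tr": design.tr})
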