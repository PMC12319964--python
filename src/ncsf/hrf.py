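"""Two-gamma hemodynamic response function basis.

The canonical impulse response is the conventional double-gamma: a gamma
density peaking at 6 s minus a gamma density peaking at 16 s scaled by a
peak/undershoot ratio of 6, truncated at 32 s. The basis adds the temporal
derivative (finite difference of the canonical) and the dispersion
derivative (partial with respect to the peak dispersion). Default weights
(1, 1, 0) — canonical plus temporal derivative, no dispersion term —
reproduce the fixed HRF used for fitting. The kernel is scaled to unit
canonical peak so amplitudes stay in percent-signal-change units.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.typing import NDArray
from scipy import stats

__all__ = ["HrfSpec", "hrf_kernel", "double_gamma"]

# double-gamma shape constants (seconds); all exposed through HrfSpec
PEAK_DELAY = 6.0
UNDERSHOOT_DELAY = 16.0
PEAK_DISPERSION = 1.0
UNDERSHOOT_DISPERSION = 1.0
PEAK_UNDERSHOOT_RATIO = 6.0
KERNEL_DURATION = 32.0
_DERIV_DT = 0.1
_DISP_DELTA = 0.01


@dataclass(frozen=True)
class HrfSpec:
    """Basis weights and shape constants of the two-gamma HRF."""

    coef_canonical: float = 1.0
    coef_derivative: float = 1.0
    coef_dispersion: float = 0.0
    kernel_duration: float = KERNEL_DURATION
    peak_delay: float = PEAK_DELAY
    undershoot_delay: float = UNDERSHOOT_DELAY
    peak_dispersion: float = PEAK_DISPERSION
    undershoot_dispersion: float = UNDERSHOOT_DISPERSION
    peak_undershoot_ratio: float = PEAK_UNDERSHOOT_RATIO

    def __post_init__(self) -> None:
        if self.kernel_duration <= 0:
            raise ValueError("kernel_duration must be > 0")


def double_gamma(t: NDArray, spec: HrfSpec | None = None,
                 peak_dispersion: float | None = None) -> NDArray:
    """Canonical double-gamma evaluated at times ``t`` (seconds)."""
    spec = spec or HrfSpec()
    pd_ = peak_dispersion if peak_dispersion is not None else spec.peak_dispersion
    peak = stats.gamma.pdf(t, spec.peak_delay / pd_, scale=pd_)
    under = stats.gamma.pdf(t, spec.undershoot_delay / spec.undershoot_dispersion,
                            scale=spec.undershoot_dispersion)
    return peak - under / spec.peak_undershoot_ratio


def hrf_kernel(spec: HrfSpec | None = None, tr: float = 1.5) -> NDArray:
    """Weighted two-gamma basis sampled every ``tr`` seconds.

    kernel = c_can * g + c_der * dg/dt + c_disp * dg/d(dispersion), each
    term divided by the canonical's peak value so the canonical alone has
    unit peak.
    """
    spec = spec or HrfSpec()
    if tr <= 0:
        raise ValueError("tr must be > 0")
    t = np.arange(0.0, spec.kernel_duration + tr / 2, tr)
    g = double_gamma(t, spec)
    dg = (double_gamma(t + _DERIV_DT, spec) -
          double_gamma(t - _DERIV_DT, spec)) / (2 * _DERIV_DT)
    ddisp = (double_gamma(t, spec, spec.peak_dispersion + _DISP_DELTA) -
             double_gamma(t, spec, spec.peak_dispersion - _DISP_DELTA)
             ) / (2 * _DISP_DELTA)
    # normalize by the canonical's peak on a dense grid (tr-independent)
    t_dense = np.arange(0.0, spec.kernel_duration, 0.01)
    scale = double_gamma(t_dense, spec).max()
    kernel = (spec.coef_canonical * g + spec.coef_derivative * dg +
              spec.coef_dispersion * ddisp) / scale
    return kernel
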