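"""Closed-form contrast sensitivity and contrast response mathematics.

The contrast sensitivity function (CSF) is modeled as an asymmetric
parabola in log10-log10 space:

    f(SF) = 10 ** ( log10(CS_p) - (log10(SF) - log10(SF_p))**2 * width**2 )

with ``width = width_l`` for SF below the peak and ``width = width_r`` at or
above it. ``width`` parameters are fall-off *rates*: a larger ``width_r``
means a faster drop in sensitivity toward high spatial frequencies.

The transition from no response to full response at a given spatial
frequency is a Naka-Rushton contrast response function (CRF)

    R(C) = a * C**q / (C**q + Q**q)

whose semisaturation contrast Q is tied to the CSF: by default
``Q(SF) = 100 / f(SF)``, the CSF-implied threshold contrast (sensitivity is
defined as 100 / threshold-contrast-%), so the response reaches half its
amplitude exactly at the CSF threshold.

The normalized area under the log10 CSF over the stimulus interval
(0.5-18 c/deg), expressed relative to a standard healthy-control CSF,
serves as the single-number summary of the whole curve.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from numpy.typing import ArrayLike, NDArray

from .config import (
    AUC_GRID_POINTS,
    AUC_INTERVAL,
    SENSITIVITY_EPS,
    STANDARD_CSF,
    WIDTH_L_DEFAULT,
)

__all__ = [
    "CsfParams",
    "CrfParams",
    "NcsfParams",
    "AucResult",
    "csf_sensitivity",
    "crf_response",
    "semisaturation_from_csf",
    "ncsf_response",
    "auc_normalized",
    "standard_csf_params",
]


@dataclass(frozen=True)
class CsfParams:
    """Asymmetric log-parabola CSF parameters.

    cs_p : peak contrast sensitivity (100 / threshold contrast %), > 0
    sf_p : peak spatial frequency in cycles/degree, > 0
    width_r : right-branch fall-off rate (log10 units), > 0
    width_l : left-branch fall-off rate, fixed at 0.68 by default
    """

    cs_p: float
    sf_p: float
    width_r: float
    width_l: float = WIDTH_L_DEFAULT

    def __post_init__(self) -> None:
        for name in ("cs_p", "sf_p", "width_r", "width_l"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and > 0, got {v!r}")


@dataclass(frozen=True)
class CrfParams:
    """Naka-Rushton CRF parameters (semisaturation is supplied by the CSF).

    slope_crf : exponent q of the Naka-Rushton function, > 0
    amplitude : saturation response a, in percent signal change
    semisaturation_rule : maps CSF sensitivity at a spatial frequency to the
        semisaturation contrast Q (%). Default: Q = 100 / sensitivity.
    """

    slope_crf: float
    amplitude: float = 1.0
    semisaturation_rule: Callable[[ArrayLike], NDArray] = field(
        default=None, repr=False, compare=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not np.isfinite(self.slope_crf) or self.slope_crf <= 0:
            raise ValueError(f"slope_crf must be > 0, got {self.slope_crf!r}")
        if self.semisaturation_rule is None:
            object.__setattr__(self, "semisaturation_rule",
                               _threshold_semisaturation)


def _threshold_semisaturation(sensitivity: ArrayLike) -> NDArray:
    """Default rule: Q = 100 / sensitivity, sensitivity floored at eps."""
    s = np.maximum(np.asarray(sensitivity, dtype=float), SENSITIVITY_EPS)
    return 100.0 / s


@dataclass(frozen=True)
class NcsfParams:
    """A cortical location's full model: CSF + CRF + additive baseline."""

    csf: CsfParams
    crf: CrfParams
    baseline: float = 0.0


@dataclass(frozen=True)
class AucResult:
    """Area under the clamped log10 CSF and its percent-of-standard form."""

    auc_raw: float
    auc_normalized: float
    clamped: bool = False


def standard_csf_params() -> CsfParams:
    """The standard healthy-control reference CSF."""
    cs_p, sf_p, width_l, width_r = STANDARD_CSF
    return CsfParams(cs_p=cs_p, sf_p=sf_p, width_r=width_r, width_l=width_l)


def csf_sensitivity(params: CsfParams, sf: ArrayLike) -> NDArray | float:
    """Contrast sensitivity at spatial frequency ``sf`` (c/deg).

    Uses the left-branch width below the peak and the right-branch width at
    or above it; continuous at the peak, where the value is exactly
    ``cs_p``.
    """
    sf_arr = np.asarray(sf, dtype=float)
    if np.any(~np.isfinite(sf_arr)) or np.any(sf_arr <= 0):
        raise ValueError("spatial frequency must be finite and > 0")
    dlog = np.log10(sf_arr) - np.log10(params.sf_p)
    width = np.where(sf_arr < params.sf_p, params.width_l, params.width_r)
    out = 10.0 ** (np.log10(params.cs_p) - dlog**2 * width**2)
    return out if out.ndim else float(out)


def crf_response(contrast: ArrayLike, q: float, Q: ArrayLike,
                 a: float = 1.0) -> NDArray | float:
    """Naka-Rushton response ``a * C**q / (C**q + Q**q)``.

    Monotone nondecreasing in contrast, bounded in [0, a); exactly a/2 at
    C = Q and 0 at C = 0 (no singularity).
    """
    c = np.asarray(contrast, dtype=float)
    if np.any(c < 0):
        raise ValueError("contrast must be >= 0")
    q = float(q)
    Q_arr = np.asarray(Q, dtype=float)
    if q <= 0 or np.any(Q_arr <= 0):
        raise ValueError("q and Q must be > 0")
    # Work in a ratio form that is stable for very large C**q.
    with np.errstate(divide="ignore"):
        ratio = (Q_arr / np.where(c > 0, c, 1.0)) ** q
    out = np.where(c > 0, a / (1.0 + ratio), 0.0)
    return out if out.ndim else float(out)


def semisaturation_from_csf(params: CsfParams, sf: ArrayLike,
                            rule: Callable[[ArrayLike], NDArray] | None = None,
                            ) -> NDArray | float:
    """Semisaturation contrast Q (%) implied by the CSF at ``sf``.

    Default rule: Q = 100 / sensitivity — the CSF threshold contrast, so
    the CRF is at half response exactly at threshold. Q grows as
    sensitivity falls.
    """
    sens = csf_sensitivity(params, sf)
    rule = rule or _threshold_semisaturation
    out = rule(sens)
    out = np.asarray(out, dtype=float)
    return out if out.ndim else float(out)


def ncsf_response(params: NcsfParams, sf: ArrayLike, contrast: ArrayLike,
                  ) -> NDArray | float:
    """Pre-HRF neural response to a (sf, contrast) stimulus condition.

    Composes the CSF-implied semisaturation with the Naka-Rushton CRF;
    returns 0 at zero contrast. The baseline is *not* added here — it is an
    additive offset of the measured signal, applied in the forward model.
    """
    Q = semisaturation_from_csf(params.csf, sf,
                                rule=params.crf.semisaturation_rule)
    return crf_response(contrast, params.crf.slope_crf, Q,
                        params.crf.amplitude)


def auc_normalized(params: CsfParams,
                   sf_lo: float = AUC_INTERVAL[0],
                   sf_hi: float = AUC_INTERVAL[1],
                   n_points: int = AUC_GRID_POINTS) -> AucResult:
    """Normalized area under the log10 CSF over [sf_lo, sf_hi] c/deg.

    Trapezoid integration of ``max(0, log10 f(SF))`` over log10 SF on a
    fixed log-spaced grid, divided by the same integral for the standard
    reference CSF and expressed in percent (the reference maps to 100).
    Sensitivities at or below 1 contribute zero area (clamping).
    """
    if not (0 < sf_lo < sf_hi):
        raise ValueError(f"need 0 < sf_lo < sf_hi, got ({sf_lo}, {sf_hi})")
    raw, clamped = _auc_raw(params, sf_lo, sf_hi, n_points)
    ref, _ = _auc_raw(standard_csf_params(), sf_lo, sf_hi, n_points)
    return AucResult(auc_raw=raw, auc_normalized=100.0 * raw / ref,
                     clamped=clamped)


def _auc_raw(params: CsfParams, sf_lo: float, sf_hi: float,
             n_points: int) -> tuple[float, bool]:
    sf = np.logspace(np.log10(sf_lo), np.log10(sf_hi), n_points)
    logs = np.log10(csf_sensitivity(params, sf))
    clamped = bool(np.any(logs < 0))
    area = float(np.trapezoid(np.maximum(logs, 0.0), np.log10(sf)))
    return area, clamped
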