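"""Minimal BOLD time-series preprocessing: DCT detrending and percent
signal change.

The inputs are assumed to be already motion/distortion corrected; only the
final two steps of the pipeline are implemented here. Low-frequency drift
is removed by demeaning and projecting out the first three non-constant
discrete-cosine basis vectors (orthonormal DCT-II convention; the mean is
handled separately, matching "demeaning" as its own step). Percent signal
change divides by the per-unit mean of the *raw* series, computed before
detrending — detrended series have near-zero mean, which would make PSC
undefined.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
from numpy.typing import NDArray

__all__ = ["TimeSeriesMatrix", "dct_basis", "detrend_dct",
           "to_percent_signal_change", "preprocess", "average_runs"]


@dataclass
class TimeSeriesMatrix:
    """Units x volumes data with identifiers, TR and an inclusion mask."""

    values: NDArray
    tr: float
    unit_ids: NDArray | None = None
    space: str = "table"  # volume | surface | table
    mask: NDArray | None = None
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.tr <= 0:
            raise ValueError("tr must be > 0")
        n = self.values.shape[0]
        if self.unit_ids is None:
            self.unit_ids = np.arange(n)
        if self.mask is None:
            self.mask = np.ones(n, dtype=bool)

    @property
    def n_units(self) -> int:
        return self.values.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.values.shape[1]


def dct_basis(n_volumes: int, n_components: int) -> NDArray:
    """First ``n_components`` non-constant orthonormal DCT-II vectors.

    Column k (1-based frequency) is sqrt(2/N) * cos(pi * k * (t + 1/2) / N);
    all columns are unit norm and orthogonal to the constant.
    """
    t = np.arange(n_volumes)
    k = np.arange(1, n_components + 1)
    return np.sqrt(2.0 / n_volumes) * np.cos(
        np.pi * np.outer(t + 0.5, k) / n_volumes)


def detrend_dct(ts: TimeSeriesMatrix, n_remove: int = 3) -> TimeSeriesMatrix:
    """Demean each unit and project out the lowest DCT frequencies.

    The output is orthogonal to the removed regressors and has zero mean.
    """
    if ts.n_volumes <= n_remove:
        raise ValueError(
            f"series of {ts.n_volumes} volumes too short to remove "
            f"{n_remove} DCT components")
    X = ts.values - ts.values.mean(axis=1, keepdims=True)
    B = dct_basis(ts.n_volumes, n_remove)  # orthonormal columns
    detrended = X - (X @ B) @ B.T
    return TimeSeriesMatrix(values=detrended, tr=ts.tr, unit_ids=ts.unit_ids,
                            space=ts.space, mask=ts.mask.copy(),
                            meta={**ts.meta, "detrend_dct": n_remove})


def to_percent_signal_change(ts: TimeSeriesMatrix,
                             mean: NDArray | None = None,
                             ) -> TimeSeriesMatrix:
    """Convert to percent signal change: 100 * (x - mean) / mean.

    ``mean`` defaults to the per-unit mean of ``ts`` itself; pass the raw
    mean when converting an already-detrended series. Units with a
    nonpositive mean cannot be scaled; they are masked out and set to NaN.
    """
    m = ts.values.mean(axis=1) if mean is None else np.asarray(mean, float)
    bad = ~(m > 0)
    safe = np.where(bad, 1.0, m)
    psc = 100.0 * (ts.values - m[:, None]) / safe[:, None]
    psc[bad] = np.nan
    mask = ts.mask & ~bad
    return TimeSeriesMatrix(values=psc, tr=ts.tr, unit_ids=ts.unit_ids,
                            space=ts.space, mask=mask,
                            meta={**ts.meta, "psc": True,
                                  "psc_excluded": int(bad.sum())})


def preprocess(ts: TimeSeriesMatrix, n_remove: int = 3) -> TimeSeriesMatrix:
    """Detrend then convert to PSC using the pre-detrend mean.

    The detrended series is already zero-mean, so PSC here is
    100 * detrended / raw_mean (no second mean subtraction).
    """
    raw_mean = ts.values.mean(axis=1)
    detrended = detrend_dct(ts, n_remove)
    bad = ~(raw_mean > 0)
    safe = np.where(bad, 1.0, raw_mean)
    vals = 100.0 * detrended.values / safe[:, None]
    vals[bad] = np.nan
    return TimeSeriesMatrix(values=vals, tr=ts.tr, unit_ids=ts.unit_ids,
                            space=ts.space, mask=detrended.mask & ~bad,
                            meta={**detrended.meta, "psc": True,
                                  "psc_excluded": int(bad.sum())})


def average_runs(runs: list[TimeSeriesMatrix]) -> TimeSeriesMatrix:
    """Average time-locked runs of identical shape."""
    shapes = {r.values.shape for r in runs}
    trs = {r.tr for r in runs}
    if len(shapes) != 1 or len(trs) != 1:
        raise ValueError("runs must share shape and TR")
    first = runs[0]
    mean = np.mean([r.values for r in runs], axis=0)
    mask = np.logical_and.reduce([r.mask for r in runs])
    return TimeSeriesMatrix(values=mean, tr=first.tr,
                            unit_ids=first.unit_ids, space=first.space,
                            mask=mask, meta={"n_runs": len(runs)})
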