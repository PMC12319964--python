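"""Stimulus design: the grating protocol as a per-volume (SF, contrast) sequence.

The default protocol presents sinewave gratings at six spatial frequencies
(0.5, 1, 3, 6, 12, 18 c/deg). Each spatial frequency appears in one
ascending-contrast and one descending-contrast block of 18 s (12 volumes at
TR = 1.5 s, one contrast level per volume). A 15 s mean-luminance blank
(10 volumes) precedes every pair of stimulus blocks and one extra blank
ends the run: 12 stimulus blocks + 7 blanks = 214 volumes = 321 s.

Twelve Michelson contrasts in 0.25-80% are shown per block; the per-SF
contrast grid adapts to the standard CSF so that sampling straddles the
expected threshold (log-spaced from max(0.25, threshold/4) to 80%). Block
order is a fixed seed-reproducible permutation recorded in the metadata.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .config import RunConfig
from .csf import csf_sensitivity, standard_csf_params

__all__ = ["StimulusDesign", "build_design", "contrast_grid",
           "read_design", "write_design", "DesignError"]

BLANK_LABEL = "blank"


class DesignError(ValueError):
    """Invalid stimulus-design configuration or file."""


@dataclass
class StimulusDesign:
    """Per-volume stimulus sequence plus timing metadata.

    sf_seq and contrast_seq are 0 for mean-luminance (blank) volumes;
    block_labels identify the block and contrast direction per volume.
    """

    tr: float
    sf_seq: NDArray
    contrast_seq: NDArray
    block_labels: list[str]
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.sf_seq = np.asarray(self.sf_seq, dtype=float)
        self.contrast_seq = np.asarray(self.contrast_seq, dtype=float)
        n = len(self.sf_seq)
        if len(self.contrast_seq) != n or len(self.block_labels) != n:
            raise DesignError("sf_seq, contrast_seq and block_labels must "
                              "have equal length")
        if np.any(self.contrast_seq < 0):
            raise DesignError("negative contrast in design")
        blank_sf = self.sf_seq == 0
        blank_c = self.contrast_seq == 0
        if not np.array_equal(blank_sf, blank_c):
            raise DesignError("contrast 0 must coincide with sf 0 (blank)")

    @property
    def n_volumes(self) -> int:
        return len(self.sf_seq)

    @property
    def duration(self) -> float:
        """Total run duration in seconds."""
        return self.n_volumes * self.tr

    def stimulus_blocks(self) -> dict[str, NDArray]:
        """Map block label -> volume indices, stimulus blocks only."""
        out: dict[str, list[int]] = {}
        for i, lab in enumerate(self.block_labels):
            if lab != BLANK_LABEL:
                out.setdefault(lab, []).append(i)
        return {k: np.asarray(v) for k, v in out.items()}


def contrast_grid(sf: float, config: RunConfig | None = None,
                  ) -> NDArray:
    """Twelve increasing Michelson contrasts (%) for a stimulus block.

    Default rule: log-spaced from max(lower_range, threshold(sf)/4) to the
    upper range limit (80%), where threshold(sf) = 100 / standard-CSF
    sensitivity. Values outside the configured range are clipped (recorded
    by the caller). Low-SF blocks therefore start near 0.25% while high-SF
    blocks, whose thresholds are higher, start higher.
    """
    config = config or RunConfig()
    lo_lim, hi_lim = config.contrast_range
    thr = 100.0 / float(csf_sensitivity(standard_csf_params(), sf))
    lo = max(lo_lim, thr / 4.0)
    grid = np.logspace(np.log10(lo), np.log10(hi_lim), config.n_contrasts)
    return np.clip(grid, lo_lim, hi_lim)


def build_design(config: RunConfig | None = None) -> StimulusDesign:
    """Build the default block protocol as a :class:`StimulusDesign`.

    Raises :class:`DesignError` if the TR does not evenly divide the block
    or blank durations.
    """
    config = config or RunConfig()
    tr = config.tr
    n_block = config.block_duration / tr
    n_blank = config.blank_duration / tr
    if abs(n_block - round(n_block)) > 1e-9 or abs(n_blank - round(n_blank)) > 1e-9:
        raise DesignError(
            f"TR {tr} s must evenly divide block ({config.block_duration} s) "
            f"and blank ({config.blank_duration} s) durations")
    n_block, n_blank = int(round(n_block)), int(round(n_blank))
    if n_block != config.n_contrasts:
        raise DesignError(
            f"block holds {n_block} volumes but {config.n_contrasts} "
            "contrasts are configured (one contrast per volume)")

    # One ascending and one descending block per SF, in a fixed
    # seed-reproducible pseudo-random order.
    blocks = [(sf, d) for sf in config.sfs for d in ("asc", "desc")]
    rng = np.random.default_rng(config.order_seed)
    order = rng.permutation(len(blocks))
    ordered = [blocks[i] for i in order]

    grids = {sf: contrast_grid(sf, config) for sf in config.sfs}
    clipped = sorted(sf for sf, g in grids.items()
                     if g[0] <= config.contrast_range[0])

    sf_seq: list[float] = []
    contrast_seq: list[float] = []
    labels: list[str] = []

    def add_blank() -> None:
        sf_seq.extend([0.0] * n_blank)
        contrast_seq.extend([0.0] * n_blank)
        labels.extend([BLANK_LABEL] * n_blank)

    for i, (sf, direction) in enumerate(ordered):
        if i % 2 == 0:  # blank before every pair of stimulus blocks
            add_blank()
        g = grids[sf]
        contrasts = g if direction == "asc" else g[::-1]
        sf_seq.extend([sf] * n_block)
        contrast_seq.extend(contrasts.tolist())
        labels.extend([f"sf{sf:g}:{direction}"] * n_block)
    add_blank()  # closing blank

    metadata = {
        "tr": tr,
        "sfs": list(config.sfs),
        "n_contrasts": config.n_contrasts,
        "contrast_range": list(config.contrast_range),
        "grid_rule": "log-spaced from max(range_lo, standard-threshold/4) "
                     "to range_hi",
        "order_seed": config.order_seed,
        "block_order": [f"sf{sf:g}:{d}" for sf, d in ordered],
        "clipped_lower_bound_sfs": clipped,
    }
    return StimulusDesign(tr=tr, sf_seq=np.array(sf_seq),
                          contrast_seq=np.array(contrast_seq),
                          block_labels=labels, metadata=metadata)


def write_design(design: StimulusDesign, path: str | Path) -> None:
    """Write a design as TSV (volume, sf_cpd, contrast_pct) + JSON sidecar.

    The sidecar (``<path>.json``) carries tr, block labels and metadata so
    a read round-trips exactly.
    """
    path = Path(path)
    df = pd.DataFrame({
        "volume": np.arange(design.n_volumes),
        "sf_cpd": design.sf_seq,
        "contrast_pct": design.contrast_seq,
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    sidecar = {"tr": design.tr, "block_labels": design.block_labels,
               "metadata": design.metadata}
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_design(path: str | Path, tr: float | None = None) -> StimulusDesign:
    """Read a design TSV (+ optional JSON sidecar) written by write_design.

    Without a sidecar, ``tr`` must be given and block labels are
    reconstructed by scanning for contiguous same-SF stimulus runs.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    required = {"volume", "sf_cpd", "contrast_pct"}
    missing = required - set(df.columns)
    if missing:
        raise DesignError(f"design file missing columns: {sorted(missing)}")
    for row, c in zip(df["volume"], df["contrast_pct"]):
        if c < 0:
            raise DesignError(f"negative contrast at volume {int(row)}")

    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        sidecar = json.loads(sidecar_path.read_text())
        tr = sidecar["tr"]
        labels = sidecar["block_labels"]
        metadata = sidecar.get("metadata", {})
    else:
        if tr is None:
            raise DesignError("no JSON sidecar found; tr must be provided")
        labels = _scan_block_labels(df["sf_cpd"].to_numpy(),
                                    df["contrast_pct"].to_numpy())
        metadata = {"source": str(path)}
    return StimulusDesign(tr=tr, sf_seq=df["sf_cpd"].to_numpy(),
                          contrast_seq=df["contrast_pct"].to_numpy(),
                          block_labels=labels, metadata=metadata)


def _scan_block_labels(sf_seq: NDArray, contrast_seq: NDArray) -> list[str]:
    """Label volumes by contiguous same-SF runs; direction from contrast.

    An ascending and a descending block of the same SF may be adjacent
    (they form a pair between blanks), so a same-SF run is split where the
    contrast sequence reverses direction.
    """
    labels: list[str] = []
    i, n = 0, len(sf_seq)
    while i < n:
        sf = sf_seq[i]
        j = i
        while j < n and sf_seq[j] == sf:
            j += 1
        if sf == 0:
            labels.extend([BLANK_LABEL] * (j - i))
        else:
            for seg in _split_on_reversal(contrast_seq[i:j]):
                direction = "asc" if seg[-1] >= seg[0] else "desc"
                labels.extend([f"sf{sf:g}:{direction}"] * len(seg))
        i = j
    return labels


def _split_on_reversal(contrasts: NDArray) -> list[NDArray]:
    """Split a contrast run where its monotonic direction flips."""
    if len(contrasts) < 3:
        return [contrasts]
    diffs = np.diff(contrasts)
    sign0 = np.sign(diffs[0]) or 1.0
    flips = np.flatnonzero(np.sign(diffs) != sign0)
    if flips.size == 0:
        return [contrasts]
    cut = int(flips[0]) + 1
    return [contrasts[:cut]] + _split_on_reversal(contrasts[cut:])
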