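"""Readers and writers: NIfTI/GIFTI/TSV time series, fit tables, maps.

NIfTI 4D volumes are flattened to in-mask voxels x time; GIFTI functional
files are stacked vertex arrays; delimited text holds one unit per row.
Fit tables round-trip through TSV, and fitted parameters can be written
back as 3D NIfTI maps (preserving the source affine and header geometry)
or GIFTI shape files.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable

import nibabel as nib
import numpy as np
import pandas as pd
from numpy.typing import NDArray

from .preproc import TimeSeriesMatrix

__all__ = ["read_timeseries", "write_timeseries_tsv", "write_results",
           "read_results", "write_nifti_maps", "write_gifti_maps",
           "write_provenance"]

RESULT_COLUMNS = ["unit_id", "sf_p", "cs_p", "width_r", "slope_crf",
                  "amplitude", "baseline", "rss", "r2", "auc_normalized",
                  "included"]


def read_timeseries(path: str | Path, tr: float | None = None,
                    mask: str | Path | None = None) -> TimeSeriesMatrix:
    """Read a units x time matrix from NIfTI, GIFTI or delimited text.

    NIfTI: a 4D image; ``mask`` (3D image of the same grid) selects the
    voxels, otherwise all voxels are used. TR defaults to the header's
    time step. GIFTI: one data array per time point. Text (.tsv/.csv/.txt):
    one unit per row, an optional leading ``unit_id`` column; ``tr`` is
    then required.
    """
    path = Path(path)
    suffixes = "".join(path.suffixes)
    if ".nii" in suffixes:
        return _read_nifti(path, tr, mask)
    if ".gii" in suffixes:
        return _read_gifti(path, tr)
    return _read_table(path, tr)


def _read_nifti(path: Path, tr: float | None,
                mask_path: str | Path | None) -> TimeSeriesMatrix:
    img = nib.load(path)
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D NIfTI series, got shape {data.shape}")
    if mask_path is not None:
        mask_img = nib.load(mask_path)
        mask = np.asanyarray(mask_img.dataobj).astype(bool)
        if mask.shape != data.shape[:3]:
            raise ValueError(
                f"mask shape {mask.shape} does not match data grid "
                f"{data.shape[:3]}")
    else:
        mask = np.ones(data.shape[:3], dtype=bool)
    if tr is None:
        tr = float(img.header.get_zooms()[3])
    values = data[mask]  # (n_voxels, time)
    return TimeSeriesMatrix(values=values, tr=tr,
                            unit_ids=np.flatnonzero(mask.ravel()),
                            space="volume",
                            meta={"source": str(path), "affine": img.affine,
                                  "header": img.header,
                                  "grid_shape": data.shape[:3],
                                  "voxel_mask": mask})


def _read_gifti(path: Path, tr: float | None) -> TimeSeriesMatrix:
    img = nib.load(path)
    values = np.column_stack([d.data for d in img.darrays]).astype(float)
    if tr is None:
        raise ValueError("tr must be provided for GIFTI input")
    return TimeSeriesMatrix(values=values, tr=tr, space="surface",
                            meta={"source": str(path)})


def _read_table(path: Path, tr: float | None) -> TimeSeriesMatrix:
    if tr is None:
        raise ValueError("tr must be provided for delimited-text input")
    sep = "," if path.suffix == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    if "unit_id" in df.columns:
        unit_ids = df["unit_id"].to_numpy()
        values = df.drop(columns="unit_id").to_numpy(dtype=float)
    else:
        unit_ids = np.arange(len(df))
        values = df.to_numpy(dtype=float)
    return TimeSeriesMatrix(values=values, tr=tr, unit_ids=unit_ids,
                            space="table", meta={"source": str(path)})


def write_timeseries_tsv(ts: TimeSeriesMatrix, path: str | Path) -> None:
    df = pd.DataFrame(ts.values,
                      columns=[f"t{i}" for i in range(ts.n_volumes)])
    df.insert(0, "unit_id", ts.unit_ids)
    df.to_csv(path, sep="\t", index=False)


def write_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write a fit table as TSV with the canonical column order."""
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    cols += [c for c in results.columns if c not in cols]
    results[cols].to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_nifti_maps(results: pd.DataFrame, ts: TimeSeriesMatrix,
                     out_dir: str | Path,
                     columns: Iterable[str] = ("sf_p", "cs_p", "width_r",
                                               "slope_crf", "r2",
                                               "auc_normalized"),
                     ) -> list[Path]:
    """Write per-parameter 3D NIfTI maps in the source volume geometry."""
    if ts.space != "volume" or "affine" not in ts.meta:
        raise ValueError("parameter maps need a NIfTI-sourced time series")
    mask = ts.meta["voxel_mask"]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for col in columns:
        vol = np.full(ts.meta["grid_shape"], np.nan, dtype=float)
        vol[mask] = results[col].to_numpy()
        img = nib.Nifti1Image(vol, ts.meta["affine"])
        img.header.set_zooms(ts.meta["header"].get_zooms()[:3])
        out = out_dir / f"{col}.nii"
        nib.save(img, out)
        written.append(out)
    return written


def write_gifti_maps(results: pd.DataFrame, out_dir: str | Path,
                     columns: Iterable[str] = ("sf_p", "cs_p", "width_r",
                                               "slope_crf", "r2",
                                               "auc_normalized"),
                     ) -> list[Path]:
    """Write per-parameter GIFTI shape files (one scalar per vertex)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for col in columns:
        arr = nib.gifti.GiftiDataArray(
            results[col].to_numpy(dtype=np.float32))
        img = nib.gifti.GiftiImage(darrays=[arr])
        out = out_dir / f"{col}.shape.gii"
        nib.save(img, out)
        written.append(out)
    return written


def write_provenance(out_dir: str | Path, config: dict, seed: int | None,
                     ) -> Path:
    """Record config hash, seed and package version next to the outputs."""
    from . import __version__
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(config, sort_keys=True, default=str)
    record = {"config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
              "config": json.loads(json.dumps(config, default=str)),
              "seed": seed, "version": __version__}
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2))
    return path
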