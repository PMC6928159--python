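"""Slice-wise reduction: ROI means per nerve cross-section and outlier rules.

The unit of analysis downstream is the slice: each axial cross-section of a
nerve is labeled proximal / injury / distal relative to the injury zone and
summarized by the arithmetic mean of each scalar index over its ROI voxels.
Slices with RD > 1 um^2/ms, RK < 0 or RK > 2 are treated as outliers
(strict inequalities; boundary values are retained).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "REGIONS",
    "SLICE_COLUMNS",
    "label_slices",
    "aggregate_slices",
    "filter_outliers",
]

REGIONS = ("proximal", "injury", "distal")

#: canonical slice-record column schema (version 1)
SLICE_COLUMNS = [
    "animal_id", "cohort", "week", "region", "slice_index",
    "fa", "md", "ad", "rd", "mk", "ak", "rk", "n_voxels",
]
SLICE_SCHEMA_VERSION = 1


def label_slices(n_slices: int, injury_start: int, injury_end: int) -> np.ndarray:
    """Region label per slice index along the nerve axis.

    The injury zone is the 0-based inclusive interval
    ``[injury_start, injury_end]``; earlier slices are proximal, later ones
    distal.
    """
    if not (0 <= injury_start <= injury_end < n_slices):
        raise ValueError(
            f"invalid injury interval [{injury_start}, {injury_end}] "
            f"for {n_slices} slices"
        )
    labels = np.empty(n_slices, dtype=object)
    labels[:injury_start] = "proximal"
    labels[injury_start : injury_end + 1] = "injury"
    labels[injury_end + 1 :] = "distal"
    return labels


def aggregate_slices(
    maps: dict[str, np.ndarray],
    roi_mask: np.ndarray,
    labels: np.ndarray,
    animal_id: str = "",
    cohort: str = "",
    week: int = 0,
) -> pd.DataFrame:
    """Reduce 3-D scalar maps to one mean record per slice.

    The slice axis is the third image axis.  Flagged / NaN voxels are
    excluded from the means; slices with no valid ROI voxel are omitted
    (and logged).
    """
    roi_mask = np.asarray(roi_mask, dtype=bool)
    index_names = [k for k in maps if k != "flag"]
    for k in index_names:
        if maps[k].shape != roi_mask.shape:
            raise ValueError(
                f"map {k!r} shape {maps[k].shape} != mask {roi_mask.shape}"
            )
    n_slices = roi_mask.shape[2]
    if len(labels) != n_slices:
        raise ValueError(f"{len(labels)} labels for {n_slices} slices")
    rows = []
    for z in range(n_slices):
        sl_mask = roi_mask[:, :, z]
        valid = sl_mask & np.isfinite(maps[index_names[0]][:, :, z])
        n_valid = int(valid.sum())
        if n_valid == 0:
            logger.info("slice %d omitted: no valid ROI voxels", z)
            continue
        row = {
            "animal_id": animal_id,
            "cohort": cohort,
            "week": week,
            "region": labels[z],
            "slice_index": z,
            "n_voxels": n_valid,
        }
        for k in index_names:
            row[k] = float(np.nanmean(maps[k][:, :, z][valid]))
        rows.append(row)
    df = pd.DataFrame(rows)
    cols = [c for c in SLICE_COLUMNS if c in df.columns]
    return df[cols] if len(df) else df


def filter_outliers(
    records: pd.DataFrame,
    rd_max: float = 1.0,
    rk_min: float = 0.0,
    rk_max: float = 2.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split records into (kept, excluded) by the slice outlier rules.

    A record is excluded iff RD > ``rd_max`` um^2/ms, RK < ``rk_min``, or
    RK > ``rk_max`` — all strict, so boundary values survive.  NaN kurtosis
    does not trigger the RK rules.  Exclusion reasons are logged per record.
    """
    for col in ("rd", "rk"):
        if col not in records.columns:
            raise KeyError(f"records lack required column {col!r}")
    rd = records["rd"].to_numpy(dtype=float)
    rk = records["rk"].to_numpy(dtype=float)
    bad_rd = rd > rd_max
    with np.errstate(invalid="ignore"):
        bad_rk = (rk < rk_min) | (rk > rk_max)
    bad_rk &= np.isfinite(rk)
    excluded_mask = bad_rd | bad_rk
    for i in np.nonzero(excluded_mask)[0]:
        reasons = []
        if bad_rd[i]:
            reasons.append(f"RD={rd[i]:.3f} > {rd_max}")
        if bad_rk[i]:
            reasons.append(f"RK={rk[i]:.3f} outside ({rk_min}, {rk_max})")
        logger.info("record %s excluded: %s", records.index[i], "; ".join(reasons))
    return records[~excluded_mask], records[excluded_mask]
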