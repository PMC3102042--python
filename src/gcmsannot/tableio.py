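"""Aligned-peak-table CSV I/O and the organized output matrix.

Input dialect (one row per aligned mass signal, modeled on the CSV export of
alignment preprocessing software):

    rt_sec, mz, <sample_1>, ..., <sample_n>

Signals close in retention time are clustered into peaks; each peak carries a
reconstructed spectrum (per-mass intensity averaged over samples, then
normalized to base peak 100) and per-sample heights taken at the base-peak
m/z, the quantifier-ion convention.

Output: the "organized data matrix" -- one row per peak with its status
(identified / annotated / unknown), the compound name or chemical class, the
match score (DOC or p-value), and every sample height.  No cell is ever
empty: unknowns are retained as first-class rows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .identify import AlignedPeak
from .spectra import MZ_MAX_DEFAULT, MZ_MIN_DEFAULT, MassSpectrum, normalize_spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "PeakTable",
    "AnnotationReport",
    "PeakTableParseError",
    "read_peak_csv",
    "write_peak_csv",
    "group_signals_into_peaks",
    "write_organized_matrix",
    "read_organized_matrix",
]

PEAK_CSV_FIXED_COLUMNS = ("rt_sec", "mz")


class PeakTableParseError(ValueError):
    """Malformed peak-table CSV (bad header or non-numeric cell)."""


@dataclass(frozen=True)
class PeakTable:
    """Aligned peaks for one batch, ascending RT, no missing heights."""

    sample_names: tuple[str, ...]
    peaks: tuple[AlignedPeak, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "sample_names", tuple(self.sample_names))
        object.__setattr__(self, "peaks", tuple(self.peaks))
        n = len(self.sample_names)
        rts = [p.rt for p in self.peaks]
        if any(b < a for a, b in zip(rts, rts[1:])):
            raise ValueError("peaks must be sorted by ascending RT")
        for p in self.peaks:
            if p.heights.shape != (n,):
                raise ValueError(
                    f"{p.peak_id}: {p.heights.shape[0]} heights for {n} samples"
                )

    def __len__(self) -> int:
        return len(self.peaks)


@dataclass(frozen=True)
class AnnotationReport:
    """Final per-peak outcome of the pipeline."""

    peak_id: str
    status: str  # "identified" | "annotated" | "unknown"
    label: str  # compound name, class name, or "unknown"
    score: float  # DOC for identified, p-value otherwise

    def __post_init__(self) -> None:
        if self.status not in ("identified", "annotated", "unknown"):
            raise ValueError(f"bad status {self.status!r}")


def read_peak_csv(path) -> tuple[pd.DataFrame, list[str]]:
    """Parse the signal-level peak CSV.

    Returns (rows, sample_names).  Rows hold float rt_sec, integer mz and one
    non-negative intensity column per sample.  Malformed cells are rejected
    with their row and column named.
    """
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    cols = list(df.columns)
    if cols[: len(PEAK_CSV_FIXED_COLUMNS)] != list(PEAK_CSV_FIXED_COLUMNS):
        raise PeakTableParseError(
            f"{path}: header must start with {PEAK_CSV_FIXED_COLUMNS}, got {cols[:2]}"
        )
    sample_names = cols[len(PEAK_CSV_FIXED_COLUMNS):]
    if not sample_names:
        raise PeakTableParseError(f"{path}: no sample columns after rt_sec, mz")
    out = pd.DataFrame(index=df.index)
    for col in cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.index[vals.isna()]
        if len(bad):
            row = int(bad[0]) + 2  # 1-based, counting the header line
            raise PeakTableParseError(
                f"{path}: non-numeric value {df[col][bad[0]]!r} at line {row}, column {col!r}"
            )
        out[col] = vals
    if (out["rt_sec"] < 0).any():
        raise PeakTableParseError(f"{path}: negative retention time")
    if (out[sample_names].to_numpy() < 0).any():
        raise PeakTableParseError(f"{path}: negative intensity")
    frac, _ = np.modf(out["mz"].to_numpy())
    if np.any(frac != 0):
        raise PeakTableParseError(f"{path}: non-integer m/z value")
    out["mz"] = out["mz"].astype(int)
    return out, sample_names


def write_peak_csv(rows: pd.DataFrame, path) -> None:
    """Write signal rows back in the documented dialect."""
    cols = list(PEAK_CSV_FIXED_COLUMNS) + [
        c for c in rows.columns if c not in PEAK_CSV_FIXED_COLUMNS
    ]
    rows[cols].to_csv(path, index=False, float_format="%.10g")


def group_signals_into_peaks(
    rows: pd.DataFrame,
    sample_names: Sequence[str],
    rt_tolerance: float = 1.5,
    mz_min: int = MZ_MIN_DEFAULT,
    mz_max: int = MZ_MAX_DEFAULT,
    height_mode: str = "base_peak",
) -> PeakTable:
    """Cluster mass signals into aligned peaks.

    Single-pass centroid linkage in RT order: a signal joins the open cluster
    when it lies within ``rt_tolerance`` seconds of the cluster's
    intensity-weighted RT centroid, else it opens a new cluster.  Per peak,
    each member mass's intensity is averaged across samples to reconstruct
    the spectrum (then normalized); the per-sample heights are read at the
    base-peak m/z (``height_mode="base_peak"``, the quantifier-ion
    convention) or summed over all member masses (``height_mode="sum"``);
    the peak RT is the intensity-weighted mean of member RTs.
    """
    if height_mode not in ("base_peak", "sum"):
        raise ValueError(f"height_mode must be 'base_peak' or 'sum', got {height_mode!r}")
    sample_names = list(sample_names)
    rows = rows.sort_values("rt_sec", kind="stable").reset_index(drop=True)
    rts = rows["rt_sec"].to_numpy(float)
    mzs = rows["mz"].to_numpy(int)
    inten = rows[sample_names].to_numpy(float)
    mean_inten = inten.mean(axis=1)

    clusters: list[list[int]] = []
    centroid = weight = 0.0
    for i in range(len(rows)):
        w = max(mean_inten[i], 1e-12)
        if clusters and abs(rts[i] - centroid) <= rt_tolerance:
            clusters[-1].append(i)
            weight += w
            centroid += (rts[i] - centroid) * w / weight
        else:
            clusters.append([i])
            centroid, weight = rts[i], w

    peaks = []
    for k, members in enumerate(clusters):
        spec_vec = np.zeros(mz_max - mz_min + 1)
        best_row: dict[int, int] = {}  # mz bin -> row index currently kept
        for i in members:
            mz = mzs[i]
            if not mz_min <= mz <= mz_max:
                logger.warning(
                    "dropping out-of-range m/z %d at rt %.2f s", mz, rts[i]
                )
                continue
            b = mz - mz_min
            if b in best_row:
                logger.warning(
                    "duplicate m/z %d within one peak cluster at rt %.2f s; "
                    "keeping the more intense signal (possible deconvolution issue)",
                    mz,
                    rts[i],
                )
                if mean_inten[i] <= spec_vec[b]:
                    continue
            best_row[b] = i
            spec_vec[b] = mean_inten[i]
        if not best_row:
            logger.warning("cluster %d has no in-range masses; skipped", k)
            continue
        spectrum = normalize_spectrum(MassSpectrum(spec_vec, mz_min, mz_max))
        kept = list(best_row.values())
        if height_mode == "sum":
            heights = inten[kept].sum(axis=0)
        else:
            base_bin = int(np.argmax(spec_vec))
            heights = inten[best_row[base_bin]].copy()
        wsum = mean_inten[kept].sum()
        rt = float((rts[kept] * mean_inten[kept]).sum() / wsum) if wsum > 0 else float(
            rts[kept].mean()
        )
        peaks.append(
            AlignedPeak(
                peak_id=f"P{len(peaks) + 1:04d}",
                rt=rt,
                spectrum=spectrum,
                heights=heights,
            )
        )
    peaks.sort(key=lambda p: p.rt)
    return PeakTable(sample_names=tuple(sample_names), peaks=tuple(peaks))


ORGANIZED_FIXED_COLUMNS = ("peak_id", "rt_sec", "status", "annotation", "score")


def write_organized_matrix(
    reports: Sequence[AnnotationReport], table: PeakTable, path
) -> None:
    """Write the organized peak x sample matrix; every cell is filled."""
    if len(reports) != len(table):
        raise ValueError(
            f"{len(reports)} reports for {len(table)} peaks"
        )
    records = []
    for rep, peak in zip(reports, table.peaks):
        if rep.peak_id != peak.peak_id:
            raise ValueError(f"report/peak order mismatch at {rep.peak_id} vs {peak.peak_id}")
        rec = {
            "peak_id": rep.peak_id,
            "rt_sec": peak.rt,
            "status": rep.status,
            "annotation": rep.label,
            "score": rep.score,
        }
        rec.update(dict(zip(table.sample_names, peak.heights)))
        records.append(rec)
    cols = list(ORGANIZED_FIXED_COLUMNS) + list(table.sample_names)
    pd.DataFrame.from_records(records, columns=cols).to_csv(
        path, index=False, float_format="%.10g"
    )


def read_organized_matrix(path) -> pd.DataFrame:
    """Read an organized matrix back; verifies there are no missing cells."""
    df = pd.read_csv(path)
    missing = [c for c in ORGANIZED_FIXED_COLUMNS if c not in df.columns]
    if missing:
        raise PeakTableParseError(f"{path}: missing columns {missing}")
    if df.isna().any().any():
        raise PeakTableParseError(f"{path}: organized matrix contains empty cells")
    return df
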