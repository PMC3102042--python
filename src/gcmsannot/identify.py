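"""Library matching: RT window candidate search + weighted-Pearson DOC.

A peak eluting at time ``rt`` is compared only against reference compounds
whose (corrected) library retention time lies within the closed window
``[rt - c, rt + c]``, where ``c`` is the user-set time-width parameter in
seconds.  Among the candidates, the compound with the highest degree of
coincidence (DOC, the Pearson correlation of mass-weighted spectra) wins;
ties break on smaller |delta RT|, then library file order.  Peaks with no
acceptable candidate are left unidentified and handed to the SIMCA
class-annotation stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .spectra import (
    MassSpectrum,
    SpectrumWeighting,
    UndefinedCorrelationError,
    pearson_doc,
    weight_spectrum,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ReferenceEntry",
    "AlignedPeak",
    "IdentificationResult",
    "candidate_window",
    "identify_peak",
    "identify_all",
    "read_library_csv",
    "write_library_csv",
]


@dataclass(frozen=True)
class ReferenceEntry:
    """A named compound in the reference library."""

    name: str
    rt: float  # seconds
    spectrum: MassSpectrum
    class_label: Optional[str] = None
    cas: Optional[str] = None
    kegg: Optional[str] = None

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError(f"{self.name}: negative retention time {self.rt}")


@dataclass(frozen=True)
class AlignedPeak:
    """One aligned peak: RT, reconstructed spectrum, per-sample heights."""

    peak_id: str
    rt: float
    spectrum: MassSpectrum
    heights: np.ndarray

    def __post_init__(self) -> None:
        h = np.asarray(self.heights, dtype=float)
        object.__setattr__(self, "heights", h)
        if np.any(h < 0):
            raise ValueError(f"{self.peak_id}: negative sample height")


@dataclass(frozen=True)
class IdentificationResult:
    peak_id: str
    status: str  # "identified" | "unidentified"
    match_name: Optional[str] = None
    doc: Optional[float] = None
    delta_rt: Optional[float] = None
    candidates_considered: int = 0

    def __post_init__(self) -> None:
        if self.status == "identified":
            if self.match_name is None or self.doc is None:
                raise ValueError("identified result needs match_name and doc")
            if not -1.0 <= self.doc <= 1.0:
                raise ValueError(f"DOC out of range: {self.doc}")


def candidate_window(
    rt: float, c: float, library: Sequence[ReferenceEntry]
) -> list[ReferenceEntry]:
    """Library entries with |entry.rt - rt| <= c, ascending RT (closed window)."""
    if c <= 0:
        raise ValueError(f"time width c must be > 0, got {c}")
    hits = [e for e in library if abs(e.rt - rt) <= c]
    hits.sort(key=lambda e: e.rt)
    return hits


def identify_peak(
    peak: AlignedPeak,
    library: Sequence[ReferenceEntry],
    c: float,
    w: SpectrumWeighting = SpectrumWeighting(),
    min_doc: float = 0.0,
) -> IdentificationResult:
    """Best-DOC match for one peak within the RT window, or unidentified.

    A candidate whose weighted spectrum has zero variance cannot be
    correlated and is treated as a non-match.
    """
    if not -1.0 <= min_doc <= 1.0:
        raise ValueError(f"min_doc must be in [-1, 1], got {min_doc}")
    candidates = candidate_window(peak.rt, c, library)
    order = {id(e): i for i, e in enumerate(library)}
    peak_vec = weight_spectrum(peak.spectrum, w)

    best: Optional[tuple[float, float, int, ReferenceEntry]] = None
    for entry in candidates:
        try:
            doc = pearson_doc(peak_vec, weight_spectrum(entry.spectrum, w))
        except UndefinedCorrelationError:
            logger.warning(
                "zero-variance weighted spectrum for %s vs %s; treated as non-match",
                peak.peak_id,
                entry.name,
            )
            continue
        # rank: higher DOC, then smaller |dRT|, then library file order
        key = (-doc, abs(entry.rt - peak.rt), order[id(entry)])
        if best is None or key < (-best[0], best[1], best[2]):
            best = (doc, abs(entry.rt - peak.rt), order[id(entry)], entry)

    if best is not None and best[0] >= min_doc:
        doc, drt, _, entry = best
        return IdentificationResult(
            peak_id=peak.peak_id,
            status="identified",
            match_name=entry.name,
            doc=doc,
            delta_rt=drt,
            candidates_considered=len(candidates),
        )
    return IdentificationResult(
        peak_id=peak.peak_id,
        status="unidentified",
        candidates_considered=len(candidates),
    )


def identify_all(
    peaks: Sequence[AlignedPeak],
    library: Sequence[ReferenceEntry],
    c: float,
    w: SpectrumWeighting = SpectrumWeighting(),
    min_doc: float = 0.0,
) -> list[IdentificationResult]:
    """Identify every peak; order-preserving and deterministic.

    A single library compound may legitimately match several peaks (e.g.
    sugar anomers produce multiple chromatographic peaks); duplicates are
    logged rather than forbidden.
    """
    results = [identify_peak(p, library, c, w, min_doc) for p in peaks]
    seen: dict[str, list[str]] = {}
    for r in results:
        if r.status == "identified":
            seen.setdefault(r.match_name, []).append(r.peak_id)
    for name, ids in seen.items():
        if len(ids) > 1:
            logger.info("compound %s matched %d peaks: %s", name, len(ids), ids)
    return results


# ---------------------------------------------------------------------------
# Reference-library CSV: header  name,rt_sec,class,cas,kegg,i85,...,i500
# ---------------------------------------------------------------------------

def _intensity_columns(mz_min: int, mz_max: int) -> list[str]:
    return [f"i{m}" for m in range(mz_min, mz_max + 1)]


def read_library_csv(
    path, mz_min: int = 85, mz_max: int = 500
) -> list[ReferenceEntry]:
    """Read a reference library from CSV.

    Blank class/cas/kegg cells are tolerated; spectra are stored as given
    (relative intensities).
    """
    df = pd.read_csv(path, dtype={"name": str})
    cols = _intensity_columns(mz_min, mz_max)
    missing = [c for c in ["name", "rt_sec", *cols] if c not in df.columns]
    if missing:
        raise ValueError(
            f"{path}: missing library columns {missing[:5]}"
            + (" ..." if len(missing) > 5 else "")
        )
    entries = []
    for _, row in df.iterrows():
        spec = MassSpectrum(row[cols].to_numpy(dtype=float), mz_min, mz_max)

        def opt(key):
            v = row.get(key)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else str(v)

        entries.append(
            ReferenceEntry(
                name=str(row["name"]),
                rt=float(row["rt_sec"]),
                spectrum=spec,
                class_label=opt("class"),
                cas=opt("cas"),
                kegg=opt("kegg"),
            )
        )
    return entries


def write_library_csv(entries: Sequence[ReferenceEntry], path) -> None:
    if not entries:
        raise ValueError("refusing to write an empty library")
    mz_min = entries[0].spectrum.mz_min
    mz_max = entries[0].spectrum.mz_max
    cols = _intensity_columns(mz_min, mz_max)
    records = []
    for e in entries:
        rec = {
            "name": e.name,
            "rt_sec": e.rt,
            "class": e.class_label or "",
            "cas": e.cas or "",
            "kegg": e.kegg or "",
        }
        rec.update(dict(zip(cols, e.spectrum.intensities)))
        records.append(rec)
    pd.DataFrame.from_records(records, columns=["name", "rt_sec", "class", "cas", "kegg", *cols]).to_csv(
        path, index=False, float_format="%.10g"
    )
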