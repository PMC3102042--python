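"""End-to-end orchestration: RT correction -> identification -> annotation.

Stages, in order:

1. read the signal-level peak CSV and cluster signals into aligned peaks;
2. locate each pseudo-internal-standard anchor: the highest-DOC peak within
   a wide window around its library RT;
3. build the monotone RT map from the anchor pairs and update the library;
4. identify every peak by RT window + weighted-Pearson DOC;
5. classify every unidentified peak against the SIMCA class models
   (annotated when a class accepts, unknown otherwise);
6. write the organized peak x sample matrix -- one row per peak, no missing
   cells -- and log the per-category counts.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import yaml

from . import simca
from .identify import (
    ReferenceEntry,
    identify_all,
    read_library_csv,
)
from .rtcorr import Anchor, AnchorSet, build_rt_map, update_library
from .spectra import (
    MZ_MAX_DEFAULT,
    MZ_MIN_DEFAULT,
    SpectrumWeighting,
    UndefinedCorrelationError,
    pearson_doc,
    weight_spectrum,
)
from .tableio import (
    AnnotationReport,
    PeakTable,
    group_signals_into_peaks,
    read_peak_csv,
    write_organized_matrix,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineResult", "AnchorMatchError", "run_pipeline"]


class AnchorMatchError(RuntimeError):
    """A pseudo-internal-standard anchor could not be located in the batch."""


@dataclass
class PipelineConfig:
    """Everything a run needs; loadable from a YAML file."""

    peak_table: Path
    library: Path
    output: Path
    anchors: list[str]
    training: Optional[Path] = None  # training CSV -> models fitted at run time
    models: Optional[Path] = None  # or: pre-fitted serialized models
    time_width_c: float = 2.0  # seconds; the RT search half-window
    anchor_window: Optional[float] = None  # defaults to 5 * time_width_c
    weighting: SpectrumWeighting = field(default_factory=SpectrumWeighting)
    alpha: float = 0.05
    df_convention: str = "paper"
    min_doc: float = 0.0
    rt_tolerance: float = 1.5  # seconds; signal-clustering tolerance
    height_mode: str = "base_peak"  # or "sum": total over member masses
    mz_min: int = MZ_MIN_DEFAULT
    mz_max: int = MZ_MAX_DEFAULT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.time_width_c <= 0:
            raise ValueError("time_width_c must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 1 <= len(self.anchors) <= 8:
            raise ValueError(f"need 1-8 anchors, got {len(self.anchors)}")
        if self.training is None and self.models is None:
            raise ValueError("config needs either a training CSV or a models file")

    @property
    def effective_anchor_window(self) -> float:
        return self.anchor_window if self.anchor_window is not None else 5.0 * self.time_width_c

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent

        def resolve(key):
            return (base / raw[key]).resolve() if raw.get(key) else None

        w = raw.get("weighting") or {}
        return cls(
            peak_table=resolve("peak_table"),
            library=resolve("library"),
            output=resolve("output"),
            anchors=list(raw.get("anchors", [])),
            training=resolve("training"),
            models=resolve("models"),
            time_width_c=float(raw.get("time_width_c", 2.0)),
            anchor_window=(
                float(raw["anchor_window"]) if raw.get("anchor_window") is not None else None
            ),
            weighting=SpectrumWeighting(
                intensity_exponent=float(w.get("intensity_exponent", 0.5)),
                mass_exponent=float(w.get("mass_exponent", 2.0)),
            ),
            alpha=float(raw.get("alpha", 0.05)),
            df_convention=str(raw.get("df_convention", "paper")),
            min_doc=float(raw.get("min_doc", 0.0)),
            rt_tolerance=float(raw.get("rt_tolerance", 1.5)),
            height_mode=str(raw.get("height_mode", "base_peak")),
            mz_min=int(raw.get("mz_min", MZ_MIN_DEFAULT)),
            mz_max=int(raw.get("mz_max", MZ_MAX_DEFAULT)),
            seed=int(raw.get("seed", 0)),
        )

    def validate_files(self) -> list[str]:
        """Return a list of problems (empty when the config is runnable)."""
        problems = []
        for label, p in [
            ("peak_table", self.peak_table),
            ("library", self.library),
            ("training", self.training),
            ("models", self.models),
        ]:
            if p is not None and not Path(p).is_file():
                problems.append(f"{label}: file not found: {p}")
        return problems


@dataclass
class PipelineResult:
    reports: list[AnnotationReport]
    table: PeakTable
    counts: dict[str, int]
    class_counts: dict[str, int]
    rt_map_anchors: list[Anchor]
    output_path: Path


def _locate_anchors(
    table: PeakTable,
    library: Sequence[ReferenceEntry],
    anchor_names: Sequence[str],
    window: float,
    w: SpectrumWeighting,
) -> AnchorSet:
    by_name = {e.name: e for e in library}
    missing = [n for n in anchor_names if n not in by_name]
    if missing:
        raise AnchorMatchError(f"anchor compounds not in the library: {missing}")
    anchors = []
    for name in anchor_names:
        entry = by_name[name]
        ref_vec = weight_spectrum(entry.spectrum, w)
        best = None
        for peak in table.peaks:
            if abs(peak.rt - entry.rt) > window:
                continue
            try:
                doc = pearson_doc(weight_spectrum(peak.spectrum, w), ref_vec)
            except UndefinedCorrelationError:
                continue
            if best is None or doc > best[0]:
                best = (doc, peak)
        if best is None:
            raise AnchorMatchError(
                f"anchor {name!r} (library RT {entry.rt:.1f} s) has no matching "
                f"peak within +/- {window:.1f} s"
            )
        doc, peak = best
        logger.info(
            "anchor %s: library %.2f s -> observed %.2f s (DOC %.4f)",
            name, entry.rt, peak.rt, doc,
        )
        anchors.append(Anchor(name=name, rt_old=entry.rt, rt_new=peak.rt))
    return AnchorSet(anchors)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run all stages; every peak ends up identified, annotated, or unknown."""
    problems = config.validate_files()
    if problems:
        raise FileNotFoundError("; ".join(problems))

    t0 = time.perf_counter()
    stage = "read peak table"
    try:
        rows, sample_names = read_peak_csv(config.peak_table)
        table = group_signals_into_peaks(
            rows, sample_names, config.rt_tolerance, config.mz_min, config.mz_max,
            height_mode=config.height_mode,
        )
        logger.info("[%s] %d signals -> %d peaks (%.2fs)",
                    stage, len(rows), len(table), time.perf_counter() - t0)

        stage = "load library"
        library = read_library_csv(config.library, config.mz_min, config.mz_max)

        stage = "load class models"
        if config.models is not None:
            models = simca.load_models(config.models)
            training = None
        else:
            training = simca.load_training_csv(config.training, config.mz_min, config.mz_max)
            models = [simca.fit_class_model(t, r="auto") for t in training]

        stage = "locate anchors"
        anchor_set = _locate_anchors(
            table, library, config.anchors, config.effective_anchor_window, config.weighting
        )

        stage = "retention-time correction"
        rt_map = build_rt_map(anchor_set)
        corrected = update_library(library, rt_map)

        stage = "identification"
        id_results = identify_all(
            table.peaks, corrected, config.time_width_c, config.weighting, config.min_doc
        )

        stage = "class annotation"
        reports = []
        class_counts: dict[str, int] = {}
        for peak, res in zip(table.peaks, id_results):
            if res.status == "identified":
                reports.append(
                    AnnotationReport(peak.peak_id, "identified", res.match_name, res.doc)
                )
                continue
            cls = simca.classify(
                peak.spectrum.intensities, models, config.alpha, config.df_convention
            )
            if cls.final_label == "unknown":
                reports.append(
                    AnnotationReport(peak.peak_id, "unknown", "unknown", cls.best_p_value)
                )
            else:
                reports.append(
                    AnnotationReport(
                        peak.peak_id, "annotated", cls.final_label,
                        cls.per_class[cls.final_label].p_value,
                    )
                )
                class_counts[cls.final_label] = class_counts.get(cls.final_label, 0) + 1

        stage = "write organized matrix"
        config.output.parent.mkdir(parents=True, exist_ok=True)
        write_organized_matrix(reports, table, config.output)
    except Exception as exc:
        raise type(exc)(f"pipeline stage '{stage}' failed: {exc}") from exc

    counts = {
        "identified": sum(r.status == "identified" for r in reports),
        "annotated": sum(r.status == "annotated" for r in reports),
        "unknown": sum(r.status == "unknown" for r in reports),
    }
    assert sum(counts.values()) == len(table)
    logger.info(
        "pipeline done in %.2fs: %d peaks -> %d identified, %d annotated, %d unknown; "
        "annotated per class: %s",
        time.perf_counter() - t0, len(table), counts["identified"],
        counts["annotated"], counts["unknown"], class_counts,
    )
    return PipelineResult(
        reports=reports,
        table=table,
        counts=counts,
        class_counts=class_counts,
        rt_map_anchors=list(anchor_set.anchors),
        output_path=config.output,
    )
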