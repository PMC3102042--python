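"""Seeded generators for class-structured EI spectra and drifted peak tables.

The five default class templates mimic the fragment chemistry of
trimethylsilylated metabolite classes: each class has a small set of
diagnostic fragment masses at high relative intensity (e.g. m/z 86/100/174
for amines, m/z 299 for sugar phosphates, m/z 117/129/132/145 for fatty
acids) over a low-intensity random background.  Spectra are drawn from a
template with multiplicative lognormal noise -- detector-like, scale-free --
and normalized to base peak 100.

``make_synthetic_batch`` builds a full end-to-end scenario: a reference
library on an RT grid, an observed batch whose retention times are linearly
drifted (rt_obs = alpha * rt_lib + beta + jitter), a signal-level peak-table
CSV in the documented dialect, and a ground-truth label per peak.  Optional
extras emulate the situations the annotation stage exists for: class-member
peaks absent from the library (should be annotated) and structureless noise
peaks (should come out unknown).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .identify import ReferenceEntry
from .simca import TrainingSet
from .spectra import MZ_MAX_DEFAULT, MZ_MIN_DEFAULT, MassSpectrum, normalize_spectrum

__all__ = [
    "ClassTemplate",
    "SyntheticBatch",
    "DEFAULT_DIAGNOSTIC_MASSES",
    "DEFAULT_CLASS_SIZES",
    "make_default_templates",
    "template_spectrum",
    "sample_spectrum",
    "make_training_set",
    "make_default_training_sets",
    "make_synthetic_batch",
]

# Diagnostic fragment masses per chemical class (TMS-derivative chemistry).
DEFAULT_DIAGNOSTIC_MASSES: dict[str, tuple[int, ...]] = {
    "sugar phosphate": (89, 147, 217, 299),
    "organic acid": (101, 133, 147),
    "sugar": (89, 103, 147, 217),
    "amine": (86, 100, 174),
    "fatty acid": (117, 129, 132, 145),
}

# Default training-set sizes per class.
DEFAULT_CLASS_SIZES: dict[str, int] = {
    "sugar": 12,
    "sugar phosphate": 10,
    "organic acid": 12,
    "fatty acid": 9,
    "amine": 13,
}


@dataclass(frozen=True)
class ClassTemplate:
    """Generative template for one chemical class."""

    class_name: str
    diagnostic_masses: tuple[int, ...]
    background_masses: tuple[int, ...]
    diagnostic_intensities: tuple[float, ...]
    background_intensities: tuple[float, ...]
    intensity_sd_rel: float = 0.05

    def __post_init__(self) -> None:
        for m in (*self.diagnostic_masses, *self.background_masses):
            if not MZ_MIN_DEFAULT <= m <= MZ_MAX_DEFAULT:
                raise ValueError(f"mass {m} outside [{MZ_MIN_DEFAULT}, {MZ_MAX_DEFAULT}]")
        if self.intensity_sd_rel < 0:
            raise ValueError("intensity_sd_rel must be >= 0")
        if len(self.diagnostic_intensities) != len(self.diagnostic_masses):
            raise ValueError("one intensity per diagnostic mass required")
        if len(self.background_intensities) != len(self.background_masses):
            raise ValueError("one intensity per background mass required")


def make_default_templates(
    seed: int = 0, intensity_sd_rel: float = 0.05, n_background: int = 14
) -> list[ClassTemplate]:
    """Five class templates with the default diagnostic fragment sets.

    Background masses and all intensity levels are drawn from the seeded
    generator, so identical seeds give identical templates.
    """
    rng = np.random.default_rng(seed)
    templates = []
    for name, diag in DEFAULT_DIAGNOSTIC_MASSES.items():
        pool = [m for m in range(MZ_MIN_DEFAULT, MZ_MAX_DEFAULT + 1) if m not in diag]
        background = tuple(
            int(m) for m in rng.choice(pool, size=n_background, replace=False)
        )
        diag_int = tuple(float(v) for v in rng.uniform(55.0, 100.0, size=len(diag)))
        back_int = tuple(float(v) for v in rng.uniform(2.0, 15.0, size=n_background))
        templates.append(
            ClassTemplate(
                class_name=name,
                diagnostic_masses=diag,
                background_masses=background,
                diagnostic_intensities=diag_int,
                background_intensities=back_int,
                intensity_sd_rel=intensity_sd_rel,
            )
        )
    return templates


def _template_vector(template: ClassTemplate) -> np.ndarray:
    vec = np.zeros(MZ_MAX_DEFAULT - MZ_MIN_DEFAULT + 1)
    for m, v in zip(template.diagnostic_masses, template.diagnostic_intensities):
        vec[m - MZ_MIN_DEFAULT] = v
    for m, v in zip(template.background_masses, template.background_intensities):
        vec[m - MZ_MIN_DEFAULT] = v
    return vec


def template_spectrum(template: ClassTemplate) -> MassSpectrum:
    """The noiseless template spectrum, normalized to base peak 100."""
    return normalize_spectrum(MassSpectrum(_template_vector(template)))


def sample_spectrum(
    template: ClassTemplate, seed: Optional[int] = None, rng=None
) -> MassSpectrum:
    """One noisy draw: multiplicative lognormal noise, then normalized.

    With ``intensity_sd_rel == 0`` the exact template spectrum is returned.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    vec = _template_vector(template)
    sd = template.intensity_sd_rel
    if sd > 0:
        nz = vec > 0
        vec[nz] *= rng.lognormal(mean=-0.5 * sd * sd, sigma=sd, size=int(nz.sum()))
    return normalize_spectrum(MassSpectrum(vec))


def make_training_set(
    template: ClassTemplate,
    m: int,
    seed: int = 0,
    n_factors: int = 2,
    factor_sd: float = 0.2,
    baseline_sd: float = 6.0,
) -> TrainingSet:
    """m training spectra emulating distinct compounds of one class.

    Real class training sets are built from different compounds that share
    the class's diagnostic fragments in varying proportions.  That structure
    is emulated by ``n_factors`` latent factors: fixed per-class modulation
    patterns over the fragment masses, scaled per compound by bounded
    (uniform, unit-variance) scores of relative amplitude ``factor_sd``.
    The base peak is the normalization reference and is excluded from the
    modulation.  Multiplicative lognormal measurement noise
    (``template.intensity_sd_rel``) acts on the fragment intensities; after
    normalization a Gaussian detector baseline (``baseline_sd``,
    relative-intensity units, clipped at zero) overlays every m/z bin, as in
    real chromatograms.  The baseline gives the residual full rank, so the
    membership F-test sees homogeneous residual variance across objects.
    """
    rng = np.random.default_rng(seed)
    base = _template_vector(template)
    nz = base > 0
    modulation = rng.uniform(-1.0, 1.0, size=(n_factors, int(nz.sum())))
    modulation[:, np.argmax(base[nz])] = 0.0  # base peak stays the reference
    sd = template.intensity_sd_rel
    half_width = np.sqrt(3.0)  # unit-variance uniform scores
    rows = []
    for _ in range(m):
        vec = base.copy()
        scores = rng.uniform(-half_width, half_width, size=n_factors)
        vec[nz] *= np.clip(1.0 + factor_sd * (scores @ modulation), 0.05, None)
        if sd > 0:
            vec[nz] *= rng.lognormal(mean=-0.5 * sd * sd, sigma=sd, size=int(nz.sum()))
        vec = normalize_spectrum(MassSpectrum(vec)).intensities
        if baseline_sd > 0:
            vec = np.clip(vec + rng.normal(0.0, baseline_sd, size=vec.size), 0.0, None)
        rows.append(vec)
    names = tuple(f"{template.class_name}_{i + 1}" for i in range(m))
    return TrainingSet(class_name=template.class_name, X=np.vstack(rows), compound_names=names)


def make_default_training_sets(
    seed: int = 0, sizes: Optional[dict[str, int]] = None, intensity_sd_rel: float = 0.05
) -> list[TrainingSet]:
    """Five-class training sets at the default sizes (12/10/12/9/13)."""
    sizes = dict(DEFAULT_CLASS_SIZES if sizes is None else sizes)
    templates = make_default_templates(seed, intensity_sd_rel=intensity_sd_rel)
    rng = np.random.default_rng(seed + 1)
    sets = []
    for t in templates:
        sub = int(rng.integers(0, 2**31 - 1))
        sets.append(make_training_set(t, sizes[t.class_name], seed=sub))
    return sets


@dataclass(frozen=True)
class SyntheticBatch:
    """A complete simulated batch with ground truth."""

    library: tuple[ReferenceEntry, ...]  # original (pre-drift) RTs
    drifted_library: tuple[ReferenceEntry, ...]  # RTs after the true drift
    signal_rows: pd.DataFrame  # peak-table dialect: rt_sec, mz, samples...
    sample_names: tuple[str, ...]
    truth: pd.DataFrame  # rt_obs, name, class, kind per simulated peak
    anchor_names: tuple[str, ...]


def _compound_spectrum(template: ClassTemplate, rng, unique_pool: list[int]) -> MassSpectrum:
    """A distinct compound of the class: template with per-compound intensity
    variation plus two compound-specific fragment masses."""
    vec = _template_vector(template)
    nz = vec > 0
    vec[nz] *= rng.uniform(0.7, 1.3, size=int(nz.sum()))
    for _ in range(2):
        if unique_pool:
            m = unique_pool.pop(rng.integers(0, len(unique_pool)))
            vec[m - MZ_MIN_DEFAULT] = rng.uniform(30.0, 50.0)
    return normalize_spectrum(MassSpectrum(vec))


def make_synthetic_batch(
    templates: Optional[Sequence[ClassTemplate]] = None,
    library_size: int = 50,
    n_samples: int = 5,
    drift: tuple[float, float] = (1.0, 0.0),
    rt_jitter: float = 0.0,
    seed: int = 0,
    rt_start: float = 300.0,
    rt_step: float = 10.0,
    noise_rel: float = 0.05,
    n_class_only_peaks: int = 0,
    n_noise_peaks: int = 0,
) -> SyntheticBatch:
    """Simulate a reference library and an observed, drifted batch.

    Library compounds sit on an RT grid ``rt_start + i * rt_step``; the
    observed batch elutes at ``alpha * rt + beta + jitter``.  The first and
    last library compounds act as pseudo-internal-standard anchors and are
    simulated jitter-free (anchors are, by selection, stable peaks).
    Optional class-only peaks (class members missing from the library) are
    placed between grid points, and noise peaks carry random spectra.
    """
    alpha, beta = drift
    if alpha <= 0:
        raise ValueError("drift slope alpha must be > 0")
    templates = list(make_default_templates(seed) if templates is None else templates)
    rng = np.random.default_rng(seed)
    sample_names = tuple(f"S{j + 1:02d}" for j in range(n_samples))

    used = {m for t in templates for m in (*t.diagnostic_masses, *t.background_masses)}
    unique_pool = [m for m in range(MZ_MIN_DEFAULT, MZ_MAX_DEFAULT + 1) if m not in used]

    library: list[ReferenceEntry] = []
    for i in range(library_size):
        t = templates[i % len(templates)]
        spec = _compound_spectrum(t, rng, unique_pool)
        library.append(
            ReferenceEntry(
                name=f"cmpd_{i + 1:03d}",
                rt=rt_start + i * rt_step,
                spectrum=spec,
                class_label=t.class_name,
            )
        )
    anchor_names = (library[0].name, library[-1].name)

    # observed peaks: library compounds + optional class-only and noise peaks
    peaks: list[tuple[float, MassSpectrum, str, Optional[str], Optional[str]]] = []
    for e in library:
        jit = 0.0 if e.name in anchor_names else float(rng.uniform(-rt_jitter, rt_jitter))
        rt_obs = alpha * e.rt + beta + jit
        peaks.append((rt_obs, e.spectrum, "library", e.name, e.class_label))
    for k in range(n_class_only_peaks):
        t = templates[k % len(templates)]
        # halfway between grid points: out of any identification window
        rt_lib = rt_start + (k + 0.5) * rt_step
        rt_obs = alpha * rt_lib + beta
        peaks.append((rt_obs, sample_spectrum(t, rng=rng), "class_only", None, t.class_name))
    for k in range(n_noise_peaks):
        masses = rng.choice(
            np.arange(MZ_MIN_DEFAULT, MZ_MAX_DEFAULT + 1), size=25, replace=False
        )
        vec = np.zeros(MZ_MAX_DEFAULT - MZ_MIN_DEFAULT + 1)
        vec[masses - MZ_MIN_DEFAULT] = rng.uniform(5.0, 100.0, size=masses.size)
        # snap to a grid point, then offset so the peak clears both the
        # identification window and the clustering tolerance of neighbours
        idx = round((k + 1) * (library_size - 1) / (n_noise_peaks + 1))
        rt_lib = rt_start + idx * rt_step
        rt_obs = alpha * (rt_lib + 0.27 * rt_step) + beta
        peaks.append(
            (rt_obs, normalize_spectrum(MassSpectrum(vec)), "noise", None, None)
        )
    peaks.sort(key=lambda item: item[0])

    rows = []
    truth = []
    for rt_obs, spec, kind, name, cls in peaks:
        heights = rng.lognormal(mean=np.log(1e4), sigma=0.3, size=n_samples)
        for b in np.flatnonzero(spec.intensities > 0.5):
            mz = MZ_MIN_DEFAULT + int(b)
            base = spec.intensities[b] / 100.0
            inten = heights * base
            if noise_rel > 0:
                inten = inten * rng.lognormal(
                    mean=-0.5 * noise_rel**2, sigma=noise_rel, size=n_samples
                )
            rows.append({"rt_sec": rt_obs, "mz": mz, **dict(zip(sample_names, inten))})
        truth.append({"rt_obs": rt_obs, "name": name, "class": cls, "kind": kind})

    signal_rows = pd.DataFrame(rows, columns=["rt_sec", "mz", *sample_names])
    drifted = tuple(
        ReferenceEntry(
            name=e.name,
            rt=alpha * e.rt + beta,
            spectrum=e.spectrum,
            class_label=e.class_label,
        )
        for e in library
    )
    return SyntheticBatch(
        library=tuple(library),
        drifted_library=drifted,
        signal_rows=signal_rows,
        sample_names=sample_names,
        truth=pd.DataFrame(truth),
        anchor_names=anchor_names,
    )
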