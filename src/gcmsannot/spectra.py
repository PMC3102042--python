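"""Electron-ionization mass spectra as fixed integer-m/z bin vectors.

A spectrum is a vector of non-negative intensities over a contiguous integer
m/z range (default 85-500, i.e. 416 bins).  Spectra are compared by the
Pearson product-moment correlation of their *weighted* intensity vectors:
because EI fragmentation pushes most ion current into low masses, the high
masses -- which carry most of the structural information -- are emphasised by
a power-law weight ``intensity**a * mz**b`` before correlation.  The resulting
correlation is called the degree of coincidence (DOC) throughout the package.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

MZ_MIN_DEFAULT = 85
MZ_MAX_DEFAULT = 500

__all__ = [
    "MZ_MIN_DEFAULT",
    "MZ_MAX_DEFAULT",
    "MassSpectrum",
    "SpectrumWeighting",
    "EmptySpectrumError",
    "UndefinedCorrelationError",
    "normalize_spectrum",
    "weight_spectrum",
    "pearson_doc",
]


class EmptySpectrumError(ValueError):
    """Raised when an operation needs at least one positive intensity."""


class UndefinedCorrelationError(ValueError):
    """Raised when Pearson correlation is undefined (zero-variance vector)."""


@dataclass(frozen=True, eq=False)
class MassSpectrum:
    """An EI spectrum binned at unit m/z resolution over [mz_min, mz_max]."""

    intensities: np.ndarray
    mz_min: int = MZ_MIN_DEFAULT
    mz_max: int = MZ_MAX_DEFAULT

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        if self.mz_max < self.mz_min:
            raise ValueError(f"mz_max ({self.mz_max}) < mz_min ({self.mz_min})")
        expected = self.mz_max - self.mz_min + 1
        if arr.ndim != 1 or arr.size != expected:
            raise ValueError(
                f"expected {expected} intensities for m/z "
                f"{self.mz_min}-{self.mz_max}, got shape {arr.shape}"
            )
        if not np.all(np.isfinite(arr)):
            raise ValueError("intensities must be finite")
        if np.any(arr < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def mz(self) -> np.ndarray:
        """Integer m/z axis, length ``n_bins``."""
        return np.arange(self.mz_min, self.mz_max + 1)

    @property
    def n_bins(self) -> int:
        return self.mz_max - self.mz_min + 1

    @property
    def base_peak_mz(self) -> int:
        """m/z of the most intense bin (first one on ties)."""
        return int(self.mz_min + int(np.argmax(self.intensities)))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MassSpectrum):
            return NotImplemented
        return (
            self.mz_min == other.mz_min
            and self.mz_max == other.mz_max
            and np.array_equal(self.intensities, other.intensities)
        )


@dataclass(frozen=True)
class SpectrumWeighting:
    """Power-law spectral weighting ``intensity**a * mz**b``.

    ``intensity_exponent=1, mass_exponent=0`` is the identity transform.  The
    defaults (0.5, 2) damp the dominant low-mass fragments and emphasise the
    diagnostic high-mass ions, the convention used by EI library-search
    scoring.
    """

    intensity_exponent: float = 0.5
    mass_exponent: float = 2.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.intensity_exponent) and np.isfinite(self.mass_exponent)):
            raise ValueError("weighting exponents must be finite")
        if self.intensity_exponent < 0 or self.mass_exponent < 0:
            raise ValueError("weighting exponents must be >= 0")


IDENTITY_WEIGHTING = SpectrumWeighting(intensity_exponent=1.0, mass_exponent=0.0)


def normalize_spectrum(spec: MassSpectrum) -> MassSpectrum:
    """Rescale so the base peak is exactly 100 (relative intensities).

    Raises :class:`EmptySpectrumError` for an all-zero spectrum.
    """
    peak = float(np.max(spec.intensities))
    if peak <= 0.0:
        raise EmptySpectrumError("cannot normalize an all-zero spectrum")
    scaled = spec.intensities * (100.0 / peak)
    # guard against rounding drift: the base peak must be 100 exactly
    scaled[np.argmax(spec.intensities)] = 100.0
    return MassSpectrum(scaled, spec.mz_min, spec.mz_max)


def weight_spectrum(spec: MassSpectrum, w: SpectrumWeighting) -> np.ndarray:
    """Return the weighted vector ``intensity**a * mz**b`` (one value per bin)."""
    return spec.intensities ** w.intensity_exponent * spec.mz.astype(float) ** w.mass_exponent


def pearson_doc(u: np.ndarray, v: np.ndarray) -> float:
    """Degree of coincidence: Pearson correlation of two (weighted) vectors.

    Symmetric, invariant to positive affine rescaling of either argument,
    always in [-1, 1].  Raises :class:`UndefinedCorrelationError` if either
    vector has zero variance.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    du = u - u.mean()
    dv = v - v.mean()
    su = float(np.sqrt(du @ du))
    sv = float(np.sqrt(dv @ dv))
    if su == 0.0 or sv == 0.0:
        raise UndefinedCorrelationError("zero-variance vector has no correlation")
    r = float(du @ dv) / (su * sv)
    return float(np.clip(r, -1.0, 1.0))
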