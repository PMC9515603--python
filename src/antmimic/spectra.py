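"""Reflectance standardization and spectral distances.

Specimens are measured twice (whole anterior and whole posterior body part)
over 300–700 nm relative to a white standard.  Each body-part spectrum is
standardized against white/black references, resampled to a common 400-point
grid, and the two parts concatenated into one 800-value specimen vector.
Species are summarised by the pointwise mean vector and compared by Euclidean
distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Number of resampled reflectance values per body part.
N_POINTS = 400
#: Wavelength range retained from the spectrometer, nm.
WL_MIN, WL_MAX = 300.0, 700.0

#: The common wavelength grid all spectra are resampled onto.
WAVELENGTH_GRID = np.linspace(WL_MIN, WL_MAX, N_POINTS)

BODY_PARTS = ("anterior", "posterior")


@dataclass
class ReflectanceSpectrum:
    """One standardized body-part spectrum on the common grid."""

    wavelengths: np.ndarray
    values: np.ndarray
    body_part: str = "anterior"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.wavelengths.shape != self.values.shape:
            raise ValueError("wavelengths and values must have the same shape")
        if len(self.values) != N_POINTS:
            raise ValueError(f"expected {N_POINTS} values, got {len(self.values)}")
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("reflectance values must be finite")
        if self.body_part not in BODY_PARTS:
            raise ValueError(f"body_part must be one of {BODY_PARTS}")


@dataclass
class SpecimenSpectra:
    """Concatenated anterior(400) ++ posterior(400) vector for one specimen."""

    specimen_id: str
    vector: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float)
        if self.vector.shape != (2 * N_POINTS,):
            raise ValueError(
                f"specimen vector must have length {2 * N_POINTS}, got {self.vector.shape}"
            )

    @classmethod
    def from_parts(
        cls, specimen_id: str, anterior: ReflectanceSpectrum, posterior: ReflectanceSpectrum
    ) -> "SpecimenSpectra":
        return cls(specimen_id, np.concatenate([anterior.values, posterior.values]))


def standardize_reflectance(
    wavelengths: np.ndarray,
    raw: np.ndarray,
    white_ref: np.ndarray,
    black_ref: np.ndarray,
    body_part: str = "anterior",
) -> ReflectanceSpectrum:
    """Standardize a raw spectrum against white and black references.

    Relative reflectance is ``(raw - black) / (white - black)`` computed on the
    instrument's native grid, then linearly interpolated onto the common
    400-point 300–700 nm grid.  Values below the black standard are clipped to
    zero with a warning.

    Raises
    ------
    ValueError
        If the white reference does not exceed the black reference at every
        wavelength, or the grids disagree.
    """
    wavelengths = np.asarray(wavelengths, dtype=float)
    raw = np.asarray(raw, dtype=float)
    white_ref = np.asarray(white_ref, dtype=float)
    black_ref = np.asarray(black_ref, dtype=float)
    if not (wavelengths.shape == raw.shape == white_ref.shape == black_ref.shape):
        raise ValueError("raw, white and black must share one wavelength grid")
    if np.any(white_ref <= black_ref):
        bad = wavelengths[white_ref <= black_ref]
        raise ValueError(
            f"white reference must exceed black reference everywhere; "
            f"violated at {bad.size} wavelengths (first: {bad[0]:g} nm)"
        )
    rel = (raw - black_ref) / (white_ref - black_ref)
    if np.any(rel < 0):
        logger.warning(
            "clipping %d negative standardized reflectance values to 0",
            int(np.sum(rel < 0)),
        )
        rel = np.clip(rel, 0.0, None)
    values = np.interp(WAVELENGTH_GRID, wavelengths, rel)
    return ReflectanceSpectrum(WAVELENGTH_GRID.copy(), values, body_part)


def species_mean_spectrum(specimens: list[SpecimenSpectra] | list[np.ndarray]) -> np.ndarray:
    """Pointwise mean 800-vector over specimens of one species."""
    if len(specimens) == 0:
        raise ValueError("need at least one specimen")
    vectors = [s.vector if isinstance(s, SpecimenSpectra) else np.asarray(s, float) for s in specimens]
    lengths = {len(v) for v in vectors}
    if len(lengths) != 1:
        raise ValueError(f"mixed vector lengths: {sorted(lengths)}")
    return np.mean(vectors, axis=0)


def spectral_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Euclidean distance between two reflectance vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.linalg.norm(a - b))
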