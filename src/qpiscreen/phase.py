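"""Quantitative phase image container.

The package-wide unit convention: optical path difference (OPD) in
nanometres, lengths (pixel size, propagation distances) in micrometres,
wavelengths in nanometres, concentrations in micromolar, time in hours.
Pixel indices are 0-based ``(row, col)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = ["PhaseImage"]


@dataclass
class PhaseImage:
    """A 2D optical path difference map.

    Parameters
    ----------
    opd : ndarray
        OPD in nanometres, shape ``(rows, cols)``.
    pixel_size_um : float
        Lateral sampling in micrometres per pixel.
    meta : dict
        Free-form provenance (well, field, time point, reconstruction flags).
    """

    opd: np.ndarray
    pixel_size_um: float
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.opd = np.asarray(self.opd, dtype=np.float64)
        if self.opd.ndim != 2:
            raise ValueError("OPD map must be 2D")
        if not np.isfinite(self.pixel_size_um) or self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive and finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.opd.shape  # type: ignore[return-value]

    def phase_rad(self, wavelength_nm: float) -> np.ndarray:
        """Phase delay in radians at the given illumination wavelength."""
        if wavelength_nm <= 0:
            raise ValueError("wavelength must be positive")
        return 2.0 * np.pi * self.opd / wavelength_nm

    @classmethod
    def from_phase_rad(
        cls, phase: np.ndarray, wavelength_nm: float, pixel_size_um: float, **meta: Any
    ) -> "PhaseImage":
        """Build a PhaseImage from a phase map in radians."""
        opd = np.asarray(phase, dtype=np.float64) * wavelength_nm / (2.0 * np.pi)
        return cls(opd=opd, pixel_size_um=pixel_size_um, meta=dict(meta))

    def copy(self) -> "PhaseImage":
        return PhaseImage(self.opd.copy(), self.pixel_size_um, dict(self.meta))
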