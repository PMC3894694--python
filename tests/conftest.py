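"""Shared fixtures: small synthetic phase objects used across the suite."""
from __future__ import annotations

import numpy as np
import pytest

from qpiscreen import PhaseImage
from qpiscreen.optics import DHM_WAVELENGTH_NM


def radial_phase_bump(
    n: int = 256, radius_px: float = 40.0, peak_rad: float = 2.0
) -> np.ndarray:
    """Centered squared-cosine phase cap, zero at and beyond ``radius_px``."""
    rr, cc = np.mgrid[0:n, 0:n]
    r = np.hypot(rr - n / 2, cc - n / 2)
    rho = np.clip(r / radius_px, 0.0, 1.0)
    return peak_rad * np.cos(0.5 * np.pi * rho) ** 2 * (r < radius_px)


@pytest.fixture
def smooth_bump() -> PhaseImage:
    """A 2-rad smooth phase object on a 256^2 grid (OPD peak ~218 nm)."""
    phi = radial_phase_bump()
    return PhaseImage.from_phase_rad(phi, DHM_WAVELENGTH_NM, 0.62)


@pytest.fixture
def flat_field() -> PhaseImage:
    return PhaseImage(np.zeros((256, 256)), 0.62)
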