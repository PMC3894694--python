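"""Physical forward models: off-axis holograms and defocused bright-field stacks.

Free-space propagation uses the exact angular-spectrum kernel (not the
Fresnel approximation): a few micrometres of defocus at NA ~ 0.25 is
near-field, where the paraxial kernel is noticeably biased. The kernel is
unitary over the propagating band, so energy is conserved for band-limited
fields.

An off-axis hologram is the interferogram ``I = |O + R|^2`` of the object
wave ``O = exp(i φ)`` with a tilted plane reference ``R``; the tilt puts a
carrier fringe on the camera that separates the object sideband from the
DC term in the Fourier plane. A defocus stack is the set of intensities
``|P_z O|^2`` at a few axial offsets; for a pure phase object the in-focus
plane is featureless and contrast only appears out of focus.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np

from .phase import PhaseImage

__all__ = [
    "Hologram",
    "IntensityStack",
    "propagate",
    "synthesize_hologram",
    "synthesize_defocus_stack",
    "phase_taper",
    "cosine_window",
    "DHM_WAVELENGTH_NM",
    "BF_WAVELENGTH_NM",
    "DEFAULT_CARRIER",
    "DEFAULT_Z_OFFSETS_UM",
]

#: coherent source wavelength of the holographic arm (nm)
DHM_WAVELENGTH_NM = 684.0
#: LED wavelength of the bright-field arm (nm)
BF_WAVELENGTH_NM = 740.0
#: off-axis carrier in cycles/pixel (row, col)
DEFAULT_CARRIER = (0.25, 0.25)
#: defocus planes for the three-plane stack (um)
DEFAULT_Z_OFFSETS_UM = (-5.0, 0.0, 5.0)


@dataclass
class Hologram:
    """Off-axis interferogram with its acquisition parameters."""

    intensity: np.ndarray
    wavelength_nm: float = DHM_WAVELENGTH_NM
    pixel_size_um: float = 0.62
    carrier: tuple[float, float] | None = DEFAULT_CARRIER
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.ndim != 2:
            raise ValueError("hologram intensity must be 2D")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if self.carrier is not None:
            if max(abs(c) for c in self.carrier) >= 0.5:
                raise ValueError("carrier must be below Nyquist (|f| < 0.5)")


@dataclass
class IntensityStack:
    """Defocused bright-field planes at symmetric axial offsets."""

    planes: np.ndarray  # (n_z, rows, cols)
    z_offsets_um: tuple[float, ...] = DEFAULT_Z_OFFSETS_UM
    wavelength_nm: float = BF_WAVELENGTH_NM
    pixel_size_um: float = 0.62
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.planes = np.asarray(self.planes, dtype=np.float64)
        if self.planes.ndim != 3:
            raise ValueError("planes must be a (n_z, rows, cols) array")
        if len(self.z_offsets_um) != self.planes.shape[0]:
            raise ValueError("one z offset per plane required")
        if len(set(self.z_offsets_um)) != len(self.z_offsets_um):
            raise ValueError("z offsets must be distinct")
        if np.any(self.planes < 0):
            raise ValueError("intensity must be non-negative")


def _freq_grids(shape: tuple[int, int], pixel_size_um: float):
    fr = np.fft.fftfreq(shape[0], d=pixel_size_um)
    fc = np.fft.fftfreq(shape[1], d=pixel_size_um)
    return np.meshgrid(fr, fc, indexing="ij")


def propagate(
    field_xy: np.ndarray,
    distance_um: float,
    wavelength_nm: float,
    pixel_size_um: float,
) -> np.ndarray:
    """Angular-spectrum propagation of a complex field.

    Evanescent components (spatial frequencies beyond 1/λ) are truncated,
    which keeps the operator unitary and the ±z round trip exact.
    """
    if pixel_size_um <= 0 or wavelength_nm <= 0:
        raise ValueError("pixel size and wavelength must be positive")
    field_xy = np.asarray(field_xy, dtype=np.complex128)
    if not np.all(np.isfinite(field_xy)):
        raise ValueError("field contains non-finite values")
    if distance_um == 0:
        return field_xy.copy()
    lam_um = wavelength_nm * 1.0e-3
    fr, fc = _freq_grids(field_xy.shape, pixel_size_um)
    f2 = fr**2 + fc**2
    kz2 = 1.0 / lam_um**2 - f2
    propagating = kz2 > 0
    kz = np.sqrt(np.where(propagating, kz2, 0.0))
    kernel = np.where(propagating, np.exp(2j * np.pi * kz * distance_um), 0.0)
    return np.fft.ifft2(np.fft.fft2(field_xy) * kernel)


def cosine_window(n: int, width: int) -> np.ndarray:
    """1D raised-cosine edge taper: 0→1 over ``width`` samples at each end."""
    w = np.ones(n)
    if width > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(width) / width))
        w[:width] = ramp
        w[-width:] = ramp[::-1]
    return w


def phase_taper(phase: np.ndarray, width: int) -> np.ndarray:
    """Roll the phase smoothly to zero at the field border.

    Tapering the *phase* (rather than the amplitude) suppresses FFT
    wrap-around without injecting spurious intensity structure into the
    forward model; metrics downstream exclude the tapered margin.
    """
    if width <= 0:
        return phase
    win = np.outer(
        cosine_window(phase.shape[0], width), cosine_window(phase.shape[1], width)
    )
    return phase * win


def synthesize_hologram(
    phase: PhaseImage,
    *,
    carrier: tuple[float, float] = DEFAULT_CARRIER,
    reference_amplitude: float = 1.0,
    object_amplitude: float = 1.0,
    wavelength_nm: float = DHM_WAVELENGTH_NM,
    defocus_um: float = 0.0,
    photon_budget: float | None = None,
    taper_px: int = 16,
    seed: int | np.random.Generator | None = None,
) -> Hologram:
    """Record an off-axis hologram of a phase object.

    The object wave is ``exp(i φ)`` with ``φ = 2π·OPD/λ``, optionally
    propagated ``defocus_um`` out of focus before the camera; the tilted
    plane reference adds a carrier fringe. With ``photon_budget`` set, the
    camera applies Poisson shot noise at that expected photon count per
    unit intensity (deterministic given ``seed``).
    """
    if max(abs(c) for c in carrier) >= 0.5:
        raise ValueError("carrier at or above Nyquist would alias")
    phi = phase_taper(phase.phase_rad(wavelength_nm), taper_px)
    obj = object_amplitude * np.exp(1j * phi)
    if defocus_um != 0.0:
        obj = propagate(obj, defocus_um, wavelength_nm, phase.pixel_size_um)
    rr, cc = np.mgrid[0 : phi.shape[0], 0 : phi.shape[1]]
    ref = reference_amplitude * np.exp(
        2j * np.pi * (carrier[0] * rr + carrier[1] * cc)
    )
    intensity = np.abs(obj + ref) ** 2
    if photon_budget is not None:
        rng = np.random.default_rng(seed)
        intensity = rng.poisson(intensity * photon_budget) / photon_budget
    return Hologram(
        intensity,
        wavelength_nm=wavelength_nm,
        pixel_size_um=phase.pixel_size_um,
        carrier=carrier,
        meta={"defocus_um": defocus_um, "taper_px": taper_px},
    )


def synthesize_defocus_stack(
    phase: PhaseImage,
    *,
    z_offsets_um: Sequence[float] = DEFAULT_Z_OFFSETS_UM,
    wavelength_nm: float = BF_WAVELENGTH_NM,
    taper_px: int = 16,
    photon_budget: float | None = None,
    seed: int | np.random.Generator | None = None,
) -> IntensityStack:
    """Record defocused bright-field intensities of a pure phase object.

    Each plane is ``|propagate(exp(iφ), z)|^2``; the in-focus plane of a
    phase object is unit intensity up to numerical error. Defocused planes
    on either side of focus show opposite-signed contrast (the axial
    intensity derivative is proportional to −∇²φ for uniform intensity).
    """
    if len(z_offsets_um) < 2:
        raise ValueError("need at least two distinct z offsets")
    if len(set(z_offsets_um)) != len(z_offsets_um):
        raise ValueError("z offsets must be distinct")
    phi = phase_taper(phase.phase_rad(wavelength_nm), taper_px)
    if not np.all(np.isfinite(phi)):
        raise ValueError("phase contains non-finite values")
    obj = np.exp(1j * phi)
    planes = np.stack(
        [
            np.abs(propagate(obj, z, wavelength_nm, phase.pixel_size_um)) ** 2
            for z in z_offsets_um
        ]
    )
    if photon_budget is not None:
        rng = np.random.default_rng(seed)
        planes = rng.poisson(planes * photon_budget) / photon_budget
    return IntensityStack(
        planes,
        z_offsets_um=tuple(float(z) for z in z_offsets_um),
        wavelength_nm=wavelength_nm,
        pixel_size_um=phase.pixel_size_um,
        meta={"taper_px": taper_px},
    )
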