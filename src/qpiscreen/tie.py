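"""Transport-of-intensity phase retrieval from a defocus stack.

For a paraxial beam the axial intensity derivative and the transverse
phase are linked by the transport-of-intensity equation (TIE),

    -(2π/λ) ∂I/∂z = ∇·(I ∇φ).

For a nearly transparent specimen the intensity is uniform (I ≈ I₀) and
the equation reduces to a Poisson problem, solved spectrally:

    φ = -(2π/λ) · InverseLaplacian(∂I/∂z) / I₀ ,

with ∂I/∂z estimated by the central difference of the ±Δz planes and the
inverse Laplacian regularized à la Tikhonov (division by 4π²|q|² + ε).
The zero-frequency component is not observable — the recovered phase is
mean-free by convention. The image is mirror-padded before the spectral
solve, which imposes even (Neumann-like) symmetry and suppresses the
wrap-around artifacts of the periodic Laplacian.

Low spatial frequencies are the known weak spot of TIE: the 1/|q|²
amplification blows up noise at large scales, which the ε floor bounds at
the price of a slight low-frequency underestimate.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics import IntensityStack
from .phase import PhaseImage

__all__ = ["reconstruct_tie", "compare_modalities", "ModalityComparison"]

#: Tikhonov floor as a fraction of the maximum of 4π²|q|².
#: 1e-6 preserves cell-scale frequencies (tens of um) while still bounding
#: the 1/|q|² blow-up; raise it for shot-noise-limited stacks.
DEFAULT_REGULARIZATION = 1e-6


def _inverse_laplacian(source: np.ndarray, pixel_size_um: float, eps_frac: float):
    """Mean-free solution of ∇²u = source with mirror padding."""
    n_r, n_c = source.shape
    padded = np.pad(source, ((0, n_r), (0, n_c)), mode="symmetric")
    fr = np.fft.fftfreq(2 * n_r, d=pixel_size_um)[:, None]
    fc = np.fft.fftfreq(2 * n_c, d=pixel_size_um)[None, :]
    q2 = 4.0 * np.pi**2 * (fr**2 + fc**2)
    eps = eps_frac * q2.max()
    inv = -1.0 / (q2 + eps)
    inv[0, 0] = 0.0  # mean-free
    u = np.fft.ifft2(np.fft.fft2(padded) * inv).real
    return u[:n_r, :n_c]


def reconstruct_tie(
    stack: IntensityStack,
    regularization: float = DEFAULT_REGULARIZATION,
    *,
    allow_two_plane: bool = False,
) -> PhaseImage:
    """Recover a mean-free OPD map from a symmetric 3-plane defocus stack.

    Parameters
    ----------
    regularization : float
        Tikhonov ε as a fraction of the largest 4π²|q|² on the grid.
    allow_two_plane : bool
        Accept a general two-plane stack (derivative from the first and
        last planes) instead of requiring symmetric ±Δz around focus.
    """
    if regularization <= 0:
        raise ValueError("regularization must be positive")
    planes = stack.planes
    z = np.asarray(stack.z_offsets_um, dtype=np.float64)
    if planes.shape[0] == 3 and not allow_two_plane:
        order = np.argsort(z)
        z_s, p_s = z[order], planes[order]
        if not (np.isclose(z_s[1], 0.0) and np.isclose(z_s[0], -z_s[2])):
            raise ValueError(
                "need symmetric offsets (-dz, 0, +dz); "
                "pass allow_two_plane=True for the general case"
            )
        didz = (p_s[2] - p_s[0]) / (2.0 * z_s[2])
        i0 = float(p_s[1].mean())
    elif allow_two_plane and planes.shape[0] >= 2:
        order = np.argsort(z)
        z_s, p_s = z[order], planes[order]
        didz = (p_s[-1] - p_s[0]) / (z_s[-1] - z_s[0])
        i0 = float(planes.mean())
    else:
        raise ValueError("expected a 3-plane stack with symmetric offsets")
    if i0 <= 0:
        raise ValueError("non-positive mean intensity")
    lam_um = stack.wavelength_nm * 1.0e-3
    # uniform-intensity TIE: phi = -(2π/λ) InvLap(dI/dz) / I0
    phi = (
        -(2.0 * np.pi / lam_um)
        * _inverse_laplacian(didz, stack.pixel_size_um, regularization)
        / i0
    )
    phi -= phi.mean()
    opd = phi * stack.wavelength_nm / (2.0 * np.pi)
    return PhaseImage(
        opd, stack.pixel_size_um, meta={"regularization": regularization}
    )


@dataclass(frozen=True)
class ModalityComparison:
    """Mean-free agreement between two phase maps over an interior region."""

    rmse_nm: float
    correlation: float
    margin_px: int


def compare_modalities(
    truth: PhaseImage, recon: PhaseImage, margin_px: int = 0
) -> ModalityComparison:
    """Mean-free RMSE (nm) and Pearson correlation inside a margin.

    Both maps lose their interior mean before comparison, matching the
    mean-free convention of the spectral TIE solver.
    """
    if truth.shape != recon.shape:
        raise ValueError("phase maps must share a shape")
    if margin_px < 0 or 2 * margin_px >= min(truth.shape):
        raise ValueError("margin must be non-negative and below half the image")
    sl = (
        slice(margin_px, truth.shape[0] - margin_px),
        slice(margin_px, truth.shape[1] - margin_px),
    )
    a = truth.opd[sl] - truth.opd[sl].mean()
    b = recon.opd[sl] - recon.opd[sl].mean()
    rmse = float(np.sqrt(np.mean((a - b) ** 2)))
    denom = np.sqrt((a**2).sum() * (b**2).sum())
    corr = float((a * b).sum() / denom) if denom > 0 else 1.0 if rmse == 0 else 0.0
    return ModalityComparison(rmse_nm=rmse, correlation=corr, margin_px=margin_px)
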