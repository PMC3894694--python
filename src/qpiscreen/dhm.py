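"""Off-axis hologram demodulation to a quantitative phase image.

Pipeline: detect (or accept) the carrier → demodulate the interferogram to
baseband → isolate the +1 object sideband with a raised-cosine low-pass →
inverse FFT → optional numerical refocus by angular-spectrum propagation →
phase extraction → 2D unwrapping → background flattening (low-order
polynomial fitted over a cell-free mask) → OPD in nm via ``φ·λ/2π``.

The sideband window radius defaults to half the carrier-to-DC distance:
larger windows admit DC leakage, smaller ones clip the object spectrum.
Because the two sidebands are complex conjugates, the sign of the
recovered phase is fixed by a convention: the detected carrier is reported
in the half-plane with positive row frequency.
"""
from __future__ import annotations

import numpy as np
from skimage.filters import threshold_otsu
from skimage.restoration import unwrap_phase

from .optics import Hologram, propagate
from .phase import PhaseImage

__all__ = ["detect_carrier", "reconstruct_hologram", "flatten_background"]

#: carrier distances below this (cycles/pixel) leave no room for a sideband
MIN_CARRIER_CPP = 0.06


def detect_carrier(holo: Hologram) -> tuple[float, float]:
    """Locate the off-axis carrier as the strongest non-DC Fourier peak.

    Returns (f_row, f_col) in cycles/pixel, refined to sub-bin precision
    by a centroid over the 3x3 peak neighbourhood. The peak is searched in
    the f_row > 0 half-plane (the two sidebands are conjugate twins).

    Raises ``ValueError`` when no peak stands above the noise floor
    (fringe-free input).
    """
    spec = np.abs(np.fft.fft2(holo.intensity))
    n_r, n_c = spec.shape
    fr = np.fft.fftfreq(n_r)[:, None]
    fc = np.fft.fftfreq(n_c)[None, :]
    dist = np.hypot(fr, fc)
    search = (dist > MIN_CARRIER_CPP) & (
        (fr > 0) | ((fr == 0) & (fc > 0))
    )
    if not np.any(search):
        raise ValueError("hologram too small for carrier detection")
    masked = np.where(search, spec, 0.0)
    peak = np.unravel_index(int(np.argmax(masked)), masked.shape)
    floor = np.median(spec[search])
    if masked[peak] < 10.0 * max(floor, 1e-300):
        raise ValueError("no off-axis carrier peak above the noise floor")
    # sub-bin refinement: magnitude centroid over the wrapped 3x3 patch
    num_r = num_c = den = 0.0
    for dr in (-1, 0, 1):
        for dc in (-1, 0, 1):
            w = spec[(peak[0] + dr) % n_r, (peak[1] + dc) % n_c]
            num_r += w * dr
            num_c += w * dc
            den += w
    f_row = float(np.fft.fftfreq(n_r)[peak[0]] + (num_r / den) / n_r)
    f_col = float(np.fft.fftfreq(n_c)[peak[1]] + (num_c / den) / n_c)
    return (f_row, f_col)


def _poly2_design(rows: np.ndarray, cols: np.ndarray, shape) -> np.ndarray:
    x = cols / max(shape[1] - 1, 1) - 0.5
    y = rows / max(shape[0] - 1, 1) - 0.5
    return np.column_stack([np.ones_like(x), x, y, x * y, x**2, y**2])


def flatten_background(
    opd: np.ndarray, order: int = 2, max_fit_pixels: int = 50_000
) -> tuple[np.ndarray, np.ndarray]:
    """Remove a low-order polynomial background fitted on cell-free pixels.

    The cell-free mask is pixels below an Otsu threshold on the OPD map
    (falling back to the full image when thresholding is degenerate).
    Returns the flattened map and the background mask used.
    """
    if order not in (0, 1, 2):
        raise ValueError("flattening order must be 0, 1 or 2")
    finite = np.isfinite(opd)
    try:
        thr = threshold_otsu(opd[finite])
        background = (opd < thr) & finite
        if background.sum() < 64:
            background = finite
    except ValueError:
        background = finite
    rows, cols = np.nonzero(background)
    if rows.size > max_fit_pixels:
        step = rows.size // max_fit_pixels + 1
        rows, cols = rows[::step], cols[::step]
    design = _poly2_design(rows.astype(float), cols.astype(float), opd.shape)
    n_terms = {0: 1, 1: 3, 2: 6}[order]
    coef, *_ = np.linalg.lstsq(design[:, :n_terms], opd[rows, cols], rcond=None)
    rr, cc = np.mgrid[0 : opd.shape[0], 0 : opd.shape[1]]
    full = _poly2_design(rr.ravel().astype(float), cc.ravel().astype(float), opd.shape)
    fitted = (full[:, :n_terms] @ coef).reshape(opd.shape)
    return opd - fitted, background


def reconstruct_hologram(
    holo: Hologram,
    refocus_um: float = 0.0,
    *,
    carrier: tuple[float, float] | None = None,
    window_radius_frac: float = 0.5,
    window_edge_frac: float = 0.2,
    flatten_order: int = 2,
    unwrap: bool = True,
) -> PhaseImage:
    """Reconstruct a quantitative OPD map from an off-axis hologram.

    Parameters
    ----------
    refocus_um : float
        Numerical refocus distance applied to the demodulated field
        (negative of the defocus at recording brings the object in focus).
    carrier : optional
        Carrier in cycles/pixel; defaults to the hologram's metadata and
        falls back to automatic detection.
    window_radius_frac : float
        Sideband window radius as a fraction of the carrier-to-DC distance.
    """
    intensity = np.asarray(holo.intensity, dtype=np.float64)
    if not np.all(np.isfinite(intensity)):
        raise ValueError("hologram contains non-finite values")
    if carrier is None:
        carrier = holo.carrier if holo.carrier is not None else detect_carrier(holo)
    k = float(np.hypot(*carrier))
    if k < MIN_CARRIER_CPP:
        raise ValueError(
            f"carrier too low ({k:.3f} cycles/px): sideband overlaps the DC term"
        )
    n_r, n_c = intensity.shape
    rr, cc = np.mgrid[0:n_r, 0:n_c]
    # demodulate: shift the +1 sideband to baseband
    demod = intensity * np.exp(-2j * np.pi * (carrier[0] * rr + carrier[1] * cc))
    spec = np.fft.fft2(demod)
    fr = np.fft.fftfreq(n_r)[:, None]
    fc = np.fft.fftfreq(n_c)[None, :]
    dist = np.hypot(fr, fc)
    radius = window_radius_frac * k
    edge = window_edge_frac * radius
    # raised-cosine circular low-pass
    win = np.zeros_like(dist)
    win[dist <= radius - edge] = 1.0
    ramp = (dist > radius - edge) & (dist < radius)
    win[ramp] = 0.5 * (1 + np.cos(np.pi * (dist[ramp] - (radius - edge)) / edge))
    # the sideband centred at +carrier is the conjugate cross term O*·R:
    # conjugating the demodulated field recovers the object phase with
    # its physical sign
    field = np.conj(np.fft.ifft2(spec * win))
    if refocus_um != 0.0:
        field = propagate(field, refocus_um, holo.wavelength_nm, holo.pixel_size_um)
    phi = np.angle(field)
    meta: dict = {"carrier": tuple(carrier), "refocus_um": refocus_um}
    if unwrap:
        phi = np.asarray(unwrap_phase(phi), dtype=np.float64)
        # residual wraps after unwrapping indicate an unreliable result
        jumps = np.abs(np.diff(phi, axis=0))
        if jumps.size and (jumps > np.pi).mean() > 0.05:
            meta["unwrap_suspect"] = True
    opd = phi * holo.wavelength_nm / (2.0 * np.pi)
    opd, background = flatten_background(opd, order=flatten_order)
    # pin the background to zero OPD
    if background.any():
        opd = opd - np.median(opd[background])
    return PhaseImage(opd, holo.pixel_size_um, meta=meta)
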