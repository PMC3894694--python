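"""Phase reconstruction: holographic demodulation and the TIE solver.

Accuracy is always judged by forward-model round trips against the known
synthetic input phase — the only available oracle, since reconstruction
inverts the forward models implemented here.
"""
from __future__ import annotations

import numpy as np
import pytest

from qpiscreen import PhaseImage
from qpiscreen.dhm import detect_carrier, reconstruct_hologram
from qpiscreen.optics import (
    DHM_WAVELENGTH_NM,
    Hologram,
    synthesize_defocus_stack,
    synthesize_hologram,
)
from qpiscreen.tie import compare_modalities, reconstruct_tie

MARGIN = 24  # px, excludes the forward-model taper


def _interior_rmse_rad(recon: PhaseImage, phi_truth: np.ndarray) -> float:
    err = recon.phase_rad(DHM_WAVELENGTH_NM)[MARGIN:-MARGIN, MARGIN:-MARGIN]
    err = err - phi_truth[MARGIN:-MARGIN, MARGIN:-MARGIN]
    err = err - err.mean()
    return float(np.sqrt((err**2).mean()))


class TestDetectCarrier:
    @pytest.mark.parametrize("carrier", [(0.25, 0.25), (0.25, -0.25), (0.15, 0.3)])
    def test_recovers_known_carrier_with_sign(self, smooth_bump, carrier):
        holo = synthesize_hologram(smooth_bump, carrier=carrier)
        est = detect_carrier(holo)
        n = holo.intensity.shape[0]
        assert abs(est[0] - carrier[0]) <= 1.0 / n
        assert abs(est[1] - carrier[1]) <= 1.0 / n

    def test_fringe_free_image_raises(self):
        holo = Hologram(np.ones((128, 128)), carrier=None)
        with pytest.raises(ValueError, match="carrier|peak"):
            detect_carrier(holo)


class TestReconstructHologram:
    def test_null_object_reconstructs_flat(self, flat_field):
        recon = reconstruct_hologram(synthesize_hologram(flat_field))
        assert recon.opd.std() < 1.0  # nm

    def test_round_trip_on_smooth_object(self, smooth_bump):
        phi = smooth_bump.phase_rad(DHM_WAVELENGTH_NM)
        recon = reconstruct_hologram(synthesize_hologram(smooth_bump))
        assert _interior_rmse_rad(recon, phi) < 0.05

    def test_linearity_doubling_opd_doubles_reconstruction(self, smooth_bump):
        doubled = PhaseImage(2 * smooth_bump.opd, smooth_bump.pixel_size_um)
        r1 = reconstruct_hologram(synthesize_hologram(smooth_bump))
        r2 = reconstruct_hologram(synthesize_hologram(doubled))
        sl = (slice(MARGIN, -MARGIN), slice(MARGIN, -MARGIN))
        mask = smooth_bump.opd[sl] > 20.0
        slope = np.polyfit(r1.opd[sl][mask], r2.opd[sl][mask], 1)[0]
        assert slope == pytest.approx(2.0, rel=0.02)

    def test_numerical_refocus_restores_defocused_hologram(self, smooth_bump):
        phi = smooth_bump.phase_rad(DHM_WAVELENGTH_NM)
        in_focus = _interior_rmse_rad(
            reconstruct_hologram(synthesize_hologram(smooth_bump)), phi
        )
        refocused = _interior_rmse_rad(
            reconstruct_hologram(
                synthesize_hologram(smooth_bump, defocus_um=10.0),
                refocus_um=-10.0,
            ),
            phi,
        )
        assert refocused < 2.0 * in_focus

    def test_phase_independent_of_reference_amplitude(self, smooth_bump):
        r1 = reconstruct_hologram(
            synthesize_hologram(smooth_bump, reference_amplitude=1.0),
            flatten_order=0,
        )
        r2 = reconstruct_hologram(
            synthesize_hologram(smooth_bump, reference_amplitude=5.0),
            flatten_order=0,
        )
        d = (r2.phase_rad(DHM_WAVELENGTH_NM) - r1.phase_rad(DHM_WAVELENGTH_NM))
        d = d - d.mean()
        assert np.abs(d).max() < 1e-6

    def test_low_carrier_rejected(self, smooth_bump):
        holo = synthesize_hologram(smooth_bump, carrier=(0.02, 0.02))
        with pytest.raises(ValueError, match="carrier too low"):
            reconstruct_hologram(holo)


class TestReconstructTie:
    def test_identical_planes_give_zero_phase(self):
        from qpiscreen.optics import IntensityStack

        stack = IntensityStack(np.ones((3, 64, 64)), z_offsets_um=(-5.0, 0.0, 5.0))
        recon = reconstruct_tie(stack)
        assert np.abs(recon.opd).max() < 1e-12

    def test_round_trip_on_smooth_object(self, smooth_bump):
        stack = synthesize_defocus_stack(smooth_bump, z_offsets_um=(-5, 0, 5))
        recon = reconstruct_tie(stack)
        cmp_ = compare_modalities(smooth_bump, recon, margin_px=MARGIN)
        sl = (slice(MARGIN, -MARGIN), slice(MARGIN, -MARGIN))
        mf = smooth_bump.opd[sl] - smooth_bump.opd[sl].mean()
        rel = cmp_.rmse_nm / np.sqrt((mf**2).mean())
        assert rel < 0.10

    def test_error_shrinks_as_defocus_halves(self, smooth_bump):
        errors = []
        for dz in (5.0, 2.5, 1.25):
            stack = synthesize_defocus_stack(smooth_bump, z_offsets_um=(-dz, 0, dz))
            cmp_ = compare_modalities(
                smooth_bump, reconstruct_tie(stack), margin_px=MARGIN
            )
            errors.append(cmp_.rmse_nm)
        assert errors[0] > errors[1] > errors[2]

    def test_solver_is_linear_in_the_derivative_signal(self):
        from qpiscreen.optics import IntensityStack

        rng = np.random.default_rng(0)
        base = np.ones((64, 64))
        delta = 0.01 * np.real(
            np.fft.ifft2(
                np.fft.fft2(rng.normal(size=(64, 64)))
                * (np.hypot(*np.meshgrid(np.fft.fftfreq(64), np.fft.fftfreq(64))) < 0.2)
            )
        )
        def recon_for(amDuring):
            planes = np.stack([base - amDuring * delta, base, base + amDuring * delta])
            return reconstruct_tie(
                IntensityStack(np.clip(planes, 0, None), z_offsets_um=(-5.0, 0.0, 5.0))
            ).opd
        a, b = recon_for(1.0), recon_for(3.0)
        assert np.allclose(3.0 * a, b, rtol=1e-6, atol=1e-9)

    def test_asymmetric_offsets_need_explicit_mode(self, smooth_bump):
        stack = synthesize_defocus_stack(smooth_bump, z_offsets_um=(-2, 0, 5))
        with pytest.raises(ValueError, match="symmetric"):
            reconstruct_tie(stack)
        recon = reconstruct_tie(stack, allow_two_plane=True)
        assert recon.opd.shape == smooth_bump.opd.shape

    def test_modalities_agree_on_smooth_cells(self, smooth_bump):
        # quantitative consistency: holographic and TIE reconstructions of
        # the same object correlate strongly
        dhm_recon = reconstruct_hologram(synthesize_hologram(smooth_bump))
        stack = synthesize_defocus_stack(smooth_bump, z_offsets_um=(-5, 0, 5))
        tie_recon = reconstruct_tie(stack)
        cmp_ = compare_modalities(dhm_recon, tie_recon, margin_px=MARGIN)
        assert cmp_.correlation > 0.95


class TestCompareModalities:
    def test_identity(self, smooth_bump):
        cmp_ = compare_modalities(smooth_bump, smooth_bump, margin_px=8)
        assert cmp_.rmse_nm == 0.0
        assert cmp_.correlation == pytest.approx(1.0)

    def test_constant_offset_is_invisible(self, smooth_bump):
        shifted = PhaseImage(smooth_bump.opd + 37.0, smooth_bump.pixel_size_um)
        cmp_ = compare_modalities(smooth_bump, shifted, margin_px=8)
        assert cmp_.rmse_nm == pytest.approx(0.0, abs=1e-9)

    def test_sign_flip_gives_anticorrelation(self, smooth_bump):
        flipped = PhaseImage(-smooth_bump.opd, smooth_bump.pixel_size_um)
        cmp_ = compare_modalities(smooth_bump, flipped, margin_px=8)
        assert cmp_.correlation == pytest.approx(-1.0)

    def test_margin_too_large_rejected(self, smooth_bump):
        with pytest.raises(ValueError, match="margin"):
            compare_modalities(smooth_bump, smooth_bump, margin_px=128)
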