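"""Synthetic phantom generator: physics, determinism, plate structure."""
from __future__ import annotations

import numpy as np
import pytest

from qpiscreen import synth
from qpiscreen.synth import (
    CellOpticalModel,
    DoseEffect,
    DoseModel,
    PlacedCell,
    place_cells,
    render_field,
    render_field_with_truth,
    simulate_plate,
    simulate_timelapse,
    spec_for,
)


def _plateau_cell(n_px: int = 64) -> np.ndarray:
    d = np.zeros((n_px, n_px))
    d[16:48, 16:48] = 1.0  # 1 um plateau
    return d


class TestOpticalModel:
    def test_opd_relation_hand_arithmetic(self):
        # 1 um thickness at n_c=1.38, n_m=1.33 -> OPD = 0.05 um = 50 nm
        model = CellOpticalModel(_plateau_cell(), n_c=1.38, n_m=1.33)
        opd = model.opd_nm()
        assert opd[32, 32] == pytest.approx(50.0, abs=1e-9)
        assert opd[0, 0] == 0.0

    def test_negative_thickness_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            CellOpticalModel(-_plateau_cell())

    def test_inverted_contrast_rejected(self):
        with pytest.raises(ValueError, match="n_c"):
            CellOpticalModel(_plateau_cell(), n_c=1.30, n_m=1.334)


class TestRenderField:
    def test_empty_field_is_zero(self):
        phase = render_field([], field_size=(64, 64), noise_sd_nm=0.0, seed=0)
        assert np.all(phase.opd == 0.0)

    def test_opd_relation_holds_pixelwise_noise_free(self):
        cells = place_cells(["control", "round"], field_size=(128, 128), rng=0)
        phase, truth = render_field_with_truth(
            cells, field_size=(128, 128), noise_sd_nm=0.0, seed=0
        )
        # rebuild the thickness sum independently and apply the relation
        thickness = np.zeros((128, 128))
        for cell in cells:
            sl_r, sl_c, d = synth._cell_thickness(cell, (128, 128), 0.62)
            thickness[sl_r, sl_c] += d
        expected = thickness * (synth.N_CELL_DEFAULT - synth.N_MEDIUM_DEFAULT) * 1e3
        assert np.max(np.abs(phase.opd - expected)) < 1e-9

    def test_same_seed_bit_identical(self):
        cells = place_cells(["control"] * 4, field_size=(128, 128), rng=3)
        a = render_field(cells, field_size=(128, 128), seed=42)
        b = render_field(cells, field_size=(128, 128), seed=42)
        assert np.array_equal(a.opd, b.opd)

    def test_half_contrast_halves_integrated_opd(self):
        # same geometry, contrast scale 0.5 -> exactly half the OPD signal
        hela = place_cells(["control"] * 3, cell_type="hela", rng=7)
        h9c2 = [
            PlacedCell(
                spec=spec_for(c.spec.class_name, "h9c2"),
                row=c.row, col=c.col, orientation_rad=c.orientation_rad,
                size_jitter=c.size_jitter, thickness_jitter=c.thickness_jitter,
                vesicle_offsets_um=c.vesicle_offsets_um,
            )
            for c in hela
        ]
        _, t_hi = render_field_with_truth(hela, noise_sd_nm=0.0, seed=0)
        _, t_lo = render_field_with_truth(h9c2, noise_sd_nm=0.0, seed=0)
        ratio = t_lo.integrated_opd_nm_px.mean() / t_hi.integrated_opd_nm_px.mean()
        assert ratio == pytest.approx(0.5, abs=0.05)

    def test_overlap_rejected_when_flagged(self):
        spec = spec_for("round")
        cells = [
            PlacedCell(spec, 64.0, 64.0),
            PlacedCell(spec, 64.0, 66.0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            render_field(cells, field_size=(128, 128), non_overlap=True, seed=0)

    def test_position_outside_field_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            render_field(
                [PlacedCell(spec_for("round"), 500.0, 10.0)],
                field_size=(128, 128),
                seed=0,
            )


class TestPhenotypeGeometry:
    def test_control_is_elongated(self):
        s = spec_for("control")
        assert s.semi_major_um / s.semi_minor_um > 2

    def test_round_has_higher_peak_opd_than_control(self):
        assert (
            spec_for("round").peak_thickness_um
            > spec_for("control").peak_thickness_um
        )

    def test_vesicle_class_carries_puncta_and_reduced_footprint(self):
        v, c = spec_for("vesicle"), spec_for("control")
        assert v.vesicle_count > 0
        assert v.footprint_area_um2 < c.footprint_area_um2


class TestDoseModel:
    def test_vehicle_concentration_gives_bottom(self):
        m = DoseModel(0.1, 0.9, 10.0, 1.5)
        assert m.response(0.0) == pytest.approx(0.1)

    def test_saturating_concentration_approaches_top(self):
        m = DoseModel(0.1, 0.9, 10.0, 1.5)
        assert m.response(1e6) == pytest.approx(0.9, abs=1e-3)

    def test_monotone_in_concentration(self):
        m = DoseModel(0.0, 1.0, 10.0, 2.0)
        c = np.logspace(-2, 4, 50)
        r = np.asarray(m.response(c))
        assert np.all(np.diff(r) > 0)

    def test_validation(self):
        with pytest.raises(ValueError):
            DoseModel(0.0, 1.0, -5.0, 1.0)
        with pytest.raises(ValueError):
            DoseModel(0.5, 0.5, 5.0, 1.0)


class TestSimulatePlate:
    def _design(self, n_rep=2, seed=0):
        return synth.endpoint_design(
            cell_types=["hela"],
            compounds=["doxorubicin"],
            n_replicates=n_rep,
            field_size=(96, 96),
            seed=seed,
        )

    def test_field_count_matches_design(self):
        design = synth.endpoint_design(
            cell_types=["hela"], compounds=["doxorubicin"],
            include_vehicle=False, n_replicates=16, field_size=(96, 96),
        )
        models = {"doxorubicin": DoseModel(0.03, 0.95, 3.0, 1.5)}
        renders = list(simulate_plate(design, models))
        assert len(renders) == 16 * 4  # 16 replicate wells x 4 fields

    def test_unknown_condition_raises_descriptive_error(self):
        design = self._design()
        with pytest.raises(KeyError, match="no dose model"):
            list(simulate_plate(design, {"staurosporine": DoseModel(0, 1, 1, 1)}))

    def test_vehicle_wells_express_baseline_fraction(self):
        design = self._design(n_rep=4, seed=1)
        models = {"doxorubicin": DoseModel(0.0, 0.95, 3.0, 1.5)}
        for fr in simulate_plate(design, models):
            if fr.well.concentration_um == 0:
                assert (fr.truth["class"] == "control").all()

    def test_saturating_dose_expresses_top_fraction(self):
        design = synth.endpoint_design(
            cell_types=["hela"], compounds=["doxorubicin"],
            concentration_um=1e5, include_vehicle=False, n_replicates=6,
            field_size=(96, 96), seed=2,
        )
        models = {"doxorubicin": DoseModel(0.0, 0.8, 3.0, 1.5)}
        fracs = [
            (fr.truth["class"] == "round").mean()
            for fr in simulate_plate(design, models)
        ]
        assert np.mean(fracs) == pytest.approx(0.8, abs=0.1)

    def test_deterministic_for_fixed_seed(self):
        models = {"doxorubicin": DoseModel(0.03, 0.95, 3.0, 1.5)}
        a = [fr.phase.opd for fr in simulate_plate(self._design(seed=5), models)]
        b = [fr.phase.opd for fr in simulate_plate(self._design(seed=5), models)]
        assert all(np.array_equal(x, y) for x, y in zip(a, b))


class TestSimulateTimelapse:
    EFFECT = {
        "doxorubicin": DoseEffect(
            DoseModel(0.03, 0.95, 3.0, 1.5), "round", onset_h=4.0, ramp_h=0.5
        )
    }

    def _design(self, seed=0):
        return synth.dose_design(
            cell_type="hela", compound="doxorubicin", n_doses=1,
            include_vehicle=False, field_size=(64, 64), seed=seed,
        )

    def test_default_protocol_yields_145_time_points(self):
        frames = list(
            simulate_timelapse(
                self._design(), self.EFFECT, interval_min=10.0, duration_h=24.0
            )
        )
        times = sorted({f.t_h for f in frames})
        assert len(times) == 145  # 24 h / 10 min + t=0

    def test_interval_must_divide_duration(self):
        with pytest.raises(ValueError, match="divide"):
            list(
                simulate_timelapse(
                    self._design(), self.EFFECT, interval_min=7.0, duration_h=24.0
                )
            )

    def test_series_is_baseline_before_onset(self):
        frames = [
            f
            for f in simulate_timelapse(
                self._design(), self.EFFECT, interval_min=60.0, duration_h=8.0
            )
        ]
        pre = [f for f in frames if f.t_h < 4.0]
        assert all((f.truth["class"] == "control").all() for f in pre)
        post = [f for f in frames if f.t_h >= 6.0]
        assert any((f.truth["class"] == "round").any() for f in post)

    def test_onset_beyond_duration_warns_and_stays_flat(self):
        effect = {
            "doxorubicin": DoseEffect(
                DoseModel(0.03, 0.95, 3.0, 1.5), "round", onset_h=30.0
            )
        }
        with pytest.warns(UserWarning, match="onset"):
            frames = list(
                simulate_timelapse(
                    self._design(), effect, interval_min=60.0, duration_h=4.0
                )
            )
        assert all((f.truth["class"] == "control").all() for f in frames)
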