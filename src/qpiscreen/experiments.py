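"""Reference screen experiments on fully synthetic plates.

These functions wire the whole pipeline together for the three study
designs the package is built around, with the plate structure of a
real label-free screen (4 fields/well, 12-16 replicate wells per
condition, 25-60% confluency, 10-min time-lapse):

* an endpoint Z'-factor screen of a strong cytotoxic phenotype, run per
  cell-type contrast regime;
* a serial-dilution time-lapse in which vesicle formation (low EC50,
  near-immediate onset) precedes cell rounding (high EC50, late onset),
  exposing the different sensitivity of the average-OPD and per-cell
  phenotype-fraction readouts;
* a single-dose time-lapse with a programmed response onset.

They are used by the acceptance checks and make convenient entry points
for exploring how assay quality reacts to the simulation parameters.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from . import metrics as metrics_mod
from . import stats as stats_mod
from . import synth
from .phenotype import PhenotypeClassifier, train_classifier
from .pipeline import ec50_from_timelapse, generate_training_records, timelapse_readouts
from .stats import DoseResponseFit, ZPrimeResult

__all__ = [
    "endpoint_zprime",
    "readout_ec50_pair",
    "onset_recovery",
    "STRONG_EFFECT",
    "DUAL_EFFECTS",
]

#: strong single-phenotype effect (rounding), near-saturated at 30 uM
STRONG_EFFECT = synth.DoseModel(bottom=0.03, top=0.95, ec50_um=3.0, hill=1.5)

#: dual-phenotype kinetics: vesicles come early and at low dose, rounding
#: late and only at high dose (the autophagy-then-death sequence)
DUAL_EFFECTS = [
    synth.DoseEffect(
        synth.DoseModel(bottom=0.0, top=0.6, ec50_um=247.0, hill=1.0),
        "round", onset_h=5.0, ramp_h=2.0,
    ),
    synth.DoseEffect(
        synth.DoseModel(bottom=0.02, top=0.9, ec50_um=15.0, hill=1.2),
        "vesicle", onset_h=0.15, ramp_h=0.5,
    ),
]


def endpoint_zprime(
    cell_type: str,
    seed: int,
    *,
    n_replicates: int = 16,
    field_size: tuple[int, int] = (192, 192),
    concentration_um: float = 30.0,
    readout: str = "average_opd",
) -> ZPrimeResult:
    """Endpoint screen of the rounding phenotype: Z' of treated vs vehicle.

    One condition group of ``n_replicates`` wells (4 fields each) per arm,
    read out through the average-OPD metric.
    """
    design = synth.endpoint_design(
        cell_types=[cell_type],
        compounds=["doxorubicin"],
        concentration_um=concentration_um,
        n_replicates=n_replicates,
        fields_per_well=4,
        field_size=field_size,
        seed=seed,
    )
    rows = []
    for fr in synth.simulate_plate(design, {"doxorubicin": STRONG_EFFECT}):
        fm = metrics_mod.field_metrics(fr.phase)
        rows.append(
            {
                "well": fr.well.well_id,
                "field": fr.field_index,
                "average_opd": fm.average_opd_nm,
            }
        )
    wells = stats_mod.aggregate_wells(pd.DataFrame(rows), design)
    pos = wells.loc[wells.concentration_um > 0, readout].to_numpy()
    neg = wells.loc[wells.concentration_um == 0, readout].to_numpy()
    return stats_mod.z_prime(pos, neg)


def _classifier_for(cell_type: str, seed: int, field_size) -> PhenotypeClassifier:
    records, labels = generate_training_records(
        cell_type, 60, seed, field_size=field_size
    )
    return train_classifier(records, labels, seed=seed)


def readout_ec50_pair(
    seed: int,
    *,
    cell_type: str = "h9c2",
    duration_h: float = 12.0,
    field_size: tuple[int, int] = (128, 128),
    top_concentration_um: float = 1000.0,
    n_doses: int = 7,
) -> dict[str, DoseResponseFit]:
    """Serial-dilution time-lapse with early vesicles and late rounding.

    Returns 4PL fits of the per-well AUC for the average-OPD readout and
    for the per-cell phenotype-fraction readouts. Because vesicles barely
    move the average OPD while rounding moves it strongly, the fraction
    readouts lock onto the low-EC50 vesicle effect and the OPD readout
    onto the high-EC50 rounding effect.
    """
    design = synth.dose_design(
        cell_type=cell_type,
        compound="chloroquine",
        top_concentration_um=top_concentration_um,
        n_doses=n_doses,
        wells_per_dose=1,
        fields_per_well=1,
        field_size=field_size,
        seed=seed,
    )
    classifier = _classifier_for(cell_type, seed, field_size)
    frames = timelapse_readouts(
        design,
        {"chloroquine": DUAL_EFFECTS},
        classifier,
        interval_min=10.0,
        duration_h=duration_h,
    )
    return {
        "average_opd": ec50_from_timelapse(frames, "average_opd", seed=seed),
        "fraction_vesicle": ec50_from_timelapse(frames, "fraction_vesicle", seed=seed),
        "fraction_phenotype": ec50_from_timelapse(
            frames, "fraction_phenotype", seed=seed
        ),
    }


def onset_recovery(
    seed: int,
    *,
    onset_h: float = 4.0,
    duration_h: float = 8.0,
    field_size: tuple[int, int] = (128, 128),
    baseline_window_h: float = 2.0,
) -> float | None:
    """Detect the onset of a programmed rounding response from time-lapse.

    Two wells at a saturating dose, imaged every 10 min; the detector runs
    on the well-averaged average-OPD series.
    """
    design = synth.dose_design(
        cell_type="hela",
        compound="doxorubicin",
        top_concentration_um=30.0,
        n_doses=1,
        wells_per_dose=2,
        include_vehicle=False,
        fields_per_well=1,
        field_size=field_size,
        seed=seed,
    )
    effect = synth.DoseEffect(STRONG_EFFECT, "round", onset_h=onset_h, ramp_h=0.5)
    frames = timelapse_readouts(
        design, {"doxorubicin": effect}, None,
        interval_min=10.0, duration_h=duration_h,
    )
    series = frames.groupby("t_h")["average_opd"].mean()
    return stats_mod.detect_onset(
        series.index.to_numpy(),
        series.to_numpy(),
        baseline_window_h=baseline_window_h,
    )
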