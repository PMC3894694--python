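"""End-to-end screen driver: simulate → reconstruct → measure → classify → stats.

The whole run is configured by one YAML document with sections
``plate``, ``optics``, ``metrics``, ``classifier`` and ``stats``; every
parameter the underlying method does not pin down (thresholds, carrier,
regularization, ...) lives here with a documented default. A single
top-level ``seed`` drives all randomness and is recorded in the report,
making a run idempotent for a fixed config.

Three imaging modalities are supported for the synthetic plate:
``truth`` (the rendered OPD map, no optics), ``dhm`` (off-axis hologram
forward model + demodulation) and ``tie`` (3-plane defocus stack +
transport-of-intensity solve).
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import dhm as dhm_mod
from . import metrics as metrics_mod
from . import phenotype as phen_mod
from . import stats as stats_mod
from . import synth, tie
from .optics import synthesize_defocus_stack, synthesize_hologram
from .phase import PhaseImage

__all__ = [
    "ConfigError",
    "load_config",
    "run_pipeline",
    "generate_training_records",
    "timelapse_readouts",
    "ec50_from_timelapse",
]

log = logging.getLogger("qpiscreen")

MODALITIES = ("truth", "dhm", "tie")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "modality": "truth",
    "plate": {
        "cell_types": ["hela"],
        "compounds": ["doxorubicin"],
        "concentration_um": 30.0,
        "n_replicates": 12,
        "fields_per_well": 4,
        "field_size": [192, 192],
        "pixel_size_um": synth.PIXEL_SIZE_UM,
    },
    "dose_models": {
        "doxorubicin": {"bottom": 0.03, "top": 0.95, "ec50_um": 3.0, "hill": 1.5},
        "chloroquine": {"bottom": 0.03, "top": 0.95, "ec50_um": 15.0, "hill": 1.2},
    },
    "optics": {
        "carrier": [0.25, 0.25],
        "dz_um": 5.0,
        "tie_regularization": tie.DEFAULT_REGULARIZATION,
        "taper_px": 16,
    },
    "metrics": {
        "threshold_nm": metrics_mod.CONFLUENCY_THRESHOLD_NM,
        "blur_sigma_px": metrics_mod.BLUR_SIGMA_PX,
        "prominence_nm": metrics_mod.PROMINENCE_NM,
    },
    "classifier": {
        "enabled": True,
        "n_train_per_class": 60,
        "family": "boosted_trees",
    },
    "stats": {"readouts": ["average_opd", "fraction_round", "fraction_vesicle"]},
}


class ConfigError(ValueError):
    """Configuration schema violation, reported with its field path."""


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(source: str | Path | Mapping | None = None) -> dict[str, Any]:
    """Merge a YAML file / mapping over the documented defaults and validate."""
    if source is None:
        user: Mapping = {}
    elif isinstance(source, Mapping):
        user = source
    else:
        user = yaml.safe_load(Path(source).read_text()) or {}
    cfg = _merge(DEFAULT_CONFIG, user)
    if cfg["modality"] not in MODALITIES:
        raise ConfigError(
            f"modality: {cfg['modality']!r} not one of {MODALITIES}"
        )
    plate = cfg["plate"]
    if plate["n_replicates"] < 2:
        raise ConfigError("plate.n_replicates: need at least 2 wells per group")
    for ct in plate["cell_types"]:
        if ct not in synth.CELL_TYPE_CONTRAST:
            raise ConfigError(
                f"plate.cell_types: unknown cell type {ct!r} "
                f"(known: {sorted(synth.CELL_TYPE_CONTRAST)})"
            )
    for cmpd in plate["compounds"]:
        if cmpd not in cfg["dose_models"]:
            raise ConfigError(f"dose_models: no model for compound {cmpd!r}")
    return cfg


def generate_training_records(
    cell_type: str,
    n_per_class: int,
    seed: int,
    *,
    field_size: tuple[int, int] = (192, 192),
    pixel_size_um: float = synth.PIXEL_SIZE_UM,
    noise_sd_nm: float = synth.NOISE_SD_NM,
    cells_per_field: int = 6,
    threshold_nm: float = metrics_mod.CONFLUENCY_THRESHOLD_NM,
) -> tuple[list[phen_mod.CellRecord], list[str]]:
    """Labelled training cells: single-class fields, segmented and featurized.

    Rendering each training field with cells of one known class makes the
    labels exact without any centroid matching.
    """
    records: list[phen_mod.CellRecord] = []
    labels: list[str] = []
    for c_idx, cls_name in enumerate(phen_mod.PHENOTYPE_CLASSES):
        produced = 0
        f_idx = 0
        while produced < n_per_class:
            rng = np.random.default_rng([seed, 77, c_idx, f_idx])
            cells = synth.place_cells(
                [cls_name] * cells_per_field,
                cell_type=cell_type,
                field_size=field_size,
                pixel_size_um=pixel_size_um,
                rng=rng,
            )
            phase = synth.render_field(
                cells,
                pixel_size_um=pixel_size_um,
                field_size=field_size,
                noise_sd_nm=noise_sd_nm,
                seed=rng,
            )
            lab, err = phen_mod.segment_cells(phase, threshold_nm)
            for rec in phen_mod.extract_features(phase, lab):
                if not err.get(rec.label_id, False):
                    records.append(rec)
                    labels.append(cls_name)
                    produced += 1
            f_idx += 1
            if f_idx > 20 * n_per_class:
                raise RuntimeError("training field generation stalled")
    return records, labels


def timelapse_readouts(
    design: synth.PlateDesign,
    dose_effects: Mapping[str, Any],
    classifier: phen_mod.PhenotypeClassifier | None = None,
    *,
    interval_min: float = 10.0,
    duration_h: float = 24.0,
    threshold_nm: float = metrics_mod.CONFLUENCY_THRESHOLD_NM,
) -> pd.DataFrame:
    """Per-frame readouts of a simulated time-lapse plate.

    Returns a tidy table (well, concentration, t_h, average_opd and —
    when a classifier is given — fraction_round / fraction_vesicle /
    fraction_phenotype, the round-or-vesicle fraction the per-cell
    analysis reports).
    """
    rows = []
    for fr in synth.simulate_timelapse(
        design, dose_effects, interval_min=interval_min, duration_h=duration_h
    ):
        fm = metrics_mod.field_metrics(fr.phase, threshold_nm=threshold_nm)
        row = {
            "well": fr.well.well_id,
            "field": fr.field_index,
            "concentration_um": fr.well.concentration_um,
            "t_h": fr.t_h,
            "average_opd": fm.average_opd_nm,
        }
        if classifier is not None:
            try:
                fractions, _ = phen_mod.score_field(
                    fr.phase, classifier, threshold_nm=threshold_nm
                )
                row["fraction_round"] = fractions.fraction_round
                row["fraction_vesicle"] = fractions.fraction_vesicle
                row["fraction_phenotype"] = (
                    fractions.fraction_round + fractions.fraction_vesicle
                )
            except ValueError:
                row["fraction_round"] = np.nan
                row["fraction_vesicle"] = np.nan
                row["fraction_phenotype"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def ec50_from_timelapse(
    frames: pd.DataFrame,
    readout: str,
    *,
    baseline_subtract: bool = True,
    seed: int = 0,
) -> stats_mod.DoseResponseFit:
    """Fit a 4PL dose-response to per-well AUCs of a time-lapse readout.

    The AUC condenses each well's series into one number; wells at zero
    concentration provide the vehicle response, placed two logs below the
    lowest tested dose by the fitter.
    """
    aucs = []
    for (well, conc), grp in frames.groupby(["well", "concentration_um"]):
        grp = grp.sort_values("t_h")
        series = grp.groupby("t_h")[readout].mean()
        aucs.append(
            {
                "well": well,
                "concentration_um": conc,
                "auc": stats_mod.timelapse_auc(
                    series.index.to_numpy(),
                    series.to_numpy(),
                    baseline_subtract=baseline_subtract,
                ),
            }
        )
    auc_df = pd.DataFrame(aucs)
    dosed = auc_df[auc_df["concentration_um"] > 0]
    vehicle = auc_df[auc_df["concentration_um"] == 0]
    vehicle_response = float(vehicle["auc"].mean()) if len(vehicle) else None
    return stats_mod.fit_dose_response(
        dosed["concentration_um"].to_numpy(),
        dosed["auc"].to_numpy(),
        vehicle_response,
        seed=seed,
    )


def _image_for_modality(
    truth_phase: PhaseImage, modality: str, optics_cfg: Mapping, seed: int
) -> PhaseImage:
    if modality == "truth":
        return truth_phase
    if modality == "dhm":
        holo = synthesize_hologram(
            truth_phase,
            carrier=tuple(optics_cfg["carrier"]),
            taper_px=int(optics_cfg["taper_px"]),
            seed=seed,
        )
        return dhm_mod.reconstruct_hologram(holo)
    if modality == "tie":
        dz = float(optics_cfg["dz_um"])
        stack = synthesize_defocus_stack(
            truth_phase,
            z_offsets_um=(-dz, 0.0, dz),
            taper_px=int(optics_cfg["taper_px"]),
        )
        recon = tie.reconstruct_tie(
            stack, regularization=float(optics_cfg["tie_regularization"])
        )
        # re-anchor the mean-free TIE phase so the background sits at 0 OPD
        opd, background = dhm_mod.flatten_background(recon.opd, order=0)
        if background.any():
            opd = opd - np.median(opd[background])
        return PhaseImage(opd, recon.pixel_size_um, meta=recon.meta)
    raise ConfigError(f"modality: unknown {modality!r}")


def run_pipeline(
    config: str | Path | Mapping | None = None,
    output_dir: str | Path | None = None,
) -> dict[str, Any]:
    """Run the full synthetic screen and return (and optionally write) a report.

    Stages: simulate plate → image through the chosen modality → global
    metrics per field → per-cell classification → well aggregation →
    Z'-factor per condition and readout. CSV tables and a JSON-able
    report are written to ``output_dir`` when given.
    """
    cfg = load_config(config)
    seed = int(cfg["seed"])
    modality = cfg["modality"]
    plate_cfg = cfg["plate"]
    log.info("pipeline start: modality=%s seed=%d", modality, seed)
    design = synth.endpoint_design(
        cell_types=plate_cfg["cell_types"],
        compounds=plate_cfg["compounds"],
        concentration_um=float(plate_cfg["concentration_um"]),
        n_replicates=int(plate_cfg["n_replicates"]),
        fields_per_well=int(plate_cfg["fields_per_well"]),
        field_size=tuple(plate_cfg["field_size"]),
        pixel_size_um=float(plate_cfg["pixel_size_um"]),
        seed=seed,
    )
    dose_models = {
        name: synth.DoseModel(**params)
        for name, params in cfg["dose_models"].items()
    }
    clf_cfg = cfg["classifier"]
    classifiers: dict[str, phen_mod.PhenotypeClassifier] = {}
    if clf_cfg["enabled"]:
        for ct in plate_cfg["cell_types"]:
            recs, labs = generate_training_records(
                ct,
                int(clf_cfg["n_train_per_class"]),
                seed,
                field_size=tuple(plate_cfg["field_size"]),
                pixel_size_um=float(plate_cfg["pixel_size_um"]),
            )
            classifiers[ct] = phen_mod.train_classifier(
                recs, labs, seed=seed, modality=modality,
                family=clf_cfg["family"],
            )
            log.info(
                "classifier[%s]: holdout accuracy %.3f",
                ct, classifiers[ct].holdout_accuracy,
            )
    m_cfg = cfg["metrics"]
    rows = []
    for fr in synth.simulate_plate(design, dose_models):
        phase = _image_for_modality(fr.phase, modality, cfg["optics"], seed)
        fm = metrics_mod.field_metrics(
            phase,
            threshold_nm=float(m_cfg["threshold_nm"]),
            blur_sigma_px=float(m_cfg["blur_sigma_px"]),
            prominence_nm=float(m_cfg["prominence_nm"]),
        )
        row = {
            "well": fr.well.well_id,
            "field": fr.field_index,
            "cell_count": fm.cell_count,
            "confluency": fm.confluency,
            "total_opd": fm.total_opd_nm_px,
            "average_opd": fm.average_opd_nm,
        }
        if clf_cfg["enabled"]:
            try:
                fractions, _ = phen_mod.score_field(
                    phase,
                    classifiers[fr.well.cell_type],
                    threshold_nm=float(m_cfg["threshold_nm"]),
                )
                row["fraction_round"] = fractions.fraction_round
                row["fraction_vesicle"] = fractions.fraction_vesicle
            except ValueError:
                row["fraction_round"] = np.nan
                row["fraction_vesicle"] = np.nan
        rows.append(row)
    fields_df = pd.DataFrame(rows).sort_values(["well", "field"]).reset_index(drop=True)
    wells_df = stats_mod.aggregate_wells(fields_df.drop(columns=[]), design)
    readouts = [
        r for r in cfg["stats"]["readouts"] if r in wells_df.columns
    ]
    zprime_rows = []
    for ct in plate_cfg["cell_types"]:
        for cmpd in plate_cfg["compounds"]:
            sel = (wells_df["cell_type"] == ct) & (wells_df["compound"] == cmpd)
            pos = wells_df[sel & (wells_df["concentration_um"] > 0)]
            neg = wells_df[sel & (wells_df["concentration_um"] == 0)]
            if len(pos) < 2 or len(neg) < 2:
                continue
            for readout in readouts:
                zr = stats_mod.z_prime(
                    pos[readout].to_numpy(), neg[readout].to_numpy()
                )
                zprime_rows.append(
                    {
                        "cell_type": ct,
                        "compound": cmpd,
                        "readout": readout,
                        "z_prime": zr.z_prime,
                        "mu_pos": zr.mu_pos,
                        "sd_pos": zr.sd_pos,
                        "mu_neg": zr.mu_neg,
                        "sd_neg": zr.sd_neg,
                        "valid": zr.valid,
                    }
                )
    zprime_df = pd.DataFrame(zprime_rows)
    report: dict[str, Any] = {
        "seed": seed,
        "modality": modality,
        "n_wells": len(design.wells),
        "n_fields": len(fields_df),
        "readouts": readouts,
        "z_prime": {
            f"{r['cell_type']}:{r['compound']}:{r['readout']}": r["z_prime"]
            for r in zprime_rows
        },
        "classifier_accuracy": {
            ct: clf.holdout_accuracy for ct, clf in classifiers.items()
        },
    }
    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        fields_df.to_csv(out / "fields.csv", index=False)
        wells_df.to_csv(out / "wells.csv", index=False)
        zprime_df.to_csv(out / "zprime.csv", index=False)
        (out / "report.json").write_text(
            __import__("json").dumps(report, indent=2, sort_keys=True)
        )
    report["fields"] = fields_df
    report["wells"] = wells_df
    report["zprime_table"] = zprime_df
    return report
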