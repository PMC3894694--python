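"""Synthetic quantitative-phase plates with drug-induced phenotypes.

Generates seeded OPD phantoms that emulate a label-free phenotypic screen:
96-well plates, 4 fields of view per well, 12-16 replicate wells per
condition, 25-60% confluency, and three morphological classes —

* ``control``  — elongated, well-attached cells (aspect ratio > 2),
* ``round``    — rounded-up, high-OPD cells (the dying-cell phenotype),
* ``vesicle``  — less-attached cells with a reduced footprint carrying
  small high-OPD puncta (the autophagy-like phenotype).

Two contrast regimes mimic the two cell types: a high-contrast compact
line (``hela``) and a flat low-contrast line (``h9c2``) with half the OPD
signal at identical geometry.

OPD follows the thin-specimen relation ``OPD(x, y) = d(x, y) · (n_c − n_m)``
with ``d`` the cell thickness and ``n_c``/``n_m`` the intracellular and
medium refractive indices. Thickness profiles are smooth squared-cosine
caps so that downstream holographic / transport-of-intensity round trips
are well-posed.

Drug response is generated from a four-parameter logistic (4PL) dose
model: the fraction of cells expressing the treated phenotype in a well
follows the model evaluated at the well's concentration.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .phase import PhaseImage

__all__ = [
    "CellOpticalModel",
    "PhenotypeSpec",
    "PlacedCell",
    "WellSpec",
    "PlateDesign",
    "DoseModel",
    "DoseEffect",
    "FieldRender",
    "PHENOTYPES",
    "CELL_TYPE_CONTRAST",
    "COMPOUND_PHENOTYPE",
    "spec_for",
    "place_cells",
    "render_field",
    "render_field_with_truth",
    "simulate_plate",
    "simulate_timelapse",
    "endpoint_design",
    "dose_design",
]

#: default refractive indices (dimensionless)
N_CELL_DEFAULT = 1.380
N_MEDIUM_DEFAULT = 1.334

#: default lateral sampling, chosen so 3 px = 1.86 um
PIXEL_SIZE_UM = 0.62

#: additive OPD read noise, nm (holographic phase noise is nm-scale)
NOISE_SD_NM = 3.0

#: residual background-flattening OPD offset, nm. Dominated by well
#: geometry (meniscus, plate bottom), so it is drawn once per well in
#: endpoint runs and does not average out over that well's fields: an
#: absolute (signal-independent) noise floor that penalizes low-contrast
#: specimens
BACKGROUND_OFFSET_SD_NM = 3.0


@dataclass
class CellOpticalModel:
    """Optical model of a field: thickness map plus refractive indices.

    ``thickness_map`` is in micrometres; OPD in nanometres follows
    ``opd = d · (n_c − n_m) · 1000``.
    """

    thickness_map: np.ndarray  # um
    n_c: float = N_CELL_DEFAULT
    n_m: float = N_MEDIUM_DEFAULT

    def __post_init__(self) -> None:
        self.thickness_map = np.asarray(self.thickness_map, dtype=np.float64)
        if np.any(self.thickness_map < 0):
            raise ValueError("thickness must be non-negative everywhere")
        if self.n_c <= self.n_m:
            raise ValueError("n_c must exceed n_m for positive OPD contrast")

    def opd_nm(self) -> np.ndarray:
        """Pixel-wise OPD in nanometres."""
        return self.thickness_map * (self.n_c - self.n_m) * 1.0e3


@dataclass(frozen=True)
class PhenotypeSpec:
    """Geometry of one phenotype class.

    ``contrast_scale`` multiplies all thicknesses and models the
    cell-type contrast regime (flat cell lines have ~half the signal).
    """

    class_name: str
    semi_major_um: float
    semi_minor_um: float
    peak_thickness_um: float
    vesicle_count: int = 0
    vesicle_radius_um: float = 1.5
    vesicle_thickness_um: float = 2.5
    contrast_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.semi_major_um < self.semi_minor_um:
            raise ValueError("semi_major must be >= semi_minor")
        if self.peak_thickness_um <= 0 or self.contrast_scale <= 0:
            raise ValueError("thickness and contrast_scale must be positive")

    @property
    def footprint_area_um2(self) -> float:
        return float(np.pi * self.semi_major_um * self.semi_minor_um)


# Class geometries. The elongated control, the rounded high-OPD treated
# cell and the small-footprint vesicle-bearing cell are free parameters
# of the generator; values are set to typical adherent-cell scales
# (peak OPD ~80 nm control, ~180 nm rounded at dn = 0.046).
PHENOTYPES: dict[str, PhenotypeSpec] = {
    "control": PhenotypeSpec("control", 13.0, 5.0, 1.8),
    "round": PhenotypeSpec("round", 7.0, 7.0, 4.0),
    "vesicle": PhenotypeSpec(
        "vesicle", 8.0, 6.0, 1.2, vesicle_count=4,
        vesicle_radius_um=1.5, vesicle_thickness_um=2.5,
    ),
}

#: OPD contrast per cell type; the flat line carries half the signal
CELL_TYPE_CONTRAST: dict[str, float] = {"hela": 1.0, "h9c2": 0.5}

#: which phenotype each reference compound drives
COMPOUND_PHENOTYPE: dict[str, str] = {
    "doxorubicin": "round",
    "chloroquine": "vesicle",
}


def spec_for(class_name: str, cell_type: str = "hela") -> PhenotypeSpec:
    """Phenotype spec for a class in a given cell-type contrast regime."""
    try:
        base = PHENOTYPES[class_name]
    except KeyError:
        raise KeyError(
            f"unknown phenotype {class_name!r}; known: {sorted(PHENOTYPES)}"
        ) from None
    try:
        scale = CELL_TYPE_CONTRAST[cell_type]
    except KeyError:
        raise KeyError(
            f"unknown cell type {cell_type!r}; known: {sorted(CELL_TYPE_CONTRAST)}"
        ) from None
    return replace(base, contrast_scale=base.contrast_scale * scale)


@dataclass(frozen=True)
class PlacedCell:
    """A phenotype instance placed in a field (pixel coordinates)."""

    spec: PhenotypeSpec
    row: float
    col: float
    orientation_rad: float = 0.0
    size_jitter: float = 1.0
    thickness_jitter: float = 1.0
    vesicle_offsets_um: tuple[tuple[float, float], ...] = ()


def _sample_vesicle_offsets(
    spec: PhenotypeSpec, rng: np.random.Generator
) -> tuple[tuple[float, float], ...]:
    """Puncta centres in the cell frame, kept inside ~70% of the soma."""
    offsets = []
    for _ in range(spec.vesicle_count):
        while True:
            u = rng.uniform(-0.7, 0.7, size=2)
            if u[0] ** 2 + u[1] ** 2 <= 0.49:
                break
        offsets.append((u[0] * spec.semi_minor_um, u[1] * spec.semi_major_um))
    return tuple(offsets)


def place_cells(
    classes: Sequence[str],
    *,
    cell_type: str = "hela",
    field_size: tuple[int, int] = (256, 256),
    pixel_size_um: float = PIXEL_SIZE_UM,
    rng: np.random.Generator | int | None = None,
    min_separation_um: float | None = None,
    size_jitter_sd: float = 0.08,
    max_attempts: int = 200,
) -> list[PlacedCell]:
    """Place one cell per class label by Poisson-disc (dart-throwing) sampling.

    Cells are kept a margin away from the field border (so segmentation
    border rules never fire on ground-truth objects) and at least
    ``min_separation_um`` apart centre-to-centre (default: sum of the two
    cells' semi-minor axes, which keeps footprints disjoint). Cells that
    cannot be placed after ``max_attempts`` darts are dropped.
    """
    rng = np.random.default_rng(rng)
    nrow, ncol = field_size
    placed: list[PlacedCell] = []
    for cname in classes:
        spec = spec_for(cname, cell_type)
        jitter = float(np.exp(rng.normal(0.0, size_jitter_sd)))
        margin_px = spec.semi_major_um * jitter / pixel_size_um + 2.0
        if 2 * margin_px >= min(nrow, ncol):
            raise ValueError("field too small for this cell size")
        for _ in range(max_attempts):
            r = rng.uniform(margin_px, nrow - margin_px)
            c = rng.uniform(margin_px, ncol - margin_px)
            ok = True
            for other in placed:
                sep_um = (
                    min_separation_um
                    if min_separation_um is not None
                    else (spec.semi_minor_um * jitter + other.spec.semi_minor_um * other.size_jitter)
                )
                d_px = np.hypot(r - other.row, c - other.col)
                if d_px * pixel_size_um < sep_um:
                    ok = False
                    break
            if ok:
                placed.append(
                    PlacedCell(
                        spec=spec,
                        row=r,
                        col=c,
                        orientation_rad=float(rng.uniform(0, np.pi)),
                        size_jitter=jitter,
                        thickness_jitter=float(np.exp(rng.normal(0.0, size_jitter_sd))),
                        vesicle_offsets_um=_sample_vesicle_offsets(spec, rng),
                    )
                )
                break
    return placed


def _cap(rho2: np.ndarray) -> np.ndarray:
    """Squared-cosine cap profile on the normalized elliptical radius."""
    rho = np.sqrt(np.clip(rho2, 0.0, 1.0))
    out = np.cos(0.5 * np.pi * rho) ** 2
    out[rho2 >= 1.0] = 0.0
    return out


def _cell_thickness(
    cell: PlacedCell, shape: tuple[int, int], pixel_size_um: float
) -> tuple[slice, slice, np.ndarray]:
    """Thickness contribution (um) of one cell on its bounding box."""
    spec = cell.spec
    a = spec.semi_major_um * cell.size_jitter / pixel_size_um
    b = spec.semi_minor_um * cell.size_jitter / pixel_size_um
    rad = a + spec.vesicle_radius_um / pixel_size_um + 1.0
    r0 = max(int(np.floor(cell.row - rad)), 0)
    r1 = min(int(np.ceil(cell.row + rad)) + 1, shape[0])
    c0 = max(int(np.floor(cell.col - rad)), 0)
    c1 = min(int(np.ceil(cell.col + rad)) + 1, shape[1])
    rr, cc = np.mgrid[r0:r1, c0:c1].astype(np.float64)
    dr = rr - cell.row
    dc = cc - cell.col
    ct, st = np.cos(cell.orientation_rad), np.sin(cell.orientation_rad)
    # rotate into the cell frame: x along semi-major, y along semi-minor
    x = dr * ct + dc * st
    y = -dr * st + dc * ct
    rho2 = (x / a) ** 2 + (y / b) ** 2
    peak = spec.peak_thickness_um * spec.contrast_scale * cell.thickness_jitter
    d = peak * _cap(rho2)
    # vesicles: added OPD puncta riding on the soma
    rv = spec.vesicle_radius_um / pixel_size_um
    for oy, ox in cell.vesicle_offsets_um:
        # offsets are (minor, major) in um in the cell frame
        vr = cell.row + (ox / pixel_size_um) * ct - (oy / pixel_size_um) * st
        vc = cell.col + (ox / pixel_size_um) * st + (oy / pixel_size_um) * ct
        rho2_v = ((rr - vr) ** 2 + (cc - vc) ** 2) / rv**2
        d += spec.vesicle_thickness_um * spec.contrast_scale * _cap(rho2_v)
    return slice(r0, r1), slice(c0, c1), d


def _check_overlap(cells: Sequence[PlacedCell], pixel_size_um: float) -> None:
    for i, a in enumerate(cells):
        for b in cells[i + 1 :]:
            d_um = np.hypot(a.row - b.row, a.col - b.col) * pixel_size_um
            tol = 0.5 * (
                a.spec.semi_minor_um * a.size_jitter
                + b.spec.semi_minor_um * b.size_jitter
            )
            if d_um < tol:
                raise ValueError(
                    f"cells at ({a.row:.0f},{a.col:.0f}) and "
                    f"({b.row:.0f},{b.col:.0f}) overlap beyond tolerance"
                )


def render_field_with_truth(
    cells: Sequence[PlacedCell],
    *,
    pixel_size_um: float = PIXEL_SIZE_UM,
    field_size: tuple[int, int] = (256, 256),
    noise_sd_nm: float = NOISE_SD_NM,
    seed: np.random.Generator | int | None = None,
    n_c: float = N_CELL_DEFAULT,
    n_m: float = N_MEDIUM_DEFAULT,
    non_overlap: bool = False,
    background_offset_nm: float = 0.0,
) -> tuple[PhaseImage, pd.DataFrame]:
    """Render placed cells into an OPD map plus a ground-truth table.

    The noise-free OPD obeys ``opd = d · (n_c − n_m)`` pixel-wise; Gaussian
    background noise of ``noise_sd_nm`` is added on top. Deterministic for
    a fixed seed. The truth table has one row per cell: class, centroid,
    and integrated OPD (nm·px) of that cell's own contribution.
    """
    if noise_sd_nm < 0:
        raise ValueError("noise_sd_nm must be >= 0")
    nrow, ncol = field_size
    for cell in cells:
        if not (0 <= cell.row < nrow and 0 <= cell.col < ncol):
            raise ValueError("cell position outside the field")
    if non_overlap:
        _check_overlap(cells, pixel_size_um)
    rng = np.random.default_rng(seed)
    thickness = np.zeros(field_size, dtype=np.float64)
    rows = []
    for cell in cells:
        sl_r, sl_c, d = _cell_thickness(cell, field_size, pixel_size_um)
        thickness[sl_r, sl_c] += d
        rows.append(
            {
                "class": cell.spec.class_name,
                "centroid_row": cell.row,
                "centroid_col": cell.col,
                "integrated_opd_nm_px": float(d.sum() * (n_c - n_m) * 1.0e3),
            }
        )
    model = CellOpticalModel(thickness, n_c=n_c, n_m=n_m)
    opd = model.opd_nm()
    if noise_sd_nm > 0:
        opd = opd + rng.normal(0.0, noise_sd_nm, size=opd.shape)
    if background_offset_nm:
        opd = opd + background_offset_nm
    truth = pd.DataFrame(
        rows,
        columns=["class", "centroid_row", "centroid_col", "integrated_opd_nm_px"],
    )
    return PhaseImage(opd, pixel_size_um), truth


def render_field(
    cells: Sequence[PlacedCell],
    *,
    pixel_size_um: float = PIXEL_SIZE_UM,
    field_size: tuple[int, int] = (256, 256),
    noise_sd_nm: float = NOISE_SD_NM,
    seed: np.random.Generator | int | None = None,
    n_c: float = N_CELL_DEFAULT,
    n_m: float = N_MEDIUM_DEFAULT,
    non_overlap: bool = False,
) -> PhaseImage:
    """Render placed cells into a noisy OPD map (see render_field_with_truth)."""
    phase, _ = render_field_with_truth(
        cells,
        pixel_size_um=pixel_size_um,
        field_size=field_size,
        noise_sd_nm=noise_sd_nm,
        seed=seed,
        n_c=n_c,
        n_m=n_m,
        non_overlap=non_overlap,
    )
    return phase


# --------------------------------------------------------------------------
# plate-level simulation


@dataclass(frozen=True)
class WellSpec:
    well_id: str
    cell_type: str
    compound: str
    concentration_um: float
    replicate: int

    @property
    def condition(self) -> str:
        return f"{self.cell_type}:{self.compound}"


@dataclass
class PlateDesign:
    """Layout of a (synthetic) screening plate.

    One integer ``seed`` determines every random draw in the simulation.
    """

    wells: list[WellSpec]
    fields_per_well: int = 4
    field_size: tuple[int, int] = (256, 256)
    pixel_size_um: float = PIXEL_SIZE_UM
    seed: int = 0
    confluency_range: tuple[float, float] = (0.25, 0.60)
    noise_sd_nm: float = NOISE_SD_NM
    background_offset_sd_nm: float = BACKGROUND_OFFSET_SD_NM

    def __post_init__(self) -> None:
        ids = [w.well_id for w in self.wells]
        if len(ids) != len(set(ids)):
            raise ValueError("well ids must be unique")
        lo, hi = self.confluency_range
        if not (0 < lo <= hi < 1):
            raise ValueError("confluency_range must satisfy 0 < lo <= hi < 1")


@dataclass(frozen=True)
class DoseModel:
    """Four-parameter logistic dose-response model.

    ``response(c) = bottom + (top − bottom) / (1 + (ec50/c)^hill)``,
    monotone in concentration; at c = 0 the response is ``bottom``.
    """

    bottom: float
    top: float
    ec50_um: float
    hill: float

    def __post_init__(self) -> None:
        if self.ec50_um <= 0:
            raise ValueError("ec50 must be positive")
        if self.top == self.bottom:
            raise ValueError("top must differ from bottom")
        if self.hill <= 0:
            raise ValueError("hill must be positive for a monotone response")

    def response(self, conc_um: float | np.ndarray) -> float | np.ndarray:
        c = np.asarray(conc_um, dtype=np.float64)
        with np.errstate(divide="ignore"):
            r = self.bottom + (self.top - self.bottom) / (
                1.0 + (self.ec50_um / c) ** self.hill
            )
        r = np.where(c <= 0, self.bottom, r)
        return float(r) if np.isscalar(conc_um) else r


@dataclass(frozen=True)
class DoseEffect:
    """A dose-dependent phenotype with its kinetics for time-lapse runs."""

    model: DoseModel
    phenotype: str
    onset_h: float = 4.0
    ramp_h: float = 2.0


@dataclass
class FieldRender:
    """One simulated field: image plus per-cell ground truth."""

    well: WellSpec
    field_index: int
    t_h: float
    phase: PhaseImage
    truth: pd.DataFrame


def _lookup_model(models: Mapping[str, object], well: WellSpec) -> object:
    for key in (well.condition, well.compound):
        if key in models:
            return models[key]
    raise KeyError(
        f"no dose model for condition {well.condition!r} "
        f"(known: {sorted(models)})"
    )


def _n_cells_for_confluency(
    confluency: float, design: PlateDesign, spec: PhenotypeSpec
) -> int:
    field_area_um2 = (
        design.field_size[0] * design.field_size[1] * design.pixel_size_um**2
    )
    return max(1, int(round(confluency * field_area_um2 / spec.footprint_area_um2)))


def simulate_plate(
    design: PlateDesign,
    dose_models: Mapping[str, DoseModel],
    *,
    compound_phenotype: Mapping[str, str] | None = None,
) -> Iterator[FieldRender]:
    """Simulate an endpoint plate, yielding one FieldRender per field.

    The fraction of cells expressing the treated phenotype in a well is
    the well's dose model evaluated at its concentration; confluency is
    drawn uniformly within the design's range. All randomness derives
    from ``design.seed``.
    """
    phen_map = dict(COMPOUND_PHENOTYPE)
    if compound_phenotype:
        phen_map.update(compound_phenotype)
    for w_idx, well in enumerate(design.wells):
        model = _lookup_model(dose_models, well)
        if well.compound not in phen_map:
            raise KeyError(
                f"no phenotype mapping for compound {well.compound!r} "
                f"(known: {sorted(phen_map)})"
            )
        phenotype = phen_map[well.compound]
        frac = float(np.clip(model.response(well.concentration_um), 0.0, 1.0))
        well_rng = np.random.default_rng([design.seed, w_idx])
        confluency = well_rng.uniform(*design.confluency_range)
        # flattening residual is a well-level artifact: one draw per well
        offset = well_rng.normal(0.0, design.background_offset_sd_nm)
        for f_idx in range(design.fields_per_well):
            field_rng = np.random.default_rng([design.seed, w_idx, f_idx])
            n_cells = _n_cells_for_confluency(
                confluency, design, spec_for("control", well.cell_type)
            )
            classes = np.where(
                field_rng.random(n_cells) < frac, phenotype, "control"
            ).tolist()
            cells = place_cells(
                classes,
                cell_type=well.cell_type,
                field_size=design.field_size,
                pixel_size_um=design.pixel_size_um,
                rng=field_rng,
            )
            phase, truth = render_field_with_truth(
                cells,
                pixel_size_um=design.pixel_size_um,
                field_size=design.field_size,
                noise_sd_nm=design.noise_sd_nm,
                seed=field_rng,
                background_offset_nm=offset,
            )
            truth.insert(0, "well", well.well_id)
            truth.insert(1, "field", f_idx)
            phase.meta.update(
                well=well.well_id, field=f_idx, condition=well.condition,
                concentration_um=well.concentration_um,
            )
            yield FieldRender(well, f_idx, 0.0, phase, truth)


def simulate_timelapse(
    design: PlateDesign,
    dose_effects: Mapping[str, Sequence[DoseEffect] | DoseEffect],
    *,
    interval_min: float = 10.0,
    duration_h: float = 24.0,
) -> Iterator[FieldRender]:
    """Simulate a time-lapse plate: every field imaged every ``interval_min``.

    Phenotype expression ramps up from baseline starting at each effect's
    ``onset_h``: a cell destined to express transitions at a time drawn
    uniformly in ``[onset, onset + ramp]``. The default 10-min / 24-h
    protocol yields 145 time points per field including t = 0. Effects
    listed first take precedence when a cell qualifies for several.
    """
    n_steps = duration_h * 60.0 / interval_min
    if abs(n_steps - round(n_steps)) > 1e-9:
        raise ValueError("interval must divide the total duration")
    times_h = np.arange(round(n_steps) + 1) * interval_min / 60.0
    for w_idx, well in enumerate(design.wells):
        effects = _lookup_model(dose_effects, well)
        if isinstance(effects, DoseEffect):
            effects = [effects]
        for eff in effects:
            if eff.onset_h > duration_h:
                warnings.warn(
                    f"onset {eff.onset_h} h beyond duration {duration_h} h: "
                    f"series for well {well.well_id} stays at baseline",
                    stacklevel=2,
                )
        well_rng = np.random.default_rng([design.seed, w_idx])
        confluency = well_rng.uniform(*design.confluency_range)
        for f_idx in range(design.fields_per_well):
            field_rng = np.random.default_rng([design.seed, w_idx, f_idx, 10_000])
            n_cells = _n_cells_for_confluency(
                confluency, design, spec_for("control", well.cell_type)
            )
            # per-cell fate: first effect whose Bernoulli draw fires wins
            fates = ["control"] * n_cells
            t_switch = np.full(n_cells, np.inf)
            for eff in effects:
                frac = float(
                    np.clip(eff.model.response(well.concentration_um), 0.0, 1.0)
                )
                hit = field_rng.random(n_cells) < frac
                t_eff = field_rng.uniform(
                    eff.onset_h, eff.onset_h + eff.ramp_h, size=n_cells
                )
                for i in range(n_cells):
                    if hit[i] and fates[i] == "control":
                        fates[i] = eff.phenotype
                        t_switch[i] = t_eff[i]
            base_cells = place_cells(
                ["control"] * n_cells,
                cell_type=well.cell_type,
                field_size=design.field_size,
                pixel_size_um=design.pixel_size_um,
                rng=field_rng,
            )
            # pre-build the expressed variant of each cell at the same site
            expressed = []
            ves_rng = np.random.default_rng([design.seed, w_idx, f_idx, 20_000])
            for i, cell in enumerate(base_cells):
                if fates[i] == "control":
                    expressed.append(cell)
                else:
                    spec = spec_for(fates[i], well.cell_type)
                    expressed.append(
                        replace(
                            cell,
                            spec=spec,
                            vesicle_offsets_um=_sample_vesicle_offsets(spec, ves_rng),
                        )
                    )
            offset_rng = np.random.default_rng([design.seed, w_idx, f_idx, 30_000])
            for t_idx, t in enumerate(times_h):
                frame_cells = [
                    expressed[i] if t >= t_switch[i] else base_cells[i]
                    for i in range(len(base_cells))
                ]
                noise_rng = np.random.default_rng(
                    [design.seed, w_idx, f_idx, 40_000 + t_idx]
                )
                offset = offset_rng.normal(0.0, design.background_offset_sd_nm)
                phase, truth = render_field_with_truth(
                    frame_cells,
                    pixel_size_um=design.pixel_size_um,
                    field_size=design.field_size,
                    noise_sd_nm=design.noise_sd_nm,
                    seed=noise_rng,
                    background_offset_nm=offset,
                )
                truth.insert(0, "well", well.well_id)
                truth.insert(1, "field", f_idx)
                phase.meta.update(
                    well=well.well_id, field=f_idx, t_h=float(t),
                    condition=well.condition,
                    concentration_um=well.concentration_um,
                )
                yield FieldRender(well, f_idx, float(t), phase, truth)


# --------------------------------------------------------------------------
# design helpers


def _well_ids(n: int) -> list[str]:
    out = []
    for i in range(n):
        out.append(f"{chr(ord('A') + i // 12)}{i % 12 + 1:02d}")
    return out


def endpoint_design(
    *,
    cell_types: Sequence[str] = ("hela",),
    compounds: Sequence[str] = ("doxorubicin",),
    concentration_um: float = 30.0,
    n_replicates: int = 12,
    include_vehicle: bool = True,
    fields_per_well: int = 4,
    field_size: tuple[int, int] = (256, 256),
    pixel_size_um: float = PIXEL_SIZE_UM,
    seed: int = 0,
) -> PlateDesign:
    """Endpoint screen: treated wells at one dose plus vehicle controls."""
    wells: list[WellSpec] = []
    concs = [concentration_um] + ([0.0] if include_vehicle else [])
    n_total = len(cell_types) * len(compounds) * len(concs) * n_replicates
    ids = iter(_well_ids(n_total))
    for ct in cell_types:
        for cmpd in compounds:
            for conc in concs:
                for rep in range(n_replicates):
                    wells.append(WellSpec(next(ids), ct, cmpd, conc, rep))
    return PlateDesign(
        wells,
        fields_per_well=fields_per_well,
        field_size=field_size,
        pixel_size_um=pixel_size_um,
        seed=seed,
    )


def dose_design(
    *,
    cell_type: str = "hela",
    compound: str = "doxorubicin",
    top_concentration_um: float = 300.0,
    n_doses: int = 7,
    dilution: float = 3.0,
    wells_per_dose: int = 1,
    include_vehicle: bool = True,
    fields_per_well: int = 1,
    field_size: tuple[int, int] = (128, 128),
    pixel_size_um: float = PIXEL_SIZE_UM,
    seed: int = 0,
) -> PlateDesign:
    """Serial-dilution design for dose-response runs (vehicle at c = 0)."""
    concs = [top_concentration_um / dilution**i for i in range(n_doses)]
    if include_vehicle:
        concs.append(0.0)
    wells: list[WellSpec] = []
    ids = iter(_well_ids(len(concs) * wells_per_dose))
    for conc in concs:
        for rep in range(wells_per_dose):
            wells.append(WellSpec(next(ids), cell_type, compound, conc, rep))
    return PlateDesign(
        wells,
        fields_per_well=fields_per_well,
        field_size=field_size,
        pixel_size_um=pixel_size_um,
        seed=seed,
    )
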