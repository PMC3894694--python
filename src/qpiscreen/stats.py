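"""Screening statistics: well aggregation, Z'-factor, AUC, 4PL fits, onset.

The assay-quality statistic is the Z'-factor,

    Z' = 1 − 3(σ_pos + σ_neg) / |μ_pos − μ_neg| ,

computed from well-level means (sample SD, n−1) of the treated and
control groups; values near 1 indicate an excellent screening window and
values below 0.5 a marginal assay.

Dose-response curves are the four-parameter logistic (variable slope)

    y(c) = bottom + (top − bottom) / (1 + 10^((log10 EC50 − log10 c)·hill)),

fitted by least squares in log10-dose space with multi-start to dodge
local minima; the vehicle (no-drug) response is placed two logs below the
lowest tested concentration, the screening convention for plotting a
zero dose on a log axis.

Time-lapse readouts are condensed to the area under the curve (raw
trapezoid, optional baseline subtraction), and the response onset is the
first time at which the readout deviates from its baseline by more than
``k_sd`` baseline SDs for ``m`` consecutive points.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .synth import PlateDesign

__all__ = [
    "ZPrimeResult",
    "DoseResponseFit",
    "aggregate_wells",
    "z_prime",
    "timelapse_auc",
    "fit_dose_response",
    "detect_onset",
]


@dataclass(frozen=True)
class ZPrimeResult:
    """Z'-factor with the group statistics behind it; ``valid`` is False
    when the means coincide and the statistic is undefined."""

    mu_pos: float
    sd_pos: float
    mu_neg: float
    sd_neg: float
    z_prime: float
    valid: bool = True


def z_prime(pos: np.ndarray, neg: np.ndarray) -> ZPrimeResult:
    """Z'-factor from well-level readouts of treated and control groups."""
    pos = np.asarray(pos, dtype=np.float64)
    neg = np.asarray(neg, dtype=np.float64)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least two wells per group")
    mu_p, mu_n = float(pos.mean()), float(neg.mean())
    sd_p = float(pos.std(ddof=1))
    sd_n = float(neg.std(ddof=1))
    if mu_p == mu_n:
        return ZPrimeResult(mu_p, sd_p, mu_n, sd_n, float("nan"), valid=False)
    z = 1.0 - 3.0 * (sd_p + sd_n) / abs(mu_p - mu_n)
    return ZPrimeResult(mu_p, sd_p, mu_n, sd_n, z, valid=True)


def aggregate_wells(
    field_metrics: pd.DataFrame,
    design: PlateDesign,
    value_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Average per-field metrics into one mean value per well.

    ``field_metrics`` must carry a ``well`` column; every field must map
    to a well of the design. Returns one row per well with the well
    metadata (condition, concentration) and the mean of each value column.
    """
    if "well" not in field_metrics.columns:
        raise ValueError("field metrics need a 'well' column")
    known = {w.well_id: w for w in design.wells}
    orphans = sorted(set(field_metrics["well"]) - set(known))
    if orphans:
        raise ValueError(f"fields reference unknown wells: {orphans}")
    if value_columns is None:
        value_columns = [
            c
            for c in field_metrics.columns
            if c not in ("well", "field", "t_h")
            and np.issubdtype(field_metrics[c].dtype, np.number)
        ]
    grouped = field_metrics.groupby("well")[value_columns].mean().reset_index()
    grouped["cell_type"] = [known[w].cell_type for w in grouped["well"]]
    grouped["compound"] = [known[w].compound for w in grouped["well"]]
    grouped["concentration_um"] = [
        known[w].concentration_um for w in grouped["well"]
    ]
    grouped["condition"] = [known[w].condition for w in grouped["well"]]
    grouped["n_fields"] = field_metrics.groupby("well").size().reindex(
        grouped["well"]
    ).to_numpy()
    return grouped


def timelapse_auc(
    times_h: np.ndarray,
    values: np.ndarray,
    *,
    baseline_subtract: bool = False,
) -> float:
    """Trapezoidal area under a time series (value·hours).

    With ``baseline_subtract`` the value at t = 0 (the first point) is
    removed before integration, so a flat series integrates to zero.
    """
    t = np.asarray(times_h, dtype=np.float64)
    v = np.asarray(values, dtype=np.float64)
    if t.size != v.size:
        raise ValueError("times and values must align")
    if t.size < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if baseline_subtract:
        v = v - v[0]
    return float(np.trapezoid(v, t))


@dataclass(frozen=True)
class DoseResponseFit:
    """4PL fit result; ``converged`` is False for flat or failed fits."""

    bottom: float
    top: float
    ec50_um: float
    hill: float
    rss: float
    converged: bool

    def predict(self, conc_um: np.ndarray) -> np.ndarray:
        c = np.asarray(conc_um, dtype=np.float64)
        return _four_pl(
            np.log10(c),
            self.bottom,
            self.top,
            np.log10(self.ec50_um),
            self.hill,
        )

    def summary(self) -> str:
        lines = [
            "4PL dose-response fit",
            "---------------------",
            f"bottom   {self.bottom: .6g}",
            f"top      {self.top: .6g}",
            f"EC50     {self.ec50_um: .6g} uM",
            f"hill     {self.hill: .6g}",
            f"RSS      {self.rss: .6g}",
            f"converged {self.converged}",
        ]
        return "\n".join(lines)


def _four_pl(log_c, bottom, top, log_ec50, hill):
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((log_ec50 - log_c) * hill))


def fit_dose_response(
    doses_um: np.ndarray,
    responses: np.ndarray,
    vehicle_response: float | None = None,
    *,
    n_starts: int = 5,
    seed: int = 0,
) -> DoseResponseFit:
    """Least-squares 4PL fit in log10-dose space with multi-start.

    ``vehicle_response`` (the no-drug control) is placed two logs below
    the lowest tested concentration. Hill is bounded to [−10, 10] and
    EC50 to the dose range ± 2 logs. A response range indistinguishable
    from flat is reported as non-convergent with no EC50.
    """
    d = np.asarray(doses_um, dtype=np.float64)
    r = np.asarray(responses, dtype=np.float64)
    if d.size != r.size:
        raise ValueError("doses and responses must align")
    if np.any(d <= 0):
        raise ValueError("doses must be positive (vehicle goes in vehicle_response)")
    log_c = np.log10(d)
    if vehicle_response is not None:
        log_c = np.append(log_c, log_c.min() - 2.0)
        r = np.append(r, vehicle_response)
    span = float(r.max() - r.min())
    scale = max(abs(r).max(), 1.0)
    if span < 1e-9 * scale:
        return DoseResponseFit(
            bottom=float(r.mean()), top=float(r.mean()),
            ec50_um=float("nan"), hill=float("nan"),
            rss=float(((r - r.mean()) ** 2).sum()), converged=False,
        )
    lo, hi = log_c.min(), log_c.max()
    bounds_lo = [r.min() - span, r.min() - span, lo - 2.0, -10.0]
    bounds_hi = [r.max() + span, r.max() + span, hi + 2.0, 10.0]
    rng = np.random.default_rng(seed)
    best = None
    starts = [(float(r.min()), float(r.max()), 0.5 * (lo + hi), 1.0)]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(
            (
                float(r.min() + span * rng.uniform(-0.2, 0.2)),
                float(r.max() + span * rng.uniform(-0.2, 0.2)),
                float(rng.uniform(lo - 1.0, hi + 1.0)),
                float(rng.choice([-2.0, -0.5, 0.5, 1.0, 2.0])),
            )
        )
    for x0 in starts:
        x0 = np.clip(x0, bounds_lo, bounds_hi)
        try:
            sol = least_squares(
                lambda p: _four_pl(log_c, *p) - r,
                x0=x0,
                bounds=(bounds_lo, bounds_hi),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
            )
        except Exception:
            continue
        rss = float((sol.fun**2).sum())
        if best is None or rss < best[0]:
            best = (rss, sol.x, sol.success)
    if best is None:
        return DoseResponseFit(
            float("nan"), float("nan"), float("nan"), float("nan"),
            float("inf"), False,
        )
    rss, x, ok = best
    bottom, top, log_ec50, hill = (float(v) for v in x)
    # the 4PL is invariant under (bottom, top, hill) -> (top, bottom, -hill);
    # report the canonical orientation with a positive slope
    if hill < 0:
        bottom, top, hill = top, bottom, -hill
    # a fit that flattened out carries no dose information
    if abs(top - bottom) < 1e-6 * scale:
        return DoseResponseFit(bottom, top, float("nan"), hill, rss, False)
    return DoseResponseFit(bottom, top, 10.0**log_ec50, hill, rss, bool(ok))


def detect_onset(
    times_h: np.ndarray,
    values: np.ndarray,
    baseline_window_h: float,
    k_sd: float = 3.0,
    m_consecutive: int = 3,
    *,
    direction: str = "increase",
    abs_tol: float = 1e-9,
) -> float | None:
    """First time the readout deviates significantly from its baseline.

    The baseline is all points with t <= ``baseline_window_h``; onset is
    the first time from which ``m_consecutive`` successive points exceed
    baseline mean + ``k_sd``·SD (or fall below, for decreasing readouts).
    With a zero-variance baseline the absolute tolerance ``abs_tol``
    stands in for the SD band. Returns None for a flat series.
    """
    t = np.asarray(times_h, dtype=np.float64)
    v = np.asarray(values, dtype=np.float64)
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    if direction not in ("increase", "decrease"):
        raise ValueError("direction must be 'increase' or 'decrease'")
    base = v[t <= baseline_window_h]
    if base.size < 2:
        raise ValueError("baseline window must contain at least two points")
    mu = float(base.mean())
    sd = float(base.std(ddof=1))
    band = k_sd * sd if sd > 0 else abs_tol
    if direction == "increase":
        exceeds = v > mu + band
    else:
        exceeds = v < mu - band
    candidate = t > baseline_window_h
    idx = np.nonzero(candidate)[0]
    run = 0
    for i in idx:
        if exceeds[i]:
            run += 1
            if run >= m_consecutive:
                return float(t[i - m_consecutive + 1])
        else:
            run = 0
    return None
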