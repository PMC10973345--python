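"""Gestational eGFR from physiological serum-creatinine hyperfiltration.

Pregnancy raises GFR and therefore lowers serum creatinine (SCr) below the
pre-implantation baseline (BSC, the GW 0-3 median). The chain of
quantities:

    hyperfiltration gap            BSC - SCr
    simple gap ratio               (BSC - SCr) / BSC
    overall hyperfiltration ratio  2 - SCr / BSC
    simple eGFR                    overall ratio x normal GFR
    k_gw                           BSC / median_curve(GW)
    gestational eGFR               (2 - SCr/BSC) x normal GFR x k_gw

with the canonical parameter set BSC = 55.25 umol/L, normal GFR = 103.1
mL/min (110.1 mL/min/1.73 m2 de-indexed by BSA 1.62 m2) and the degree-4
median-SCr polynomial. The eGFR is reported as an absolute flow (mL/min,
not BSA-indexed) because body fluid, not surface area, grows in pregnancy.

GW 0-3 is the pre-implantation period, assumed free of hemodynamic change:
``k_gw`` and the formula are undefined there and raise
:class:`PreImplantationError`.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
import yaml

from .curves import DegreeSearchConfig, PolynomialCurve, smooth_limits
from .reference_interval import (
    BinningConfig,
    GaussianCriteria,
    GestationalPeriod,
    ResampleConfig,
    ResampleSet,
    bin_into_periods,
    build_period_ri,
)

__all__ = [
    "EgfrParameters",
    "RiTableRow",
    "EgfrRiResult",
    "PreImplantationError",
    "NonPhysiologicWarning",
    "MG_DL_TO_UMOL_L",
    "load_canonical_parameters",
    "hyperfiltration_gap",
    "simple_hyperfiltration_gap_ratio",
    "overall_hyperfiltration_ratio",
    "k_gw",
    "gestational_egfr",
    "derive_normal_gfr",
    "mg_dl_to_umol_l",
    "umol_l_to_mg_dl",
    "build_egfr_ri",
    "make_ri_table",
    "analytic_median_table",
    "ri_table_to_frame",
]

#: Creatinine molar-mass conversion: 1 mg/dL = 88.42 umol/L.
MG_DL_TO_UMOL_L = 88.42


class PreImplantationError(ValueError):
    """Raised for GW 0-3, where no hemodynamic change is assumed."""


class NonPhysiologicWarning(UserWarning):
    """SCr at or above twice baseline: the formula yields eGFR <= 0."""


@dataclass(frozen=True)
class EgfrParameters:
    """Constants of the gestational eGFR formula."""

    bsc: float
    normal_gfr: float
    median_curve: PolynomialCurve

    def __post_init__(self) -> None:
        if self.bsc <= 0 or self.normal_gfr <= 0:
            raise ValueError("bsc and normal_gfr must be positive")
        gws = np.arange(self.median_curve.domain[0], self.median_curve.domain[1] + 1)
        if np.any(self.median_curve(gws) <= 0):
            raise ValueError("median curve must be positive on its domain")


def load_canonical_parameters() -> EgfrParameters:
    """The canonical parameter set shipped with the package."""
    ref = importlib.resources.files("gestri.data") / "canonical_params.yaml"
    raw = yaml.safe_load(ref.read_text())
    return EgfrParameters(
        bsc=float(raw["bsc"]),
        normal_gfr=float(raw["normal_gfr"]),
        median_curve=PolynomialCurve(
            coefficients=tuple(raw["median_curve"]["coefficients"]),
            domain=tuple(raw["median_curve"]["domain"]),
        ),
    )


def _positive(name: str, value) -> None:
    if np.any(np.asarray(value) <= 0):
        raise ValueError(f"{name} must be positive")


def hyperfiltration_gap(bsc: float, scr):
    """BSC - SCr (umol/L); positive means hyperfiltration."""
    _positive("bsc", bsc)
    _positive("scr", scr)
    return bsc - scr


def simple_hyperfiltration_gap_ratio(bsc: float, scr):
    """(BSC - SCr) / BSC, the gap as a fraction of baseline."""
    _positive("bsc", bsc)
    _positive("scr", scr)
    return (bsc - scr) / bsc


def overall_hyperfiltration_ratio(bsc: float, scr):
    """2 - SCr / BSC; equals 1 + the simple gap ratio, 1 when SCr = BSC."""
    _positive("bsc", bsc)
    _positive("scr", scr)
    return 2.0 - scr / bsc


def k_gw(gw, params: EgfrParameters | None = None):
    """GW-specific correction factor BSC / median_curve(GW).

    The factor scales the flat hyperfiltration ratio for the curvilinear
    median-SCr trajectory; it peaks at the mid-pregnancy SCr nadir.
    """
    params = params or load_canonical_parameters()
    gw_arr = np.asarray(gw, dtype=float)
    if np.any((gw_arr >= 0) & (gw_arr <= 3)):
        raise PreImplantationError("GW 0-3 is the pre-implantation baseline; k_gw undefined")
    if not params.median_curve.in_domain(gw_arr):
        raise ValueError(f"gw outside median-curve domain {params.median_curve.domain}")
    out = params.bsc / params.median_curve(gw_arr)
    return float(out) if np.ndim(gw) == 0 else out


def gestational_egfr(scr, gw, params: EgfrParameters | None = None):
    """Gestational eGFR (mL/min): (2 - SCr/BSC) x normal GFR x k_gw.

    Affine and strictly decreasing in SCr at fixed GW; equals
    ``normal_gfr x k_gw`` at SCr = BSC and reaches zero at SCr = 2 BSC
    (values at or beyond that are flagged with
    :class:`NonPhysiologicWarning` rather than silently returned).
    """
    params = params or load_canonical_parameters()
    _positive("scr", scr)
    k = k_gw(gw, params)
    if np.any(np.asarray(scr) >= 2.0 * params.bsc):
        warnings.warn(
            f"SCr >= 2 x baseline ({2 * params.bsc:.2f} umol/L): eGFR <= 0 is non-physiologic",
            NonPhysiologicWarning,
            stacklevel=2,
        )
    out = overall_hyperfiltration_ratio(params.bsc, np.asarray(scr, dtype=float)) \
        * params.normal_gfr * k
    return float(out) if np.ndim(out) == 0 else out


def derive_normal_gfr(gfr_indexed: float, bsa: float, bsa_ref: float = 1.73) -> float:
    """De-index a population GFR (mL/min/1.73 m2) to an absolute flow.

    With the canonical inputs 110.1 mL/min/1.73 m2 and BSA 1.62 m2 this
    gives 103.1 mL/min.
    """
    _positive("gfr_indexed", gfr_indexed)
    _positive("bsa", bsa)
    _positive("bsa_ref", bsa_ref)
    return gfr_indexed * bsa / bsa_ref


def mg_dl_to_umol_l(scr_mg_dl):
    """Convert creatinine from mg/dL to umol/L (factor 88.42)."""
    if np.any(np.asarray(scr_mg_dl) < 0):
        raise ValueError("creatinine cannot be negative")
    out = np.asarray(scr_mg_dl, dtype=float) * MG_DL_TO_UMOL_L
    return float(out) if np.ndim(out) == 0 else out


def umol_l_to_mg_dl(scr_umol_l):
    """Inverse of :func:`mg_dl_to_umol_l`."""
    if np.any(np.asarray(scr_umol_l) < 0):
        raise ValueError("creatinine cannot be negative")
    out = np.asarray(scr_umol_l, dtype=float) / MG_DL_TO_UMOL_L
    return float(out) if np.ndim(out) == 0 else out


@dataclass(frozen=True)
class EgfrRiResult:
    """Week-level eGFR percentile curves plus the period-level diagnostics."""

    curves: dict[float, PolynomialCurve]
    period_sets: list[ResampleSet]
    baseline: float  # pre-implantation eGFR used for the increment column


def build_egfr_ri(measurements: pd.DataFrame, params: EgfrParameters | None = None,
                  binning: BinningConfig | None = None,
                  resample: ResampleConfig | None = None,
                  search: DegreeSearchConfig | None = None,
                  criteria: GaussianCriteria | None = None,
                  percentiles=(2.5, 50.0, 97.5), *, require_accepted: bool = False,
                  rng: np.random.Generator | None = None) -> EgfrRiResult:
    """Transform SCr measurements to eGFR and rebuild the RI pipeline on them.

    Measurements at GW 0-3 are excluded from the transform (the formula is
    undefined there) but their median SCr defines the pre-implantation eGFR
    baseline ``normal_gfr x (2 - median/bsc)`` used for increment columns;
    without any such measurements the baseline falls back to ``normal_gfr``.
    """
    params = params or load_canonical_parameters()
    binning = binning or BinningConfig()
    resample = resample or ResampleConfig()
    search = search or DegreeSearchConfig()
    if rng is None:
        rng = np.random.default_rng(resample.seed)

    pre = measurements[measurements["gw"] <= 3]
    if len(pre):
        baseline = params.normal_gfr * overall_hyperfiltration_ratio(
            params.bsc, float(pre["scr_umol_l"].median()))
    else:
        baseline = params.normal_gfr

    gest = measurements[measurements["gw"] >= 4].copy()
    if len(gest) == 0:
        raise ValueError("no measurements at GW >= 4")
    gest["egfr_ml_min"] = gestational_egfr(
        gest["scr_umol_l"].to_numpy(), gest["gw"].to_numpy(), params)

    periods = bin_into_periods(gest, binning, value_col="egfr_ml_min")
    # only GW >= 4 was binned: clip nominal bounds so empty pre-implantation
    # weeks merged into the first period do not distort its midpoint
    periods = [
        GestationalPeriod(max(gp.gw_lo, 4), gp.gw_hi, gp.values, gp.label)
        if gp.gw_lo < 4 else gp
        for gp in periods
    ]
    sets = [build_period_ri(gp, resample, criteria, rng=rng) for gp in periods]
    curves = smooth_limits(sets, percentiles, search, require_accepted=require_accepted)
    return EgfrRiResult(curves=curves, period_sets=sets, baseline=baseline)


class RiTableRow(NamedTuple):
    """One GW row of the combined SCr / eGFR reference-interval table.

    Values are rounded to 0.1; increment columns are percent change of the
    rounded median against the pre-implantation baseline.
    """

    gw: int
    scr_lower: float
    scr_upper: float
    scr_median: float
    scr_increment_pct: float
    egfr_lower: float
    egfr_upper: float
    egfr_median: float
    egfr_increment_pct: float


def _increment_pct(value: float, baseline: float) -> float:
    return round(100.0 * (value / baseline - 1.0), 1)


def make_ri_table(scr_curves: dict[float, PolynomialCurve],
                  egfr_curves: dict[float, PolynomialCurve],
                  params: EgfrParameters | None = None,
                  egfr_baseline: float | None = None) -> list[RiTableRow]:
    """Tabulate the smoothed curves at integer GW 4-41.

    SCr increments are taken against the baseline SCr (``params.bsc``);
    eGFR increments against ``egfr_baseline`` (default ``normal_gfr``, the
    pre-implantation eGFR when SCr = BSC). Increments are computed from the
    0.1-rounded medians, which is the convention the canonical table uses.
    """
    params = params or load_canonical_parameters()
    if egfr_baseline is None:
        egfr_baseline = params.normal_gfr
    rows = []
    for gw in range(4, 42):
        scr_lo, scr_md, scr_hi = (scr_curves[p](gw) for p in (2.5, 50.0, 97.5))
        eg_lo, eg_md, eg_hi = (egfr_curves[p](gw) for p in (2.5, 50.0, 97.5))
        rows.append(RiTableRow(
            gw=gw,
            scr_lower=round(scr_lo, 1), scr_upper=round(scr_hi, 1),
            scr_median=round(scr_md, 1),
            scr_increment_pct=_increment_pct(round(scr_md, 1), params.bsc),
            egfr_lower=round(eg_lo, 1), egfr_upper=round(eg_hi, 1),
            egfr_median=round(eg_md, 1),
            egfr_increment_pct=_increment_pct(round(eg_md, 1), egfr_baseline),
        ))
    return rows


def analytic_median_table(params: EgfrParameters | None = None) -> pd.DataFrame:
    """Median-SCr column (GW 4-41) straight from the canonical polynomial.

    The formula-only mode: no cohort is needed, only the parameter set.
    """
    params = params or load_canonical_parameters()
    gws = np.arange(4, 42)
    med = np.round(params.median_curve(gws), 1)
    return pd.DataFrame({
        "gw": gws,
        "scr_median": med,
        "scr_increment_pct": [_increment_pct(m, params.bsc) for m in med],
    })


def ri_table_to_frame(rows: list[RiTableRow]) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=RiTableRow._fields)
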