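"""Verification against an external percentile table (Harel et al. cohort).

The pipeline's percentile curves are compared per gestational week with the
directly measured Canadian percentiles reported by Harel et al. (95th, 75th
and 50th). Differences are signed study-minus-reference, rounded to 0.1
umol/L *before* aggregation — that is the arithmetic which reproduces the
canonical comparison table — and summarised by GW, trimester and
percentile. The canonical layout labels the aggregate rows "%", but the
columns are umol/L; this module reports them in umol/L.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .curves import PolynomialCurve

__all__ = [
    "ComparisonTable",
    "trimester_of",
    "compare_to_reference",
    "load_harel_reference",
    "load_canonical_comparison",
    "load_canonical_ri_table",
    "read_reference_table",
    "write_reference_table",
]

PERCENTILES = (95, 75, 50)


def _data_path(name: str):
    return importlib.resources.files("gestri.data") / name


def load_canonical_ri_table() -> pd.DataFrame:
    """The canonical GW-specific SCr / eGFR reference-interval table (GW 4-41)."""
    with importlib.resources.as_file(_data_path("canonical_ri_table.csv")) as p:
        return pd.read_csv(p)


def load_canonical_comparison() -> pd.DataFrame:
    """Canonical comparison fixture: reference, study and derived columns per GW."""
    with importlib.resources.as_file(_data_path("canonical_comparison.csv")) as p:
        return pd.read_csv(p)


def load_harel_reference() -> pd.DataFrame:
    """Tidy external reference percentiles: ``gw, percentile, value_umol_l``."""
    wide = load_canonical_comparison()
    rows = [
        {"gw": int(r.gw), "percentile": p, "value_umol_l": float(r[f"harel_p{p}"])}
        for _, r in wide.iterrows()
        for p in PERCENTILES
    ]
    return pd.DataFrame(rows)


def read_reference_table(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = {"gw", "percentile", "value_umol_l"} - set(frame.columns)
    if missing:
        raise ValueError(f"reference CSV missing columns: {sorted(missing)}")
    if frame.duplicated(["gw", "percentile"]).any():
        raise ValueError("duplicate (gw, percentile) rows in reference table")
    if (frame["value_umol_l"] <= 0).any():
        raise ValueError("reference values must be positive")
    return frame


def write_reference_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, columns=["gw", "percentile", "value_umol_l"])


def trimester_of(gw: int) -> int:
    """Trimester assignment: GW 0-13 -> 1, 14-27 -> 2, 28-41 -> 3."""
    if not 0 <= gw <= 41:
        raise ValueError(f"gw {gw} outside [0, 41]")
    if gw <= 13:
        return 1
    if gw <= 27:
        return 2
    return 3


@dataclass(frozen=True)
class ComparisonTable:
    """Per-row differences plus GW / trimester / percentile aggregates."""

    rows: pd.DataFrame  # gw, trimester, percentile, reference, study, difference
    mean_by_gw: pd.Series  # index gw
    mean_by_trimester: pd.Series  # index trimester
    mean_by_percentile: pd.Series  # index percentile

    def to_wide_frame(self) -> pd.DataFrame:
        """Wide per-GW layout mirroring the canonical comparison table."""
        out = []
        for gw, grp in self.rows.groupby("gw"):
            row = {"gw": gw, "trimester": trimester_of(int(gw))}
            for _, r in grp.iterrows():
                p = int(r.percentile)
                row[f"reference_p{p}"] = r.reference
                row[f"study_p{p}"] = r.study
                row[f"diff_p{p}"] = r.difference
            row["mean_diff_by_gw"] = self.mean_by_gw.loc[gw]
            row["diff_by_trimester"] = self.mean_by_trimester.loc[row["trimester"]]
            out.append(row)
        return pd.DataFrame(out)


def compare_to_reference(ref: pd.DataFrame,
                         study: dict[float, PolynomialCurve] | pd.DataFrame) -> ComparisonTable:
    """Signed per-(GW, percentile) differences between study and reference.

    Parameters
    ----------
    ref :
        Tidy reference table (``gw, percentile, value_umol_l``).
    study :
        Either a mapping percentile -> fitted curve (evaluated at each
        reference GW) or a tidy table of study percentile values in the
        same schema as ``ref``.

    Study values are rounded to 0.1 before differencing, differences to 0.1
    before averaging; a negative difference means the study value is lower
    than the reference. Reference GWs outside a curve's domain are skipped
    with a warning.
    """
    records = []
    if isinstance(study, pd.DataFrame):
        lookup = {(int(r.gw), int(r.percentile)): float(r.value_umol_l)
                  for r in study.itertuples()}
        get_study = lambda gw, p: lookup.get((gw, p))
    else:
        curves = {int(k): v for k, v in study.items()}

        def get_study(gw, p):
            curve = curves.get(p)
            if curve is None:
                raise KeyError(f"no study curve for percentile {p}")
            if not curve.in_domain(gw):
                return None
            return float(curve(gw))

    for r in ref.itertuples():
        gw, p = int(r.gw), int(r.percentile)
        value = get_study(gw, p)
        if value is None:
            warnings.warn(f"GW {gw} outside study domain; skipped", stacklevel=2)
            continue
        study_val = round(value, 1)
        records.append({
            "gw": gw,
            "trimester": trimester_of(gw),
            "percentile": p,
            "reference": float(r.value_umol_l),
            "study": study_val,
            "difference": round(study_val - float(r.value_umol_l), 1),
        })
    rows = pd.DataFrame(records)
    if rows.empty:
        raise ValueError("no overlapping gestational weeks between reference and study")
    mean_by_gw = rows.groupby("gw")["difference"].mean().round(1)
    tri_of_gw = rows.groupby("gw")["trimester"].first()
    mean_by_trimester = mean_by_gw.groupby(tri_of_gw).mean().round(1)
    mean_by_trimester.index.name = "trimester"
    mean_by_percentile = rows.groupby("percentile")["difference"].mean().round(1)
    return ComparisonTable(rows, mean_by_gw, mean_by_trimester, mean_by_percentile)
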