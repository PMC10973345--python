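"""Clinical flagging and the end-to-end pipeline.

``evaluate_patient`` implements the reporting scheme: given a SCr result
and the gestational week, the gestational eGFR is calculated automatically
and both values are flagged against their GW-specific reference intervals
(below the interval suggests inadequate hyperfiltration — possible
pregnancy-induced kidney disease or preeclampsia; above it, anemia or
hypoproteinemia may be suspected; the directions are opposite for eGFR).

``run_pipeline`` chains the whole analysis: synthetic cohort (or a cohort
CSV) -> gestational periods -> bootstrap reference intervals -> smoothed
percentile curves -> eGFR transform and its intervals -> combined RI table
-> external comparison, writing every intermediate diagnostic as CSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import comparison as cmp
from .cohort import CohortConfig, generate_cohort, read_cohort, write_cohort
from .curves import DegreeSearchConfig, PolynomialCurve, smooth_limits
from .egfr import (
    EgfrParameters,
    analytic_median_table,
    build_egfr_ri,
    gestational_egfr,
    load_canonical_parameters,
    make_ri_table,
    ri_table_to_frame,
)
from .reference_interval import (
    BinningConfig,
    GaussianCriteria,
    ResampleConfig,
    bin_into_periods,
    build_period_ri,
)

__all__ = [
    "PatientReport",
    "PipelineConfig",
    "PipelineResult",
    "PipelineStageError",
    "evaluate_patient",
    "run_pipeline",
]

log = logging.getLogger("gestri")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.__cause__ = cause


@dataclass(frozen=True)
class PatientReport:
    """Flagged SCr / eGFR result for one measurement.

    Flags are ``"below" | "within" | "above"`` against closed intervals
    (a boundary value counts as within); both are ``None`` with an
    explanatory note for pre-implantation weeks.
    """

    gw: int
    scr_umol_l: float
    egfr_ml_min: float | None
    scr_flag: str | None
    egfr_flag: str | None
    scr_interval: tuple[float, float] | None
    egfr_interval: tuple[float, float] | None
    note: str = ""


def _flag(value: float, lower: float, upper: float) -> str:
    if value < lower:
        return "below"
    if value > upper:
        return "above"
    return "within"


def evaluate_patient(scr: float, gw: int, ri_table: pd.DataFrame,
                     params: EgfrParameters | None = None) -> PatientReport:
    """Flag one SCr measurement against the GW-specific intervals.

    ``ri_table`` is a frame with the combined table columns (``gw``,
    ``scr_lower`` ... ``egfr_upper``), typically from
    :func:`gestri.egfr.make_ri_table` / ``ri_table_to_frame`` or the
    canonical packaged table.
    """
    if scr <= 0:
        raise ValueError("scr must be positive")
    if 0 <= gw <= 3:
        return PatientReport(gw, scr, None, None, None, None, None,
                             note="pre-implantation period (GW 0-3): no interval established")
    params = params or load_canonical_parameters()
    if "scr_lower" not in ri_table.columns:  # canonical-table column naming
        ri_table = ri_table.rename(columns={
            "scr_p2_5": "scr_lower", "scr_p97_5": "scr_upper",
            "egfr_p2_5": "egfr_lower", "egfr_p97_5": "egfr_upper"})
    row = ri_table[ri_table["gw"] == gw]
    if len(row) != 1:
        raise ValueError(f"no unique RI row for GW {gw}")
    row = row.iloc[0]
    scr_lo, scr_hi = float(row["scr_lower"]), float(row["scr_upper"])
    eg_lo, eg_hi = float(row["egfr_lower"]), float(row["egfr_upper"])
    egfr = gestational_egfr(scr, gw, params)
    return PatientReport(
        gw=gw, scr_umol_l=scr, egfr_ml_min=egfr,
        scr_flag=_flag(scr, scr_lo, scr_hi),
        egfr_flag=_flag(egfr, eg_lo, eg_hi),
        scr_interval=(scr_lo, scr_hi),
        egfr_interval=(eg_lo, eg_hi),
    )


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; a master seed drives all randomness."""

    cohort: CohortConfig | None = field(default_factory=CohortConfig)
    cohort_csv: str | None = None
    params: EgfrParameters | None = None
    binning: BinningConfig = field(default_factory=BinningConfig)
    resample: ResampleConfig = field(default_factory=ResampleConfig)
    search: DegreeSearchConfig = field(default_factory=DegreeSearchConfig)
    criteria: GaussianCriteria = field(default_factory=GaussianCriteria)
    ri_percentiles: tuple[float, ...] = (2.5, 50.0, 97.5)
    comparison_percentiles: tuple[float, ...] = (95.0, 75.0, 50.0)
    seed: int = 0
    out_dir: str | None = None


@dataclass(frozen=True)
class PipelineResult:
    cohort: pd.DataFrame | None
    scr_sets: list | None
    scr_curves: dict[float, PolynomialCurve] | None
    egfr_curves: dict[float, PolynomialCurve] | None
    ri_table: pd.DataFrame | None
    comparison: cmp.ComparisonTable | None
    artifacts: dict[str, Path]


def _write(frame: pd.DataFrame, out_dir: Path | None, name: str,
           artifacts: dict[str, Path]) -> None:
    if out_dir is None:
        return
    path = out_dir / name
    frame.to_csv(path, index=False)
    artifacts[name] = path
    log.info("wrote %s (%d rows)", path, len(frame))


def _period_frame(sets) -> pd.DataFrame:
    return pd.DataFrame([{
        "label": rs.period.label, "gw_lo": rs.period.gw_lo, "gw_hi": rs.period.gw_hi,
        "n": rs.period.size, "kurtosis": rs.diagnostics.kurtosis,
        "skewness": rs.diagnostics.skewness, "shapiro_p": rs.diagnostics.shapiro_p,
        "ci_lower": rs.ci_lower, "ci_upper": rs.ci_upper, "coverage": rs.coverage,
        "accepted": rs.accepted, "attempts_used": rs.attempts_used,
    } for rs in sets])


def _curve_frame(curves: dict[float, PolynomialCurve],
                 details: dict | None = None) -> pd.DataFrame:
    rows = []
    for p, c in curves.items():
        row = {"percentile": p, "degree": c.degree,
               "domain_lo": c.domain[0], "domain_hi": c.domain[1]}
        row.update({f"c{i}": v for i, v in enumerate(c.coefficients)})
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig | None = None) -> PipelineResult:
    """Run the full analysis; deterministic given ``config.seed``.

    Stages are labelled in errors and logs. Without a cohort (``cohort``
    and ``cohort_csv`` both unset) only the analytic median-SCr table is
    produced — the formula-only mode.
    """
    config = config or PipelineConfig()
    params = config.params or load_canonical_parameters()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}
    master = np.random.SeedSequence(config.seed)
    log.info("pipeline start, master seed %d", config.seed)

    if config.cohort is None and config.cohort_csv is None:
        table = analytic_median_table(params)
        _write(table, out_dir, "median_table.csv", artifacts)
        return PipelineResult(None, None, None, None, table, None, artifacts)

    try:  # ---- stage: cohort
        if config.cohort_csv is not None:
            cohort = read_cohort(config.cohort_csv)
        else:
            seed = int(master.spawn(1)[0].generate_state(1)[0] % (2**31))
            cohort = generate_cohort(replace(config.cohort, seed=seed))
        log.info("cohort: %d measurements / %d subjects",
                 len(cohort), cohort["subject_id"].nunique())
        if out_dir is not None:
            write_cohort(cohort, out_dir / "cohort.csv")
            artifacts["cohort.csv"] = out_dir / "cohort.csv"
    except Exception as exc:
        raise PipelineStageError("cohort", exc) from exc

    try:  # ---- stage: scr reference intervals
        periods = bin_into_periods(cohort, config.binning)
        log.info("binned into %d gestational periods: %s", len(periods),
                 [(p.gw_lo, p.gw_hi, p.size) for p in periods])
        rng = np.random.default_rng(master.spawn(1)[0])
        scr_sets = [build_period_ri(gp, config.resample, config.criteria, rng=rng)
                    for gp in periods]
        not_acc = [rs.period.label for rs in scr_sets if not rs.accepted]
        if not_acc:
            log.warning("periods not meeting the full acceptance rule "
                        "(Gaussian + >=95%% coverage): %s", not_acc)
        _write(_period_frame(scr_sets), out_dir, "scr_period_ri.csv", artifacts)
    except Exception as exc:
        raise PipelineStageError("scr-reference-interval", exc) from exc

    try:  # ---- stage: scr percentile curves
        wanted = tuple(sorted(set(config.ri_percentiles) | set(config.comparison_percentiles)))
        scr_curves, scr_details = smooth_limits(
            scr_sets, wanted, config.search, require_accepted=False, return_details=True)
        _write(_curve_frame(scr_curves), out_dir, "scr_curves.csv", artifacts)
        freq = pd.DataFrame([
            {"percentile": p, "degree": d, "count": c}
            for p, sel in scr_details.items() for d, c in sel.frequencies.items()
        ])
        _write(freq, out_dir, "scr_degree_frequencies.csv", artifacts)
    except Exception as exc:
        raise PipelineStageError("scr-curves", exc) from exc

    try:  # ---- stage: egfr intervals
        egfr_res = build_egfr_ri(
            cohort, params, config.binning,
            replace(config.resample, seed=int(master.spawn(1)[0].generate_state(1)[0] % (2**31))),
            config.search, config.criteria, config.ri_percentiles)
        _write(_period_frame(egfr_res.period_sets), out_dir, "egfr_period_ri.csv", artifacts)
        _write(_curve_frame(egfr_res.curves), out_dir, "egfr_curves.csv", artifacts)
    except Exception as exc:
        raise PipelineStageError("egfr-reference-interval", exc) from exc

    try:  # ---- stage: combined table
        rows = make_ri_table({p: scr_curves[p] for p in (2.5, 50.0, 97.5)},
                             egfr_res.curves, params, egfr_baseline=egfr_res.baseline)
        ri_table = ri_table_to_frame(rows)
        _write(ri_table, out_dir, "ri_table.csv", artifacts)
    except Exception as exc:
        raise PipelineStageError("ri-table", exc) from exc

    try:  # ---- stage: external comparison
        ref = cmp.load_harel_reference()
        table = cmp.compare_to_reference(
            ref, {p: scr_curves[p] for p in config.comparison_percentiles})
        _write(table.to_wide_frame(), out_dir, "comparison.csv", artifacts)
    except Exception as exc:
        raise PipelineStageError("comparison", exc) from exc

    log.info("pipeline done")
    return PipelineResult(cohort, scr_sets, scr_curves, egfr_res.curves,
                          ri_table, table, artifacts)
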