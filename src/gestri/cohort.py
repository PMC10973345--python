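"""Synthetic serum-creatinine cohorts with the structure the pipeline assumes.

The original hospital measurements are not publicly available, so every
downstream stage is exercised on generated cohorts that reproduce the
study's statistical shape: ~957 subjects contributing ~1,484 measurements,
sampling heavily concentrated in the third trimester, right-skewed per-week
SCr distributions, and a curvilinear median trajectory with a mid-pregnancy
nadir (the canonical degree-4 median polynomial for GW >= 4, a constant
baseline for the pre-implantation weeks 0-3).

Per gestational week the SCr value follows a shifted log-normal

    SCr = loc + scale * exp(sigma * Z),      Z ~ N(0, 1)

parameterised so that the median is exactly the truth curve, the
coefficient of variation equals ``dispersion`` and the skewness equals
``skew``. The default dispersion 0.25 / skewness 0.76 are back-solved from
the width of the canonical reference interval and correspond to an
essentially plain log-normal (loc ~ 0); per-period skewness stays well
below 1.5, the regime in which the mean-of-two bootstrap is considered
applicable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .curves import PolynomialCurve
from .reference_interval import GW_MAX, GW_MIN

__all__ = [
    "CohortConfig",
    "InvalidConfigError",
    "default_sampling_weights",
    "generate_cohort",
    "true_quantile",
    "write_cohort",
    "read_cohort",
]

CANONICAL_MEDIAN_COEFFS = (56.7, -0.223, -0.113, 0.00545, -0.0000653)
CANONICAL_BSC = 55.25

COHORT_COLUMNS = ["subject_id", "gw", "scr_umol_l"]


class InvalidConfigError(ValueError):
    pass


def default_sampling_weights(gw_range: tuple[int, int] = (GW_MIN, GW_MAX)) -> np.ndarray:
    """Per-GW measurement probabilities, strongly third-trimester weighted.

    10% of the mass on GW 0-13, 20% on 14-27 and 70% on 28-41 (uniform
    within each block), matching the reported predominance of third-
    trimester prenatal examinations.
    """
    lo, hi = gw_range
    gws = np.arange(lo, hi + 1)
    block = np.where(gws <= 13, 0.10 / 14, np.where(gws <= 27, 0.20 / 14, 0.70 / 14))
    return block / block.sum()


def _lognormal_shape(skew: float) -> float:
    """Shape sigma of a log-normal with the given skewness (Cardano root)."""
    if skew <= 0:
        raise InvalidConfigError("skew must be positive (right-skewed)")
    # skewness g = (w + 2) sqrt(w - 1) with w = exp(sigma^2); u = sqrt(w - 1)
    # solves u^3 + 3u - g = 0
    g = float(skew)
    disc = np.sqrt(g * g / 4.0 + 1.0)
    u = np.cbrt(g / 2.0 + disc) + np.cbrt(g / 2.0 - disc)
    return float(np.sqrt(np.log(1.0 + u * u)))


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings; defaults are the emulated study conditions."""

    n_subjects: int = 957
    n_measurements: int = 1484
    gw_range: tuple[int, int] = (GW_MIN, GW_MAX)
    sampling_weights: np.ndarray | None = None
    truth_median_curve: PolynomialCurve = field(
        default_factory=lambda: PolynomialCurve(CANONICAL_MEDIAN_COEFFS, domain=(4, GW_MAX)))
    preimplantation_scr: float = CANONICAL_BSC
    dispersion: float = 0.25
    skew: float = 0.76
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.gw_range
        if lo < GW_MIN or hi > GW_MAX or lo > hi:
            raise InvalidConfigError(f"gw_range {self.gw_range} outside [{GW_MIN}, {GW_MAX}]")
        if self.n_subjects < 1 or self.n_measurements < self.n_subjects:
            raise InvalidConfigError("need n_measurements >= n_subjects >= 1")
        n_gws = hi - lo + 1
        if self.n_measurements > self.n_subjects * n_gws:
            raise InvalidConfigError("more measurements than (subject, GW) pairs available")
        if self.dispersion < 0:
            raise InvalidConfigError("dispersion must be >= 0")
        if self.preimplantation_scr <= 0:
            raise InvalidConfigError("preimplantation_scr must be positive")
        w = self.sampling_weights
        if w is None:
            w = default_sampling_weights(self.gw_range)
        else:
            w = np.asarray(w, dtype=float)
            if len(w) != n_gws:
                raise InvalidConfigError(f"sampling_weights must have {n_gws} entries")
            if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
                raise InvalidConfigError("sampling_weights must be non-negative and sum to 1")
        object.__setattr__(self, "sampling_weights", w)

    def median_at(self, gw) -> np.ndarray:
        """Truth median: constant pre-implantation level, curve for GW >= 4."""
        gw = np.asarray(gw, dtype=float)
        return np.where(gw <= 3, self.preimplantation_scr, self.truth_median_curve(gw))

    def _loc_scale_sigma(self, gw):
        """Shifted log-normal parameters matching median, CV and skewness."""
        m = self.median_at(gw)
        if self.dispersion == 0:
            return m, np.zeros_like(m), 0.0
        sigma = _lognormal_shape(self.skew)
        w = np.exp(sigma * sigma)
        a, u = np.sqrt(w), np.sqrt(w - 1.0)
        c = self.dispersion
        scale = c * m / (a * u + c * (1.0 - a))
        return m - scale, scale, sigma


def generate_cohort(config: CohortConfig | None = None) -> pd.DataFrame:
    """Generate a cohort table with columns ``subject_id, gw, scr_umol_l``.

    Every subject contributes at least one measurement; subjects may be
    measured in several gestational weeks but at most once per week,
    mirroring the rule that only the initial SCr value per GW is kept.
    Fully reproducible from ``config.seed``.
    """
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.gw_range
    gw_values = np.arange(lo, hi + 1)

    subj = np.concatenate([
        np.arange(config.n_subjects),
        rng.integers(0, config.n_subjects, size=config.n_measurements - config.n_subjects),
    ])
    gw = rng.choice(gw_values, size=config.n_measurements, p=config.sampling_weights)
    # enforce at most one measurement per subject per GW by redrawing clashes
    for _ in range(10_000):
        dup = pd.DataFrame({"s": subj, "g": gw}).duplicated(keep="first").to_numpy()
        if not dup.any():
            break
        gw[dup] = rng.choice(gw_values, size=int(dup.sum()), p=config.sampling_weights)
    else:  # pragma: no cover - only reachable with pathological weight vectors
        raise InvalidConfigError("could not place all measurements without duplicate (subject, GW)")

    loc, scale, sigma = config._loc_scale_sigma(gw)
    if config.dispersion == 0:
        scr = config.median_at(gw)
    else:
        scr = loc + scale * np.exp(sigma * rng.standard_normal(config.n_measurements))
        bad = scr <= 0
        while bad.any():  # negligible probability at sane settings; keep support positive
            scr[bad] = loc[bad] + scale[bad] * np.exp(
                sigma * rng.standard_normal(int(bad.sum())))
            bad = scr <= 0

    frame = pd.DataFrame({
        "subject_id": np.char.add("S", np.char.zfill((subj + 1).astype(str), 5)),
        "gw": gw.astype(int),
        "scr_umol_l": scr,
    })
    return frame.sort_values(["subject_id", "gw"], ignore_index=True)


def true_quantile(config: CohortConfig, gw: int, p: float) -> float:
    """Exact quantile of the generator's per-GW distribution.

    Closed form: ``loc + scale * exp(sigma * Phi^-1(p))``. The p = 0.5 case
    returns the truth median (the configured constant for GW 0-3). Serves
    as the oracle for recovery tests.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    lo, hi = config.gw_range
    if not lo <= gw <= hi:
        raise ValueError(f"gw {gw} outside configured range {config.gw_range}")
    loc, scale, sigma = config._loc_scale_sigma(gw)
    return float(loc + scale * np.exp(sigma * stats.norm.ppf(p)))


def write_cohort(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, columns=COHORT_COLUMNS)


def read_cohort(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(COHORT_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"cohort CSV missing columns: {sorted(missing)}")
    return frame
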