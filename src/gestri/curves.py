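"""Polynomial smoothing of gestational-period percentile points.

Reference intervals are first estimated per gestational *period* (a bin of
3-4 weeks), which leaves the limits defined only at a handful of abscissae.
This module converts those period-level percentile points into smooth
week-level curves: the polynomial degree is chosen by repeated k-fold
cross-validation (modal degree over many random fold repartitions), and the
final curve is an ordinary least-squares fit of that degree on all points.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np

__all__ = [
    "PolynomialCurve",
    "CurvePoint",
    "DegreeSearchConfig",
    "DegreeSelection",
    "SmoothingError",
    "cv_mse",
    "select_degree",
    "fit_polynomial",
    "smooth_limits",
]


class SmoothingError(RuntimeError):
    """Raised when period-level input is unsuitable for curve fitting."""


@dataclass(frozen=True)
class PolynomialCurve:
    """A polynomial in gestational week, ascending-power coefficients.

    The raw-power basis is used deliberately so the fitted coefficients can
    be read off in the same form as the canonical median-SCr equation.

    Parameters
    ----------
    coefficients :
        Ascending powers: ``coefficients[i]`` multiplies ``gw**i``.
    domain :
        Inclusive gestational-week interval on which the curve is meant to
        be evaluated. Evaluation outside the domain is extrapolation and is
        not prevented, only discouraged.
    """

    coefficients: tuple[float, ...]
    domain: tuple[float, float] = (4.0, 41.0)

    def __post_init__(self) -> None:
        if len(self.coefficients) == 0:
            raise ValueError("a polynomial needs at least one coefficient")
        object.__setattr__(self, "coefficients", tuple(float(c) for c in self.coefficients))

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1

    def __call__(self, gw):
        gw = np.asarray(gw, dtype=float)
        out = np.polynomial.polynomial.polyval(gw, np.asarray(self.coefficients))
        return float(out) if out.ndim == 0 else out

    def in_domain(self, gw) -> bool:
        lo, hi = self.domain
        return bool(np.all((np.asarray(gw) >= lo) & (np.asarray(gw) <= hi)))


class CurvePoint(NamedTuple):
    """One fitting point: representative GW of a period and a percentile value."""

    x: float
    y: float


@dataclass(frozen=True)
class DegreeSearchConfig:
    """Settings for the cross-validated polynomial degree search.

    ``k_folds=3`` mirrors the trimester structure of pregnancy; candidate
    degrees run from 1 to 5 and the search is repeated ``repeats`` times
    with fresh random fold partitions, the winner being the modal degree.
    """

    degree_range: tuple[int, int] = (1, 5)
    k_folds: int = 3
    repeats: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.degree_range
        if lo < 1 or hi < lo:
            raise ValueError(f"bad degree_range {self.degree_range}")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @property
    def degrees(self) -> range:
        return range(self.degree_range[0], self.degree_range[1] + 1)


@dataclass(frozen=True)
class DegreeSelection:
    """Outcome of a modal-degree search."""

    degree: int
    frequencies: dict[int, int] = field(compare=False)

    @property
    def repeats(self) -> int:
        return sum(self.frequencies.values())


def _as_xy(points: Iterable) -> tuple[np.ndarray, np.ndarray]:
    pts = [(float(p[0]), float(p[1])) for p in points]
    if not pts:
        raise ValueError("no points given")
    x, y = map(np.asarray, zip(*pts))
    return x.astype(float), y.astype(float)


def _ols_coeffs(x: np.ndarray, y: np.ndarray, degree: int) -> np.ndarray:
    """Least-squares ascending-power coefficients; error on rank deficiency."""
    design = np.vander(x, degree + 1, increasing=True)
    coeffs, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < degree + 1:
        raise SmoothingError(
            f"rank-deficient design for degree {degree} with {len(x)} points "
            "(duplicate or too few distinct x values)"
        )
    return coeffs


def _partition(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Random partition of range(n) into k folds with sizes differing by at most 1."""
    return np.array_split(rng.permutation(n), k)


def cv_mse(points: Sequence, degree: int, k_folds: int = 3, seed: int | None = 0,
           rng: np.random.Generator | None = None) -> float:
    """k-fold cross-validated mean squared error of a degree-``degree`` fit.

    The points are randomly partitioned into ``k_folds`` folds; each fold in
    turn is held out, the polynomial is fit by OLS on the rest, and the
    squared prediction error on the held-out fold is averaged; the fold
    means are then averaged.

    Identical ``seed`` gives an identical partition and hence identical MSE.
    """
    x, y = _as_xy(points)
    n = len(x)
    if n < k_folds:
        raise ValueError(f"need at least k_folds={k_folds} points, got {n}")
    min_train = n - int(np.ceil(n / k_folds))
    if degree + 1 > min_train:
        raise ValueError(
            f"degree {degree} too high: training folds have only {min_train} points"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    fold_mse = []
    for held in _partition(n, k_folds, rng):
        train = np.setdiff1d(np.arange(n), held, assume_unique=False)
        coeffs = _ols_coeffs(x[train], y[train], degree)
        pred = np.polynomial.polynomial.polyval(x[held], coeffs)
        fold_mse.append(np.mean((y[held] - pred) ** 2))
    return float(np.mean(fold_mse))


def select_degree(points: Sequence, cfg: DegreeSearchConfig | None = None) -> DegreeSelection:
    """Pick the polynomial degree by repeated cross-validation.

    Each repeat draws one random fold partition, computes the CV MSE for
    every candidate degree on that same partition, and records the argmin
    degree (ties broken toward the smaller degree). The modal degree over
    all repeats is returned together with the full frequency table; a tie
    for the mode is again broken toward the smaller degree.
    """
    cfg = cfg or DegreeSearchConfig()
    x, y = _as_xy(points)
    n = len(x)
    degrees = list(cfg.degrees)
    min_train = n - int(np.ceil(n / cfg.k_folds))
    if degrees[-1] + 1 > min_train:
        raise ValueError(
            f"max degree {degrees[-1]} needs more than {n} points with k={cfg.k_folds}"
        )
    rng = np.random.default_rng(cfg.seed)
    freq = {d: 0 for d in degrees}
    vander = np.vander(x, degrees[-1] + 1, increasing=True)
    idx = np.arange(n)
    for _ in range(cfg.repeats):
        folds = _partition(n, cfg.k_folds, rng)
        mses = np.empty(len(degrees))
        for j, d in enumerate(degrees):
            err = 0.0
            for held in folds:
                train = np.setdiff1d(idx, held, assume_unique=False)
                design = vander[train, : d + 1]
                coeffs, _, rank, _ = np.linalg.lstsq(design, y[train], rcond=None)
                if rank < d + 1:
                    raise SmoothingError(f"rank-deficient training fold for degree {d}")
                err += np.mean((y[held] - vander[held, : d + 1] @ coeffs) ** 2)
            mses[j] = err / cfg.k_folds
        freq[degrees[int(np.argmin(mses))]] += 1  # argmin keeps the first = smallest degree
    best = max(freq.values())
    modal = min(d for d, c in freq.items() if c == best)
    return DegreeSelection(degree=modal, frequencies=freq)


def fit_polynomial(points: Sequence, degree: int,
                   domain: tuple[float, float] | None = None) -> PolynomialCurve:
    """OLS polynomial of the given degree through all points.

    With exactly ``degree + 1`` distinct abscissae this interpolates the
    points (up to floating-point conditioning of the raw-power basis).
    """
    x, y = _as_xy(points)
    if len(x) < degree + 1:
        raise ValueError(f"need at least {degree + 1} points for degree {degree}")
    coeffs = _ols_coeffs(x, y, degree)
    if domain is None:
        domain = (float(x.min()), float(x.max()))
    return PolynomialCurve(coefficients=tuple(coeffs), domain=domain)


def smooth_limits(period_ris: Sequence, percentiles: Sequence[float] = (2.5, 50.0, 97.5),
                  cfg: DegreeSearchConfig | None = None, *, require_accepted: bool = True,
                  domain: tuple[float, float] = (4.0, 41.0),
                  return_details: bool = False):
    """Smooth period-level resample percentiles into week-level curves.

    The pre-implantation period (GW 0-3) is excluded: it serves as the
    baseline and no interval is established for it. For every requested
    percentile a :class:`CurvePoint` is built at each remaining period's
    midpoint, the degree is chosen by :func:`select_degree`, and the final
    OLS curve is fit on all points, with domain GW 4-41.

    Parameters
    ----------
    period_ris :
        ``ResampleSet`` objects (one per gestational period).
    percentiles :
        Percentiles of the resample sets to smooth, in percent.
    require_accepted :
        When true (default), raise :class:`SmoothingError` listing any
        period whose resample set is not accepted. The end-to-end pipeline
        relaxes this because the coverage criterion is rarely attainable;
        see the package methods note.
    return_details :
        Also return the per-percentile :class:`DegreeSelection`.

    Returns
    -------
    dict mapping percentile -> :class:`PolynomialCurve` (and, when
    ``return_details``, a second dict mapping percentile ->
    :class:`DegreeSelection`).
    """
    from .reference_interval import resample_quantile  # local import, no cycle at module load

    cfg = cfg or DegreeSearchConfig()
    usable = [rs for rs in period_ris if rs.period.gw_hi > 3]
    if len(usable) < 6:
        raise SmoothingError(
            f"need at least 6 gestational periods beyond GW 0-3, got {len(usable)}"
        )
    if require_accepted:
        bad = [rs.period.label for rs in usable if not rs.accepted]
        if bad:
            raise SmoothingError(f"non-accepted gestational periods: {bad}")

    curves: dict[float, PolynomialCurve] = {}
    details: dict[float, DegreeSelection] = {}
    for i, p in enumerate(percentiles):
        points = [
            CurvePoint(x=rs.period.midpoint, y=resample_quantile(rs.values, p / 100.0))
            for rs in usable
        ]
        sel = select_degree(points, replace(cfg, seed=cfg.seed + i))
        curve = fit_polynomial(points, sel.degree, domain=domain)
        curves[float(p)] = curve
        details[float(p)] = sel
    if return_details:
        return curves, details
    return curves
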