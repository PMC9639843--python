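"""Power-law analysis of binary occupancy data.

The central idea: for species *i* with occurrence frequency :math:`p_i`
(fraction of S-quadrats occupied) and occurrence-count variance :math:`v_i`
across L-quadrats of *n* S-quadrats each, compare the observed variance with
the variance expected under independent (binomial) occupancy on a log scale,

.. math::

    x_i = \\log \\frac{p_i (1 - p_i)}{n}, \\qquad
    y_i = \\log \\frac{v_i}{n^2},

and fit the community-wide power law :math:`y_i = \\alpha + \\beta x_i +
\\varepsilon_i` by ordinary least squares.  Under purely random occupancy
``E[v] = n p (1 - p)`` and every point falls on the identity line ``y = x``
(slope 1, intercept 0).  The vertical distance of a species from that line,

.. math::

    \\delta_i = y_i - x_i,

is its spatial heterogeneity index: positive means more aggregated (patchy)
than random, zero random, negative more even (uniform) than random.  The
regression residual :math:`\\varepsilon_i` measures heterogeneity relative to
the community trend instead of the random null.

Logs are base 10 by default (``delta`` and ``alpha`` scale by ln 10 under a
base change; ``beta`` and R² are base-invariant).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import AnalysisError, DomainError, FitError, UndefinedTransformError
from .survey import OccurrenceMatrix, SummaryTable, aggregate_counts

__all__ = [
    "SpeciesStats",
    "PowerLawFit",
    "AnalysisResult",
    "species_frequency",
    "species_count_variance",
    "binomial_transform",
    "observed_transform",
    "fit_power_law",
    "heterogeneity_index",
    "classify_distribution",
    "reconstruct_points",
    "analyze",
    "analyze_summary",
]

Label = Literal["patchy", "random", "uniform"]


@dataclass(frozen=True)
class SpeciesStats:
    """Per-species statistics of the power-law analysis.

    ``excluded`` species (p in {0, 1} or zero count variance, where the log
    transforms are undefined) carry ``nan`` for x, y, delta, epsilon and a
    human-readable ``reason``; they never enter the regression.
    """

    species: str
    p: float
    v: float = math.nan
    x: float = math.nan
    y: float = math.nan
    delta: float = math.nan
    epsilon: float = math.nan
    label: Label | None = None
    excluded: bool = False
    reason: str | None = None


@dataclass(frozen=True)
class PowerLawFit:
    """OLS fit of y on x with intercept.

    ``residuals`` are aligned to the points passed in (one per included
    species, input order) and sum to zero; ``r_squared`` is the squared
    Pearson correlation of x and y, identical to :math:`1 - SSE/SST` for
    simple regression with intercept.
    """

    alpha: float
    beta: float
    r_squared: float
    residuals: np.ndarray
    n_points: int


@dataclass(frozen=True)
class AnalysisResult:
    """Output of :func:`analyze`: per-species stats plus the community fit."""

    species_stats: tuple[SpeciesStats, ...]
    fit: PowerLawFit

    @property
    def included(self) -> tuple[SpeciesStats, ...]:
        return tuple(s for s in self.species_stats if not s.excluded)

    @property
    def excluded(self) -> tuple[SpeciesStats, ...]:
        return tuple(s for s in self.species_stats if s.excluded)


def species_frequency(counts: Sequence[int] | np.ndarray, m: int) -> float:
    """Occurrence frequency: the fraction of all S-quadrats occupied.

    ``counts`` holds one occurrence count per L-quadrat, each in ``[0, m]``;
    the frequency is their total divided by ``m × n_lquadrats`` (equivalently
    the mean of the per-L-quadrat fractions count/m).
    """
    c = np.asarray(counts, dtype=float)
    if c.size == 0:
        raise DomainError("counts must be non-empty")
    if (c < 0).any() or (c > m).any():
        raise DomainError(f"counts must lie in [0, {m}]")
    return float(c.sum() / (m * c.size))


def species_count_variance(
    counts: Sequence[int] | np.ndarray,
    estimator: Literal["sample", "population"] = "sample",
) -> float:
    """Variance of occurrence counts across L-quadrats.

    The sample estimator (divide by N−1, the default) is unbiased for the
    binomial variance ``m·p(1−p)`` under random occupancy, which keeps the
    random null exactly on the identity line; the population estimator
    (divide by N) is available for comparison.
    """
    c = np.asarray(counts, dtype=float)
    if c.size < 2:
        raise DomainError("variance requires at least 2 L-quadrat counts")
    ddof = 1 if estimator == "sample" else 0
    if estimator not in ("sample", "population"):
        raise DomainError(f"unknown estimator {estimator!r}")
    return float(c.var(ddof=ddof))


def _log(value: float, base: float) -> float:
    return math.log(value) / math.log(base)


def binomial_transform(p: float, n: int, base: float = 10.0) -> float:
    """x-value: log of the binomial (random-occupancy) variance over n².

    ``log_base(p(1−p)/n)`` — the per-L-quadrat count variance under
    independent Bernoulli occupancy, ``n·p(1−p)``, divided by ``n²``.
    Undefined at p = 0 or 1.
    """
    if not 0.0 < p < 1.0:
        raise UndefinedTransformError(
            f"binomial transform undefined for p={p} (needs 0 < p < 1)"
        )
    return _log(p * (1.0 - p) / n, base)


def observed_transform(v: float, n: int, base: float = 10.0) -> float:
    """y-value: log of the observed count variance over n²; undefined at v=0."""
    if v <= 0.0:
        raise UndefinedTransformError(
            f"observed transform undefined for v={v} (needs v > 0)"
        )
    return _log(v / (n * n), base)


def fit_power_law(points: Sequence[tuple[float, float]] | np.ndarray) -> PowerLawFit:
    """Ordinary least squares of y on x with intercept.

    Requires at least 3 points with non-degenerate x.  Residuals are returned
    in input order; R² is the squared Pearson correlation (for a perfectly
    collinear input R² = 1 and all residuals vanish).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise FitError("points must be a sequence of (x, y) pairs")
    if pts.shape[0] < 3:
        raise FitError(f"power-law fit needs >= 3 points, got {pts.shape[0]}")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0.0:
        raise FitError("x values are all identical; regression undefined")
    res = stats.linregress(x, y)
    fitted = res.intercept + res.slope * x
    residuals = y - fitted
    r2 = float(res.rvalue**2)
    if np.ptp(y) == 0.0:  # horizontal data: correlation degenerate, define R²=0
        r2 = 0.0
    return PowerLawFit(
        alpha=float(res.intercept),
        beta=float(res.slope),
        r_squared=r2,
        residuals=residuals,
        n_points=int(pts.shape[0]),
    )


def heterogeneity_index(x: float, y: float) -> float:
    """Vertical distance δ = y − x from the random-occupancy identity line."""
    return y - x


def classify_distribution(delta: float, tolerance: float = 0.0) -> Label:
    """Map δ to a spatial pattern: patchy (δ>0), random (δ=0), uniform (δ<0).

    ``tolerance`` widens the random band to |δ| ≤ tolerance for noisy
    estimates; the strict criteria correspond to tolerance 0.
    """
    if tolerance < 0:
        raise DomainError(f"tolerance must be nonnegative, got {tolerance}")
    if delta > tolerance:
        return "patchy"
    if delta < -tolerance:
        return "uniform"
    return "random"


def reconstruct_points(
    summary: SummaryTable, n: int = 4, base: float = 10.0
) -> np.ndarray:
    """Rebuild the regression points (x, y) from a published (p, δ) table.

    Inverts the definition of δ: ``x = log_base(p(1−p)/n)`` and ``y = x + δ``,
    row order preserved.  This is how the analysis is reproduced when only
    the printed summary, not the raw quadrat data, is available.
    """
    pts = np.empty((len(summary), 2), dtype=float)
    for i, (sp, p, d) in enumerate(
        zip(summary.species, summary.p, summary.delta)
    ):
        if not 0.0 < p < 1.0:
            raise UndefinedTransformError(
                f"row {i} ({sp}): p={p} outside (0, 1), x undefined"
            )
        x = _log(p * (1.0 - p) / n, base)
        pts[i] = (x, x + d)
    return pts


def analyze(
    matrix: OccurrenceMatrix,
    *,
    estimator: Literal["sample", "population"] = "sample",
    base: float = 10.0,
    tolerance: float = 0.0,
) -> AnalysisResult:
    """Run the full per-species pipeline on a raw occupancy matrix.

    Composes occurrence counts → frequency and variance → log transforms →
    community OLS → heterogeneity index, classification and residuals.
    Species whose transforms are undefined (absent, ubiquitous, or constant
    counts) are excluded with a reason; at least 3 includable species are
    required for the regression.
    """
    counts = aggregate_counts(matrix)
    m = matrix.design.m_subquadrats
    prelim: list[SpeciesStats] = []
    for sp in matrix.species:
        c = counts[sp].to_numpy()
        p = species_frequency(c, m)
        v = species_count_variance(c, estimator)
        if p == 0.0:
            prelim.append(SpeciesStats(sp, p, v, excluded=True, reason="absent (p=0)"))
        elif p == 1.0:
            prelim.append(
                SpeciesStats(sp, p, v, excluded=True, reason="ubiquitous (p=1)")
            )
        elif v == 0.0:
            prelim.append(
                SpeciesStats(
                    sp, p, v, excluded=True, reason="zero count variance (v=0)"
                )
            )
        else:
            x = binomial_transform(p, m, base)
            y = observed_transform(v, m, base)
            prelim.append(SpeciesStats(sp, p, v, x, y, delta=heterogeneity_index(x, y)))

    included = [s for s in prelim if not s.excluded]
    if len(included) < 3:
        reasons = {s.species: s.reason for s in prelim if s.excluded}
        raise AnalysisError(
            f"only {len(included)} includable species (need >= 3); "
            f"exclusions: {reasons}"
        )
    fit = fit_power_law([(s.x, s.y) for s in included])
    eps = iter(fit.residuals)
    final = [
        s
        if s.excluded
        else replace(
            s,
            epsilon=float(next(eps)),
            label=classify_distribution(s.delta, tolerance),
        )
        for s in prelim
    ]
    return AnalysisResult(tuple(final), fit)


def analyze_summary(
    summary: SummaryTable,
    *,
    n: int = 4,
    base: float = 10.0,
    tolerance: float = 0.0,
) -> AnalysisResult:
    """Re-run the community regression from a published (p, δ) summary.

    Reconstruction mode: the points are rebuilt with
    :func:`reconstruct_points` and refitted, yielding fresh residuals ε that
    can be compared against any printed values.  The count variance v is not
    recoverable from a summary and is reported as nan.
    """
    pts = reconstruct_points(summary, n, base)
    fit = fit_power_law(pts)
    stats_out = [
        SpeciesStats(
            species=sp,
            p=float(p),
            x=float(x),
            y=float(y),
            delta=float(y - x),
            epsilon=float(e),
            label=classify_distribution(float(y - x), tolerance),
        )
        for sp, p, (x, y), e in zip(
            summary.species, summary.p, pts, fit.residuals
        )
    ]
    return AnalysisResult(tuple(stats_out), fit)
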