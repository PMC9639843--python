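"""Community-level summaries: weighted heterogeneity, diversity, and the
frequency–heterogeneity trend.

The community heterogeneity index is the occurrence-frequency-weighted mean
of the per-species indices,

.. math:: \\delta_c = \\frac{\\sum_i p_i \\delta_i}{\\sum_i p_i},

a convex combination bounded by the smallest and largest δ.  Diversity is
the Shannon–Wiener index on frequencies normalized to sum to one (natural
log).  The rising trend of δ with p is summarized by a power-form fit
``δ = a·p^b`` obtained by OLS on (ln p, ln δ).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError, FitError

__all__ = [
    "CommunityIndices",
    "FrequencyHeterogeneityFit",
    "community_heterogeneity",
    "shannon_diversity",
    "frequency_heterogeneity_fit",
    "community_indices",
]


@dataclass(frozen=True)
class CommunityIndices:
    """δ_c, H' and the normalized frequencies they are built from."""

    delta_c: float
    shannon: float
    species_count: int
    normalized_frequencies: np.ndarray


@dataclass(frozen=True)
class FrequencyHeterogeneityFit:
    """Fit of the δ-vs-p trend.

    ``form='power'``: δ = a·p^b, with r_squared on the (ln p, ln δ) scale.
    ``form='linear'``: δ = a + b·p on the raw scale.
    ``n_used`` counts the pairs that entered the fit (the power form drops
    nonpositive δ, where the log is undefined).
    """

    form: Literal["power", "linear"]
    a: float
    b: float
    r_squared: float
    n_used: int


def _paired(frequencies: Sequence[float], deltas: Sequence[float]):
    p = np.asarray(frequencies, dtype=float)
    d = np.asarray(deltas, dtype=float)
    if p.shape != d.shape:
        raise DomainError(
            f"frequencies and deltas must align, got {p.shape} vs {d.shape}"
        )
    if p.size == 0:
        raise DomainError("need at least one (p, delta) pair")
    return p, d


def community_heterogeneity(
    frequencies: Sequence[float], deltas: Sequence[float]
) -> float:
    """Frequency-weighted mean heterogeneity δ_c = Σ p_i δ_i / Σ p_i."""
    p, d = _paired(frequencies, deltas)
    if (p <= 0).any():
        raise DomainError("all frequencies must be > 0 to act as weights")
    return float(np.sum(p * d) / np.sum(p))


def shannon_diversity(frequencies: Sequence[float]) -> float:
    """Shannon–Wiener H' = −Σ p'_i ln p'_i on frequencies normalized to 1.

    Scale-invariant in the input (only relative frequencies matter) and
    bounded by ln(s) for s species, attained at equal frequencies.
    """
    p = np.asarray(frequencies, dtype=float)
    if p.size == 0 or (p <= 0).any():
        raise DomainError("all frequencies must be strictly positive")
    q = p / p.sum()
    return float(-(q * np.log(q)).sum())


def frequency_heterogeneity_fit(
    frequencies: Sequence[float],
    deltas: Sequence[float],
    *,
    form: Literal["power", "linear"] = "power",
    on_nonpositive: Literal["drop", "raise"] = "drop",
) -> FrequencyHeterogeneityFit:
    """Fit the trend of the heterogeneity index against occurrence frequency.

    The default power form δ = a·p^b is an OLS line on log-log axes, so its
    r_squared is the squared Pearson correlation of (ln p, ln δ).  Pairs with
    δ ≤ 0 have no log and are dropped with a warning (``on_nonpositive=
    'raise'`` turns that into an error); the linear form uses all pairs.
    """
    p, d = _paired(frequencies, deltas)
    if form == "power":
        if (p <= 0).any():
            raise DomainError("power form requires all frequencies > 0")
        keep = d > 0
        if not keep.all():
            rows = np.flatnonzero(~keep).tolist()
            if on_nonpositive == "raise":
                raise DomainError(f"nonpositive delta at rows {rows}; log undefined")
            warnings.warn(
                f"dropping {len(rows)} pairs with delta <= 0 from power-form "
                f"fit (rows {rows})",
                stacklevel=2,
            )
        pk, dk = p[keep], d[keep]
        if pk.size < 3:
            raise FitError(f"power-form fit needs >= 3 usable pairs, got {pk.size}")
        lx, ly = np.log(pk), np.log(dk)
        if np.ptp(lx) == 0.0:
            raise FitError("frequencies all identical; fit undefined")
        res = stats.linregress(lx, ly)
        r2 = 0.0 if np.ptp(ly) == 0.0 else float(res.rvalue**2)
        return FrequencyHeterogeneityFit(
            "power", math.exp(res.intercept), float(res.slope), r2, int(pk.size)
        )
    if form == "linear":
        if p.size < 3:
            raise FitError(f"linear fit needs >= 3 pairs, got {p.size}")
        if np.ptp(p) == 0.0:
            raise FitError("frequencies all identical; fit undefined")
        res = stats.linregress(p, d)
        r2 = 0.0 if np.ptp(d) == 0.0 else float(res.rvalue**2)
        return FrequencyHeterogeneityFit(
            "linear", float(res.intercept), float(res.slope), r2, int(p.size)
        )
    raise DomainError(f"unknown fit form {form!r}")


def community_indices(
    frequencies: Sequence[float], deltas: Sequence[float]
) -> CommunityIndices:
    """Bundle δ_c and H' for one species set."""
    p, d = _paired(frequencies, deltas)
    return CommunityIndices(
        delta_c=community_heterogeneity(p, d),
        shannon=shannon_diversity(p),
        species_count=int(p.size),
        normalized_frequencies=p / p.sum(),
    )
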