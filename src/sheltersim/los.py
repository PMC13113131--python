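"""Geometric length-of-stay algebra and marketing-impact functions.

The model treats a shelter day as a discrete unit.  An available animal is
adopted on any given day with constant odds ``D`` (daily odds of adoption),
so the length of stay (LOS) is geometric with success probability
``P = D / (1 + D)`` and mean ``L = 1 / P = 1 + 1/D``.

A marketing intervention (a high-visibility kennel, an online feature, an
adoption event) is modeled as a multiplicative effect on the daily odds:
for one day the odds become ``A * D``.  The functions below give the
resulting change in expected LOS, per day of use of the intervention,
under three views of the within-day adoption process:

* :func:`one_day_impact` -- ``X(A, D)``: proportional odds, one day of
  marketing (equivalently, per-day-normalized continuous marketing).
* :func:`exponential_rate_impact` -- ``Y(A, lam)``: LOS as a continuous
  exponential variable whose rate is scaled by ``A``; the impact is
  ``1 - A`` regardless of the baseline rate.
* :func:`windowed_impact` -- ``Z(A, D)``: constant hazard within each
  day's adoption window of fixed length, so marketing maps the daily odds
  through ``D_A = (1 + D)**A - 1``.

All functions accept scalars or numpy arrays and broadcast.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Literal

import numpy as np
import pandas as pd

__all__ = [
    "adoption_probability",
    "nonadoption_probability",
    "expected_los",
    "los_to_odds",
    "one_day_impact",
    "marketed_los_one_day",
    "exponential_rate_impact",
    "windowed_odds",
    "windowed_impact",
    "impact_curve",
]

#: Shortest baseline expected LOS for which the one-day-per-step model is
#: intended; below this (daily odds above 1) intra-day timing starts to
#: matter and results should be read with care.
MIN_MODEL_LOS = 2.0


def _validate_positive(name: str, value) -> np.ndarray:
    arr = np.asarray(value, dtype=float)
    if arr.size == 0 or not np.all(arr > 0):
        raise ValueError(f"{name} must be > 0, got {value!r}")
    return arr


def _ret(arr: np.ndarray):
    # collapse 0-d results back to plain floats for scalar input
    return float(arr) if arr.ndim == 0 else arr


def adoption_probability(odds):
    """Daily probability of adoption ``P(D) = D / (1 + D)``."""
    d = _validate_positive("odds", odds)
    return _ret(d / (1.0 + d))


def nonadoption_probability(odds):
    """Daily probability of non-adoption ``Q(D) = 1 / (1 + D)``."""
    d = _validate_positive("odds", odds)
    return _ret(1.0 / (1.0 + d))


def expected_los(odds):
    """Expected length of stay ``L(D) = 1/P(D) = 1 + 1/D`` in days."""
    d = _validate_positive("odds", odds)
    return _ret(1.0 + 1.0 / d)


def los_to_odds(los):
    """Daily odds implied by an expected LOS: ``D = 1 / (L - 1)``.

    Inverse of :func:`expected_los`.  Raises for ``L <= 1`` (unreachable
    under the geometric model); warns for ``L < 2``, where the daily
    discretization is outside the model's intended range.
    """
    arr = np.asarray(los, dtype=float)
    if arr.size == 0 or not np.all(arr > 1.0):
        raise ValueError(f"expected LOS must be > 1 day, got {los!r}")
    if np.any(arr < MIN_MODEL_LOS):
        warnings.warn(
            "expected LOS below 2 days implies daily adoption odds above 1; "
            "the one-day time step is coarse for such animals",
            stacklevel=2,
        )
    return _ret(1.0 / (arr - 1.0))


def one_day_impact(multiplier, odds):
    """Change in expected LOS from one day of marketing, ``X(A, D)``.

    ``X(A, D) = (1 - A) / (1 + A D)``: negative (LOS reduced) for a boost
    ``A > 1``, positive for a penalty ``A < 1``, zero at ``A = 1``.  This
    is also the LOS change *per day of use* of a continuous intervention
    kept in place until adoption.  ``|X|`` grows with the baseline LOS and
    approaches ``A - 1`` as ``D -> 0``.
    """
    a = _validate_positive("multiplier", multiplier)
    d = _validate_positive("odds", odds)
    return _ret((1.0 - a) / (1.0 + a * d))


def marketed_los_one_day(multiplier, odds):
    """Expected LOS with one day of marketing then return to baseline.

    ``L_X(A, D) = P(AD) + (1 + L(D)) Q(AD)``: adopted on day one with
    probability ``P(AD)``; otherwise one day has passed and, the process
    being memoryless, the remaining expected stay is the baseline ``L(D)``.
    Satisfies ``L_X - L = X`` exactly.
    """
    a = _validate_positive("multiplier", multiplier)
    d = _validate_positive("odds", odds)
    ad = a * d
    p_marketed = ad / (1.0 + ad)
    q_marketed = 1.0 / (1.0 + ad)
    baseline = 1.0 + 1.0 / d
    return _ret(p_marketed + (1.0 + baseline) * q_marketed)


def exponential_rate_impact(multiplier, rate):
    """Per-day LOS impact under a continuous exponential LOS, ``Y(A, lam)``.

    If LOS is exponential with rate ``lam`` and marketing scales the rate
    to ``A * lam``, the mean drops from ``1/lam`` to ``1/(A lam)``;
    normalized by the ``1/(A lam)`` days of use this is ``1 - A`` for
    every ``lam``.  The rate argument is validated but cancels: under a
    continuous constant-hazard model the benefit of marketing does not
    depend on the baseline LOS (the same holds for a Weibull LOS when the
    intervention scales the scale parameter and leaves the shape alone).
    The preference for long-stay animals is therefore a consequence of the
    day being a discrete unit.
    """
    a = _validate_positive("multiplier", multiplier)
    lam = _validate_positive("rate", rate)
    return _ret((1.0 - a) * np.ones_like(lam))


def windowed_odds(multiplier, odds):
    """Daily odds after marketing under the intra-day-window model.

    With a constant hazard inside each day's adoption window, baseline
    odds ``D = exp(lam T) - 1`` become ``D_A = (1 + D)**A - 1`` when the
    hazard is scaled by ``A``.  Only the product ``lam * T`` matters, so
    the window length never appears explicitly.  Exceeds the proportional
    ``A * D`` for ``A > 1``.
    """
    a = _validate_positive("multiplier", multiplier)
    d = _validate_positive("odds", odds)
    return _ret(np.expm1(a * np.log1p(d)))


def windowed_impact(multiplier, odds):
    """Per-day LOS impact under the intra-day-window model, ``Z(A, D)``.

    ``Z(A, D) = ((1 + D)**(1 - A) - 1) / D``, evaluated via
    ``expm1((1 - A) * log1p(D)) / D`` so that the small-``D`` regime --
    where ``Z`` converges to ``X`` and to the common limit ``1 - A`` -- is
    computed without cancellation.
    """
    a = _validate_positive("multiplier", multiplier)
    d = _validate_positive("odds", odds)
    return _ret(np.expm1((1.0 - a) * np.log1p(d)) / d)


ImpactVariant = Literal["one_day", "windowed"]

_VARIANTS = {"one_day": one_day_impact, "windowed": windowed_impact}


def impact_curve(
    multipliers: Iterable[float],
    los_values: Iterable[float],
    variant: ImpactVariant = "one_day",
) -> pd.DataFrame:
    """Tabulate the marketing impact over a grid of (A, baseline L).

    Returns a DataFrame with columns ``variant``, ``A``, ``baseline_L``,
    ``baseline_D`` and ``impact_per_day``, one row per (A, L) pair, in
    row-major (A outer, L inner) order.  These are the curve families
    plotted when comparing intervention strength across baseline LOS.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {sorted(_VARIANTS)}, got {variant!r}")
    a_vals = np.atleast_1d(np.asarray(list(multipliers), dtype=float))
    l_vals = np.atleast_1d(np.asarray(list(los_values), dtype=float))
    if a_vals.size == 0 or l_vals.size == 0:
        raise ValueError("impact_curve requires at least one A and one L value")
    _validate_positive("multiplier", a_vals)
    if not np.all(l_vals > 1.0):
        raise ValueError("all baseline LOS values must exceed 1 day")
    d_vals = 1.0 / (l_vals - 1.0)
    a_grid, l_grid = np.meshgrid(a_vals, l_vals, indexing="ij")
    _, d_grid = np.meshgrid(a_vals, d_vals, indexing="ij")
    impact = _VARIANTS[variant](a_grid, d_grid)
    return pd.DataFrame(
        {
            "variant": variant,
            "A": a_grid.ravel(),
            "baseline_L": l_grid.ravel(),
            "baseline_D": d_grid.ravel(),
            "impact_per_day": np.asarray(impact).ravel(),
        }
    )
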