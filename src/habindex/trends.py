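"""Per-species long- and short-term trends from smoothed occupancy series.

Each species' occupancy time series is first smoothed with a cubic
smoothing spline — the one-dimensional analogue of a thin-plate spline —
whose penalty is chosen by generalized cross-validation (GCV), subject
to a floor of 3 effective degrees of freedom so the fit is never forced
all the way down to a straight line.  The smoother is the classic
natural-spline penalised least squares in fitted-value form,

    f = argmin ||y - f||^2 + lam * f' K f,

where f' K f is the integrated squared second derivative of the natural
cubic interpolant of f (Green & Silverman second-difference form).  A
single eigendecomposition of K makes the whole GCV profile cheap.

The trend between two years is the annualised proportional rate of
change of the smoothed series,

    trend = (v_pen / v_start)^(1 / (t_pen - t_start)) - 1,

between the first year of the assessment window and the penultimate
year of the species' own series (the last smoothed year is considered
unstable and never used).  ``metric="total"`` gives the unannualised
proportional change instead.  Long-term trends start at each species'
first year of data; short-term trends at a fixed window start
(2005-style).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import TRENDS_COLUMNS

__all__ = [
    "InsufficientDataError",
    "smoothing_matrix_eigh",
    "smooth_series",
    "trend_value",
    "trend_table",
]

logger = logging.getLogger(__name__)

#: GCV search grid for the roughness penalty (log10 bounds, points).
_LAM_GRID = np.logspace(-8.0, 8.0, 81)
#: Floor on effective degrees of freedom of the chosen fit.
_EDF_FLOOR = 3.0


class InsufficientDataError(ValueError):
    """Too few distinct years to smooth a series."""


def _penalty_matrix(x: np.ndarray) -> np.ndarray:
    """Roughness penalty K with f'Kf = integral of (g'')^2 for the
    natural cubic spline g interpolating (x, f)."""
    n = len(x)
    h = np.diff(x)
    # second-difference matrix D ((n-2) x n) and weight matrix W
    D = np.zeros((n - 2, n))
    idx = np.arange(n - 2)
    D[idx, idx] = 1.0 / h[:-1]
    D[idx, idx + 1] = -1.0 / h[:-1] - 1.0 / h[1:]
    D[idx, idx + 2] = 1.0 / h[1:]
    W = (
        np.diag((h[:-1] + h[1:]) / 3.0)
        + np.diag(h[1:-1] / 6.0, k=1)
        + np.diag(h[1:-1] / 6.0, k=-1)
    )
    return D.T @ np.linalg.solve(W, D)


def smoothing_matrix_eigh(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition (eigenvalues, eigenvectors) of the penalty K.

    The smoother at penalty lam is U diag(1/(1+lam s)) U'; its trace
    (the effective degrees of freedom) is sum 1/(1+lam s).
    """
    s, U = np.linalg.eigh(_penalty_matrix(np.asarray(x, dtype=float)))
    return np.clip(s, 0.0, None), U


def smooth_series(years, values, lam: float | None = None) -> np.ndarray:
    """Smoothing-spline fit of an occupancy series at its observed years.

    Parameters
    ----------
    years, values
        The series; years must be distinct, at least 4 of them.
    lam
        Roughness penalty; None (default) selects it by GCV over a log
        grid, restricted to fits with at least 3 effective degrees of
        freedom.

    Returns
    -------
    Fitted values at the input years, clamped to (0, 1) via the
    occupancy floor.
    """
    x = np.asarray(years, dtype=float)
    y = np.asarray(values, dtype=float)
    order = np.argsort(x)
    if len(np.unique(x)) < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct years to smooth, got {len(np.unique(x))}"
        )
    if len(np.unique(x)) != len(x):
        raise InsufficientDataError("years must be distinct within a series")
    xs, ys = x[order], y[order]
    n = len(xs)
    s, U = smoothing_matrix_eigh(xs)
    z = U.T @ ys
    if lam is None:
        shrink = 1.0 / (1.0 + np.outer(_LAM_GRID, s))  # (n_lam, n)
        edf = shrink.sum(axis=1)
        rss = (((1.0 - shrink) * z) ** 2).sum(axis=1)
        gcv = n * rss / (n - edf) ** 2
        ok = edf >= min(_EDF_FLOOR, n)
        candidates = np.flatnonzero(ok)
        lam = float(_LAM_GRID[candidates[np.argmin(gcv[candidates])]])
    fit_sorted = U @ (z / (1.0 + lam * s))
    fit = np.empty(n)
    fit[order] = fit_sorted
    return np.clip(fit, 1e-6, 1.0 - 1e-6)


def trend_value(
    years,
    smoothed,
    start_year: int,
    metric: str = "annual",
) -> float:
    """Proportional rate of change from ``start_year`` to the penultimate year.

    ``metric="annual"`` (default) annualises:
    (v_pen / v_start)^(1/span) - 1; ``metric="total"`` returns
    v_pen / v_start - 1.
    """
    x = np.asarray(years)
    v = np.asarray(smoothed, dtype=float)
    order = np.argsort(x)
    x, v = x[order], v[order]
    if start_year not in x:
        raise ValueError(f"start year {start_year} not in the smoothed series")
    pen_year = int(x[-2])
    if pen_year <= start_year:
        raise ValueError(
            f"penultimate year {pen_year} does not follow start year {start_year}"
        )
    v_start = float(v[x == start_year][0])
    v_pen = float(v[x == pen_year][0])
    if v_start <= 0:
        raise ValueError("smoothed value at the start year must be positive")
    if metric == "annual":
        return (v_pen / v_start) ** (1.0 / (pen_year - start_year)) - 1.0
    if metric == "total":
        return v_pen / v_start - 1.0
    raise ValueError(f"unknown trend metric {metric!r}")


def trend_table(
    occupancy: pd.DataFrame,
    short_start: int = 2005,
    end: int | None = None,
    metric: str = "annual",
) -> pd.DataFrame:
    """Long- and short-term trends for every eligible species.

    Each species' full series is smoothed once; the long-term trend runs
    from its own first year, the short-term trend from ``short_start``,
    both to the penultimate year of the series (capped at ``end`` if
    given).  Species whose data start after ``short_start`` get no
    short-term row and are flagged via the module logger; series with
    fewer than four years are skipped entirely.
    """
    rows = []
    no_short, skipped = [], []
    for species, grp in occupancy.groupby("species", sort=True):
        grp = grp.sort_values("year")
        years = grp["year"].to_numpy()
        if len(years) < 4:
            skipped.append(species)
            continue
        smoothed = smooth_series(years, grp["occupancy"].to_numpy())
        pen_year = int(years[-2]) if end is None else min(int(years[-2]), int(end))
        # re-use the full-series smooth; select the window endpoints
        long_start = int(years[0])
        if pen_year > long_start:
            t = _windowed_trend(years, smoothed, long_start, pen_year, metric)
            rows.append((species, "long", long_start, pen_year, t))
        if int(years[0]) <= short_start < pen_year:
            t = _windowed_trend(years, smoothed, short_start, pen_year, metric)
            rows.append((species, "short", short_start, pen_year, t))
        else:
            no_short.append(species)
    if skipped:
        logger.warning("species with < 4 years skipped: %s", skipped)
    if no_short:
        logger.warning(
            "species lacking the short window starting %d (long-only): %s",
            short_start,
            no_short,
        )
    return pd.DataFrame(rows, columns=TRENDS_COLUMNS)


def _windowed_trend(years, smoothed, start_year, pen_year, metric) -> float:
    v_start = float(np.asarray(smoothed)[np.asarray(years) == start_year][0])
    v_pen = float(np.asarray(smoothed)[np.asarray(years) == pen_year][0])
    if metric == "annual":
        return (v_pen / v_start) ** (1.0 / (pen_year - start_year)) - 1.0
    if metric == "total":
        return v_pen / v_start - 1.0
    raise ValueError(f"unknown trend metric {metric!r}")
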