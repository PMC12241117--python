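"""Habitat-level Distribution Index: weighted geometric statistics.

The Distribution Index (DI) for a habitat in a year is the weighted
geometric mean of the annual occupancy scores of the species weighted
into that habitat,

    DI = exp( sum_i w_i ln x_i / sum_i w_i ),

with the matching multiplicative spread measured by the weighted
geometric standard deviation,

    gsd = exp( sqrt( sum_i w_i (ln x_i - m)^2 / sum_i w_i ) ),

using the biased (population) weighted variance of log occupancies.
Both are invariant to rescaling the weights by any positive constant,
so the weighting schemes differ through how they *distribute* mass
across species, never through overall scale.

Occupancy scores are clamped to [1e-6, 1 - 1e-6] before taking logs
(the floor rule): geometric means are undefined at zero, and while
occupancy-model outputs are interior, synthetic edge cases must not
crash.  The number of clamped cells is reported via the module logger.

Species missing a particular year are dropped for that year only, with
the remaining weights renormalised; a ``coverage`` column (fraction of
the habitat's total weight present that year) makes the gaps visible.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import INDEX_COLUMNS

__all__ = [
    "OCCUPANCY_FLOOR",
    "weighted_geometric_mean",
    "weighted_geometric_sd",
    "clamp_occupancy",
    "distribution_index",
]

logger = logging.getLogger(__name__)

#: Lower clamp for occupancy before logs; the upper clamp is 1 - floor.
OCCUPANCY_FLOOR = 1e-6


def weighted_geometric_mean(values, weights) -> float:
    """exp of the weighted mean of log values.

    All values must be strictly positive and the weights nonnegative
    with a positive sum.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(x <= 0):
        raise ValueError("geometric mean requires strictly positive values")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weights must not all be zero")
    return float(np.exp(np.dot(w, np.log(x)) / wsum))


def weighted_geometric_sd(values, weights) -> float:
    """exp of the weighted (population) SD of log values; >= 1.

    Requires at least two positively weighted values, otherwise the
    spread is undefined.
    """
    x = np.asarray(values, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(x <= 0):
        raise ValueError("geometric SD requires strictly positive values")
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    if np.count_nonzero(w) < 2:
        raise ValueError("geometric SD requires at least two positively weighted values")
    wsum = w.sum()
    logs = np.log(x)
    m = np.dot(w, logs) / wsum
    var = np.dot(w, (logs - m) ** 2) / wsum
    return float(np.exp(np.sqrt(var)))


def clamp_occupancy(occupancy: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Apply the floor rule; returns (clamped table, number of clamped cells)."""
    out = occupancy.copy()
    clipped = out["occupancy"].clip(OCCUPANCY_FLOOR, 1.0 - OCCUPANCY_FLOOR)
    n_clamped = int((clipped != out["occupancy"]).sum())
    out["occupancy"] = clipped
    return out, n_clamped


def distribution_index(
    occupancy: pd.DataFrame,
    weights: pd.DataFrame,
) -> pd.DataFrame:
    """Distribution Index time series per habitat, method and year.

    Parameters
    ----------
    occupancy
        Long table (species, year, occupancy).  Every species appearing
        in ``weights`` must have at least one occupancy row; a species
        absent entirely raises a missing-species error naming it.
    weights
        Long weight table (species, habitat, method, weight); zero
        weights are ignored.

    Returns
    -------
    DataFrame with columns habitat, method, year, di, gsd, coverage,
    n_species, sorted by habitat, method, year.  ``gsd`` is NaN when a
    single species contributes (spread undefined); ``coverage`` is the
    fraction of the habitat's total weight whose species have data that
    year.
    """
    w = weights.loc[weights["weight"] > 0]
    missing = sorted(set(w["species"]) - set(occupancy["species"]))
    if missing:
        raise ValueError(f"weighted species absent from occupancy data: {missing}")
    empty = sorted(
        set(weights["habitat"].unique()) - set(w["habitat"].unique())
    )
    if empty:
        logger.warning("habitats with zero weighted species, emitting no rows: %s", empty)

    occ, n_clamped = clamp_occupancy(occupancy)
    if n_clamped:
        logger.warning("clamped %d occupancy value(s) to the floor rule", n_clamped)

    merged = w.merge(occ, on="species")
    total_weight = (
        w.groupby(["habitat", "method"])["weight"].sum().rename("total_weight")
    )

    rows = []
    for (habitat, method, year), cell in merged.groupby(
        ["habitat", "method", "year"], sort=True
    ):
        wv = cell["weight"].to_numpy()
        xv = cell["occupancy"].to_numpy()
        di = weighted_geometric_mean(xv, wv)
        gsd = weighted_geometric_sd(xv, wv) if np.count_nonzero(wv) >= 2 else np.nan
        coverage = float(wv.sum() / total_weight.loc[(habitat, method)])
        rows.append((habitat, method, int(year), di, gsd, coverage, len(cell)))
    out = pd.DataFrame(rows, columns=INDEX_COLUMNS)
    return out.sort_values(["habitat", "method", "year"], kind="stable").reset_index(
        drop=True
    )
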