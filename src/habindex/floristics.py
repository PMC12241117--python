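"""From floristic records to per-species, per-habitat mean cover.

The abundance input to the weighting schemes is an approximate cover
proportion per species per habitat, built in three steps:

1. each record's frequency class (I-V) becomes the midpoint of its
   20%-wide band (I -> 0.10, II -> 0.30, ..., V -> 0.90);
2. its Domin cover-abundance score (1-10) becomes a cover proportion via
   Currall's relation, percent cover = Domin^2.6 / 4;
3. the cover estimate for the record is the product of the two, and the
   per-habitat cover is the mean of these estimates over the communities
   of that habitat in which the species occurs, using the community ->
   habitat correspondence table.

Step 3 averages over occupied communities only by default: the floristic
table records occurrences, so absences carry no Domin score.  Set
``zero_pad_communities=True`` to average over every community of the
habitat instead (absent communities contributing zero cover).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import COVER_COLUMNS, FREQUENCY_CLASSES, SchemaError

__all__ = [
    "FREQUENCY_MIDPOINTS",
    "frequency_midpoint",
    "domin_to_cover",
    "cover_estimate",
    "aggregate_to_habitat",
]

#: Midpoint proportion of each 20%-wide frequency band.
FREQUENCY_MIDPOINTS = {"I": 0.10, "II": 0.30, "III": 0.50, "IV": 0.70, "V": 0.90}

#: Exponent and divisor of Currall's Domin -> percent-cover relation.
_CURRALL_EXPONENT = 2.6
_CURRALL_DIVISOR = 4.0


def frequency_midpoint(frequency_class: str) -> float:
    """Midpoint proportion of a Roman frequency class (e.g. II -> 0.30)."""
    try:
        return FREQUENCY_MIDPOINTS[frequency_class]
    except KeyError:
        raise SchemaError(
            f"unknown frequency class {frequency_class!r}; "
            f"expected one of {FREQUENCY_CLASSES}"
        ) from None


def domin_to_cover(domin) -> float:
    """Convert a Domin score (1-10) to a cover proportion.

    Currall's relation gives percent cover = Domin^2.6 / 4; the result is
    divided by 100 to a proportion.  Strictly increasing on 1..10, with
    Domin 10 -> 0.99527 (never reaching 1).

    Accepts a scalar or array; raises for scores outside [1, 10].
    """
    d = np.asarray(domin)
    if np.any((d < 1) | (d > 10)) or not np.allclose(d, np.round(d)):
        raise SchemaError(f"Domin score {domin!r} outside integer range [1, 10]")
    out = (d.astype(float) ** _CURRALL_EXPONENT / _CURRALL_DIVISOR) / 100.0
    return float(out) if np.isscalar(domin) else out


def cover_estimate(frequency_class: str, domin: int) -> float:
    """Cover estimate = frequency midpoint x Domin-converted cover proportion."""
    return frequency_midpoint(frequency_class) * domin_to_cover(domin)


def aggregate_to_habitat(
    floristics: pd.DataFrame,
    correspondence: pd.DataFrame,
    zero_pad_communities: bool = False,
) -> pd.DataFrame:
    """Aggregate record-level cover estimates to species x habitat means.

    Parameters
    ----------
    floristics
        Validated floristic table (community_id, species,
        frequency_class, domin).
    correspondence
        community_id -> habitat mapping; every community in
        ``floristics`` must appear, or an unmapped-community error is
        raised listing the offenders.  A community mapped to several
        habitats contributes its full cover estimate to each.
    zero_pad_communities
        If True, the per-habitat mean runs over all communities of the
        habitat, counting communities where the species is absent as
        zero cover.  Default False: mean over occupied communities only.

    Returns
    -------
    DataFrame with columns species, habitat, cover — one row per
    (species, habitat) pair reachable through the correspondence in
    which the species occurs; unreachable pairs are absent (zero
    downstream).
    """
    unmapped = sorted(
        set(floristics["community_id"]) - set(correspondence["community_id"])
    )
    if unmapped:
        raise SchemaError(
            f"communities with no habitat correspondence: {unmapped}"
        )
    records = floristics.copy()
    records["cover_estimate"] = records["frequency_class"].map(
        FREQUENCY_MIDPOINTS
    ) * domin_to_cover(records["domin"].to_numpy())
    merged = records.merge(correspondence, on="community_id")
    grouped = (
        merged.groupby(["species", "habitat"], sort=True)["cover_estimate"]
        .agg(["sum", "count"])
        .reset_index()
    )
    if zero_pad_communities:
        n_comm = correspondence.groupby("habitat")["community_id"].nunique()
        grouped["cover"] = grouped["sum"] / grouped["habitat"].map(n_comm)
    else:
        grouped["cover"] = grouped["sum"] / grouped["count"]
    out = grouped[["species", "habitat", "cover"]].reset_index(drop=True)
    return out[COVER_COLUMNS]
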