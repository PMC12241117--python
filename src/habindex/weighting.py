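"""The four species x habitat weighting schemes.

A species' occupancy trend has to be allocated among the habitats it
occurs in before habitat-level indices can be built.  Four schemes are
implemented, from simplest to most informed:

``Unw``
    unweighted presence: weight 1 in every habitat with positive cover.
    Generalists are effectively counted once per habitat, so they carry
    more total weight than specialists.
``W-S``
    even split: 1 / (number of occupied habitats), so every species has
    total weight 1 (a species in three habitats gets 0.333 in each).
``W-A``
    abundance split: weight proportional to the species' mean cover in
    each habitat, normalised to sum to 1 per species.
``W-AH``
    abundance x area: the W-A weights scaled by each habitat's share of
    total area, reflecting where most of the species' population sits.
    By default the result is renormalised so each species again sums to
    1; pass ``renormalize=False`` for the raw area-scaled weights.

All four schemes share the same support — the set of (species, habitat)
cells with strictly positive cover — and differ only in the mass placed
on those cells.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import WEIGHTS_COLUMNS, SchemaError

__all__ = [
    "METHODS",
    "weights_unweighted",
    "weights_split",
    "weights_abundance",
    "weights_abundance_area",
    "weight_table",
]

#: Canonical method order (reference level first).
METHODS = ("Unw", "W-S", "W-A", "W-AH")


class DegenerateSpeciesError(SchemaError):
    """A species has no positive weight mass under the requested scheme."""


def _support(cover: pd.DataFrame) -> pd.DataFrame:
    """Cells with strictly positive cover; the shared support of all schemes."""
    out = cover.loc[cover["cover"] > 0, ["species", "habitat", "cover"]]
    return out.reset_index(drop=True)


def _finish(df: pd.DataFrame, method: str) -> pd.DataFrame:
    df = df[["species", "habitat", "weight"]].copy()
    df.insert(2, "method", method)
    return (
        df.sort_values(["species", "habitat"], kind="stable")
        .reset_index(drop=True)[WEIGHTS_COLUMNS]
    )


def weights_unweighted(cover: pd.DataFrame) -> pd.DataFrame:
    """Unw: weight 1 wherever cover > 0."""
    sup = _support(cover)
    sup["weight"] = 1.0
    return _finish(sup, "Unw")


def weights_split(cover: pd.DataFrame) -> pd.DataFrame:
    """W-S: 1 / (number of habitats the species occupies); rows sum to 1."""
    sup = _support(cover)
    n_hab = sup.groupby("species")["habitat"].transform("size")
    sup["weight"] = 1.0 / n_hab
    return _finish(sup, "W-S")


def weights_abundance(cover: pd.DataFrame) -> pd.DataFrame:
    """W-A: cover(s, h) / sum_h cover(s, h); rows sum to 1."""
    sup = _support(cover)
    all_zero = set(cover["species"]) - set(sup["species"])
    if all_zero:
        raise DegenerateSpeciesError(
            f"species with all-zero cover, no abundance weight possible: "
            f"{sorted(all_zero)}"
        )
    total = sup.groupby("species")["cover"].transform("sum")
    sup["weight"] = sup["cover"] / total
    return _finish(sup, "W-A")


def weights_abundance_area(
    cover: pd.DataFrame,
    areas: pd.DataFrame,
    renormalize: bool = True,
) -> pd.DataFrame:
    """W-AH: W-A weights scaled by relative habitat area.

    raw(s, h) = w_WA(s, h) * area(h) / total area.  With
    ``renormalize=True`` (default) each species' row is rescaled to sum
    to 1, keeping every species' total weight equal; with False the raw
    area-scaled weights are returned.

    Raises a missing-area error for habitats in the support without an
    area entry, and a degenerate-species error if renormalising a
    species whose occupied habitats all have zero area.
    """
    wa = weights_abundance(cover)
    area_map = areas.set_index("habitat")["area"]
    missing = sorted(set(wa["habitat"]) - set(area_map.index))
    if missing:
        raise SchemaError(f"habitats in cover matrix without an area entry: {missing}")
    total_area = float(area_map.sum())
    if total_area <= 0:
        raise SchemaError("total habitat area must be positive")
    wah = wa.copy()
    wah["weight"] = wah["weight"] * wah["habitat"].map(area_map).to_numpy() / total_area
    if renormalize:
        row_sum = wah.groupby("species")["weight"].transform("sum")
        dead = row_sum <= 0
        if dead.any():
            bad = sorted(wah.loc[dead, "species"].unique())
            raise DegenerateSpeciesError(
                f"species whose occupied habitats all have zero area: {bad}"
            )
        wah["weight"] = wah["weight"] / row_sum
    return _finish(wah, "W-AH")


def weight_table(
    cover: pd.DataFrame,
    areas: pd.DataFrame | None = None,
    methods=METHODS,
    renormalize_wah: bool = True,
) -> pd.DataFrame:
    """Stack the requested weighting schemes into one long table.

    ``areas`` is only required when W-AH is among ``methods``.
    """
    builders = {
        "Unw": lambda: weights_unweighted(cover),
        "W-S": lambda: weights_split(cover),
        "W-A": lambda: weights_abundance(cover),
        "W-AH": lambda: _need_areas(cover, areas, renormalize_wah),
    }
    unknown = [m for m in methods if m not in builders]
    if unknown:
        raise ValueError(f"unknown weighting method(s) {unknown}; choose from {METHODS}")
    parts = [builders[m]() for m in methods]
    return pd.concat(parts, ignore_index=True)


def _need_areas(cover, areas, renormalize):
    if areas is None:
        raise ValueError("W-AH weighting requires a habitat area table")
    return weights_abundance_area(cover, areas, renormalize=renormalize)
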