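"""Weighted geometric statistics and the Distribution Index series."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from habindex.index import (
    distribution_index,
    weighted_geometric_mean,
    weighted_geometric_sd,
)


def brute_wgmean(values, weights):
    wsum = sum(weights)
    return math.exp(sum(w * math.log(x) for x, w in zip(values, weights)) / wsum)


def brute_wgsd(values, weights):
    wsum = sum(weights)
    m = sum(w * math.log(x) for x, w in zip(values, weights)) / wsum
    var = sum(w * (math.log(x) - m) ** 2 for x, w in zip(values, weights)) / wsum
    return math.exp(math.sqrt(var))


class TestWeightedGeometricMean:
    def test_equal_weights_two_values(self):
        assert weighted_geometric_mean([0.2, 0.8], [1, 1]) == pytest.approx(0.4)

    def test_constant_values(self):
        assert weighted_geometric_mean([0.3, 0.3, 0.3], [0.1, 5, 2]) == pytest.approx(0.3)

    def test_three_value_oracle(self):
        got = weighted_geometric_mean([0.1, 0.4, 0.9], [0.2, 0.3, 0.5])
        expected = math.exp(
            0.2 * math.log(0.1) + 0.3 * math.log(0.4) + 0.5 * math.log(0.9)
        )
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx(0.454715, abs=1e-5)

    def test_rejects_nonpositive_values_and_zero_weights(self):
        with pytest.raises(ValueError):
            weighted_geometric_mean([0.0, 0.5], [1, 1])
        with pytest.raises(ValueError):
            weighted_geometric_mean([0.2, 0.5], [0, 0])


class TestWeightedGeometricSD:
    def test_constant_values_give_one(self):
        assert weighted_geometric_sd([0.3, 0.3], [2, 1]) == pytest.approx(1.0)

    def test_symmetric_log_deviations(self):
        c = 0.2
        got = weighted_geometric_sd([c * math.e, c / math.e], [1, 1])
        assert got == pytest.approx(math.e, rel=1e-12)

    def test_single_weighted_value_rejected(self):
        with pytest.raises(ValueError):
            weighted_geometric_sd([0.3, 0.4], [1, 0])


@settings(max_examples=200, deadline=None)
@given(
    data=st.lists(
        st.tuples(
            st.floats(min_value=1e-4, max_value=1.0, allow_nan=False),
            st.floats(min_value=1e-6, max_value=10.0, allow_nan=False),
        ),
        min_size=2,
        max_size=8,
    )
)
def test_geometric_stats_match_brute_force(data):
    values = [v for v, _ in data]
    weights = [w for _, w in data]
    assert weighted_geometric_mean(values, weights) == pytest.approx(
        brute_wgmean(values, weights), abs=1e-10
    )
    assert weighted_geometric_sd(values, weights) == pytest.approx(
        brute_wgsd(values, weights), abs=1e-10
    )


def _weights_df(entries):
    return pd.DataFrame(entries, columns=["species", "habitat", "method", "weight"])


def _occ_df(entries):
    return pd.DataFrame(entries, columns=["species", "year", "occupancy"])


class TestDistributionIndex:
    def test_single_species_identity(self):
        w = _weights_df([("sp", "A", "Unw", 1.0)])
        occ = _occ_df([("sp", 2000, 0.3)])
        di = distribution_index(occ, w)
        assert di.loc[0, "di"] == pytest.approx(0.3)
        assert np.isnan(di.loc[0, "gsd"])

    def test_symmetric_habitats_identical_series(self):
        w = _weights_df(
            [("s1", h, "Unw", 1.0) for h in "AB"] + [("s2", h, "Unw", 1.0) for h in "AB"]
        )
        occ = _occ_df(
            [("s1", y, 0.2 + 0.01 * (y - 2000)) for y in range(2000, 2005)]
            + [("s2", y, 0.5) for y in range(2000, 2005)]
        )
        di = distribution_index(occ, w)
        a = di[di["habitat"] == "A"].reset_index(drop=True)
        b = di[di["habitat"] == "B"].reset_index(drop=True)
        assert np.allclose(a["di"], b["di"])
        assert np.allclose(a["gsd"], b["gsd"])

    def test_toy_set_matches_brute_force_per_cell(self):
        w = _weights_df(
            [
                ("s1", "A", "W-A", 0.7), ("s2", "A", "W-A", 0.2), ("s3", "A", "W-A", 0.1),
                ("s1", "B", "W-A", 0.3), ("s3", "B", "W-A", 0.9),
            ]
        )
        occ = _occ_df(
            [(s, y, v) for s, vals in {
                "s1": [0.2, 0.25, 0.3], "s2": [0.5, 0.45, 0.4], "s3": [0.1, 0.12, 0.11],
            }.items() for y, v in zip((2000, 2001, 2002), vals)]
        )
        di = distribution_index(occ, w).set_index(["habitat", "year"])
        occ_map = occ.set_index(["species", "year"])["occupancy"]
        for habitat, members in {"A": ["s1", "s2", "s3"], "B": ["s1", "s3"]}.items():
            ws = w.set_index(["species", "habitat"])["weight"]
            for year in (2000, 2001, 2002):
                values = [occ_map[s, year] for s in members]
                wts = [ws[s, habitat] for s in members]
                assert di.loc[(habitat, year), "di"] == pytest.approx(
                    brute_wgmean(values, wts), abs=1e-12
                )
                assert di.loc[(habitat, year), "gsd"] == pytest.approx(
                    brute_wgsd(values, wts), abs=1e-12
                )

    def test_weight_scale_invariance(self):
        w1 = _weights_df([("s1", "A", "m", 0.2), ("s2", "A", "m", 0.8)])
        w2 = w1.copy()
        w2["weight"] *= 37.5
        occ = _occ_df([("s1", 2000, 0.3), ("s2", 2000, 0.6)])
        a = distribution_index(occ, w1)
        b = distribution_index(occ, w2)
        assert a.loc[0, "di"] == pytest.approx(b.loc[0, "di"], rel=1e-12)
        assert a.loc[0, "gsd"] == pytest.approx(b.loc[0, "gsd"], rel=1e-12)

    def test_di_bounded_by_occupancy_range(self, small_study):
        from habindex.floristics import aggregate_to_habitat
        from habindex.weighting import weight_table

        cover = aggregate_to_habitat(
            small_study["floristics"], small_study["correspondence"]
        )
        w = weight_table(cover, areas=small_study["areas"])
        occ = small_study["occupancy"]
        di = distribution_index(occ, w)
        lo, hi = occ["occupancy"].min(), occ["occupancy"].max()
        assert (di["di"] >= lo - 1e-12).all() and (di["di"] <= hi + 1e-12).all()
        assert (di["gsd"].dropna() >= 1.0).all()
        assert np.allclose(di["coverage"], 1.0)

    def test_monotone_in_occupancy(self):
        w = _weights_df([("s1", "A", "m", 0.4), ("s2", "A", "m", 0.6)])
        occ1 = _occ_df([("s1", 2000, 0.3), ("s2", 2000, 0.6)])
        occ2 = _occ_df([("s1", 2000, 0.35), ("s2", 2000, 0.6)])
        assert (
            distribution_index(occ2, w).loc[0, "di"]
            > distribution_index(occ1, w).loc[0, "di"]
        )

    def test_missing_year_dropped_with_coverage(self):
        w = _weights_df([("s1", "A", "m", 0.25), ("s2", "A", "m", 0.75)])
        occ = _occ_df([("s1", 2000, 0.3), ("s2", 2000, 0.6), ("s2", 2001, 0.5)])
        di = distribution_index(occ, w).set_index("year")
        assert di.loc[2001, "di"] == pytest.approx(0.5)
        assert di.loc[2001, "coverage"] == pytest.approx(0.75)
        assert di.loc[2000, "coverage"] == pytest.approx(1.0)

    def test_species_absent_from_occupancy_raises(self):
        w = _weights_df([("ghost", "A", "m", 1.0)])
        occ = _occ_df([("sp", 2000, 0.3)])
        with pytest.raises(ValueError, match="ghost"):
            distribution_index(occ, w)

    def test_generalist_bias_direction(self):
        """A high-occupancy generalist shared between habitats lifts the
        unweighted index above the even-split index in any habitat that
        also holds a low-occupancy specialist."""
        w = _weights_df(
            [
                ("gen", "A", "Unw", 1.0), ("gen", "B", "Unw", 1.0),
                ("spec", "A", "Unw", 1.0),
                ("gen", "A", "W-S", 0.5), ("gen", "B", "W-S", 0.5),
                ("spec", "A", "W-S", 1.0),
            ]
        )
        occ = _occ_df([("gen", 2000, 0.6), ("spec", 2000, 0.1)])
        di = distribution_index(occ, w).set_index(["habitat", "method"])
        assert di.loc[("A", "Unw"), "di"] > di.loc[("A", "W-S"), "di"]
        # analytic check: exp of weighted log means
        unw = math.exp((math.log(0.6) + math.log(0.1)) / 2)
        ws = math.exp((0.5 * math.log(0.6) + math.log(0.1)) / 1.5)
        assert di.loc[("A", "Unw"), "di"] == pytest.approx(unw, rel=1e-12)
        assert di.loc[("A", "W-S"), "di"] == pytest.approx(ws, rel=1e-12)
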