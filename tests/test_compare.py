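"""Mixed-model and WLS comparisons of the weighting schemes."""

import numpy as np
import pandas as pd
import pytest

from habindex.compare import (
    compare_di,
    compare_trends,
    significance_summary,
    stack_trend_design,
)


def _index_frame(methods, habitats, years, di_fn):
    rows = [
        (h, m, y, di_fn(h, m, y), 1.1, 1.0, 5)
        for h in habitats
        for m in methods
        for y in years
    ]
    return pd.DataFrame(
        rows, columns=["habitat", "method", "year", "di", "gsd", "coverage", "n_species"]
    )


class TestCompareDI:
    def test_identical_series_zero_contrast(self):
        rng = np.random.default_rng(1)
        base = {
            (h, y): rng.uniform(0.2, 0.4) for h in "ABC" for y in range(2000, 2010)
        }
        idx = _index_frame(
            ["Unw", "W-S"], "ABC", range(2000, 2010), lambda h, m, y: base[h, y]
        )
        res = compare_di(idx)["overall"].set_index("term")
        assert res.loc["W-S", "estimate"] == pytest.approx(0.0, abs=1e-10)

    def test_constant_shift_recovered(self):
        rng = np.random.default_rng(2)
        base = {
            (h, y): rng.uniform(0.25, 0.45) for h in "ABCD" for y in range(2000, 2012)
        }
        idx = _index_frame(
            ["Unw", "W-S"],
            "ABCD",
            range(2000, 2012),
            lambda h, m, y: base[h, y] - (0.05 if m == "W-S" else 0.0),
        )
        res = compare_di(idx)["overall"].set_index("term")
        assert res.loc["W-S", "estimate"] == pytest.approx(-0.05, abs=1e-8)
        assert res.loc["W-S", "p"] < 1e-6

    def test_balanced_design_equals_cell_mean_differences(self):
        """On a balanced design the fixed method effects equal the mean
        of per-(habitat, year) differences from the reference method."""
        rng = np.random.default_rng(3)
        base = {
            (h, y): rng.uniform(0.2, 0.5) for h in "ABC" for y in range(2000, 2008)
        }
        shift = {"Unw": 0.0, "W-S": -0.03, "W-A": -0.05}
        noise = {
            (h, m, y): rng.normal(0, 0.002)
            for h in "ABC"
            for m in shift
            for y in range(2000, 2008)
        }
        idx = _index_frame(
            list(shift), "ABC", range(2000, 2008),
            lambda h, m, y: base[h, y] + shift[m] + noise[h, m, y],
        )
        res = compare_di(idx)["overall"].set_index("term")
        pivot = idx.pivot_table(index=["habitat", "year"], columns="method", values="di")
        for m in ("W-S", "W-A"):
            expected = (pivot[m] - pivot["Unw"]).mean()
            assert res.loc[m, "estimate"] == pytest.approx(expected, abs=1e-6)

    def test_reference_level_is_unweighted(self):
        idx = _index_frame(
            ["Unw", "W-S"], "AB", range(2000, 2006), lambda h, m, y: 0.3
        )
        res = compare_di(idx)["overall"]
        assert res["term"].iloc[0] == "Intercept (Unw)"
        assert set(res["term"]) == {"Intercept (Unw)", "W-S"}

    def test_per_habitat_tables_cover_all_habitats(self):
        rng = np.random.default_rng(4)
        idx = _index_frame(
            ["Unw", "W-S"], "ABC", range(2000, 2008),
            lambda h, m, y: rng.uniform(0.2, 0.4),
        )
        per = compare_di(idx)["per_habitat"]
        assert set(per["habitat"]) == set("ABC")

    def test_single_method_rejected(self):
        idx = _index_frame(["Unw"], "AB", range(2000, 2005), lambda h, m, y: 0.3)
        with pytest.raises(ValueError):
            compare_di(idx)


def _trend_weight_tables(trends_map, weights_map):
    trends = pd.DataFrame(
        [(s, "long", 2000, 2015, t) for s, t in trends_map.items()],
        columns=["species", "period", "start_year", "end_year", "trend"],
    )
    weights = pd.DataFrame(
        [(s, h, m, w) for (s, h, m), w in weights_map.items()],
        columns=["species", "habitat", "method", "weight"],
    )
    return trends, weights


class TestCompareTrends:
    def test_marginal_mean_equals_weighted_cell_mean(self):
        rng = np.random.default_rng(5)
        species = [f"s{i}" for i in range(12)]
        trends_map = {s: rng.normal(0.01, 0.02) for s in species}
        weights_map = {}
        for s in species:
            for h in "AB":
                for m in ("Unw", "W-S"):
                    weights_map[(s, h, m)] = rng.uniform(0.1, 1.0)
        trends, weights = _trend_weight_tables(trends_map, weights_map)
        res = compare_trends(trends, weights, period="long")
        emm = res["emmeans"].set_index(["habitat", "method"])
        for h in "AB":
            for m in ("Unw", "W-S"):
                num = sum(weights_map[(s, h, m)] * trends_map[s] for s in species)
                den = sum(weights_map[(s, h, m)] for s in species)
                assert emm.loc[(h, m), "mean"] == pytest.approx(num / den, abs=1e-8)

    def test_weight_scaling_invariance(self):
        rng = np.random.default_rng(6)
        species = [f"s{i}" for i in range(8)]
        trends_map = {s: rng.normal(0.0, 0.02) for s in species}
        weights_map = {
            (s, h, m): rng.uniform(0.2, 1.0)
            for s in species for h in "AB" for m in ("Unw", "W-S")
        }
        scaled = {
            k: (w * 2.0 if k[2] == "W-S" else w) for k, w in weights_map.items()
        }
        trends, w1 = _trend_weight_tables(trends_map, weights_map)
        _, w2 = _trend_weight_tables(trends_map, scaled)
        r1 = compare_trends(trends, w1, period="long")
        r2 = compare_trends(trends, w2, period="long")
        assert np.allclose(r1["emmeans"]["mean"], r2["emmeans"]["mean"], atol=1e-10)

    def test_identical_trends_identical_marginal_means(self):
        species = [f"s{i}" for i in range(6)]
        trends_map = {s: 0.015 for s in species}
        rng = np.random.default_rng(7)
        weights_map = {
            (s, h, m): rng.uniform(0.2, 1.0)
            for s in species for h in "AB" for m in ("Unw", "W-S")
        }
        trends, weights = _trend_weight_tables(trends_map, weights_map)
        res = compare_trends(trends, weights, period="long")
        # identical trends leave nothing for habitat, method or their
        # interaction to explain: every marginal mean is the common value
        assert np.allclose(res["emmeans"]["mean"], 0.015, atol=1e-12)
        assert np.ptp(res["emmeans"]["mean"]) < 1e-12

    def test_unbalanced_design_warns(self, caplog):
        trends, weights = _trend_weight_tables(
            {"s1": 0.01, "s2": -0.01},
            {("s1", "A", "Unw"): 1.0, ("s1", "A", "W-S"): 1.0,
             ("s2", "B", "Unw"): 1.0},
        )
        with caplog.at_level("WARNING", logger="habindex.compare"):
            stack_trend_design(trends, weights, "long")
        assert "unbalanced" in caplog.text

    def test_anova_terms_present(self):
        rng = np.random.default_rng(8)
        species = [f"s{i}" for i in range(10)]
        trends_map = {s: rng.normal(0, 0.02) for s in species}
        weights_map = {
            (s, h, m): rng.uniform(0.2, 1.0)
            for s in species for h in "ABC" for m in ("Unw", "W-S")
        }
        trends, weights = _trend_weight_tables(trends_map, weights_map)
        res = compare_trends(trends, weights, period="long")
        assert list(res["anova"]["term"]) == ["habitat", "method", "interaction", "residual"]
        p = res["anova"]["p"].iloc[:3]
        assert ((p >= 0) & (p <= 1)).all()


class TestSignificanceSummary:
    @pytest.mark.parametrize(
        "mean,lo,hi,expected",
        [
            (0.05, 0.01, 0.09, "positive"),
            (0.05, -0.01, 0.11, "indistinguishable"),
            (-0.03, -0.05, -0.01, "negative"),
        ],
    )
    def test_ci_classification(self, mean, lo, hi, expected):
        emm = pd.DataFrame(
            {"habitat": ["A"], "method": ["Unw"], "mean": [mean],
             "se": [0.01], "ci_low": [lo], "ci_high": [hi]}
        )
        assert significance_summary(emm)["direction"].iloc[0] == expected
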