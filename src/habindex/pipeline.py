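"""End-to-end pipeline: inputs -> covers -> weights -> index -> trends -> comparison.

A run is described by a :class:`PipelineConfig`, read from YAML or built
in code: either the four input CSVs (floristics, correspondence, areas,
occupancy) or a ``synth`` block generating them.  ``run_pipeline``
executes every stage in order, writes all output tables plus a
run-manifest (config echo, seed, package versions, warning counts) and
is byte-identical under a fixed seed and config.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, compare, floristics, index, io, synth, trends, weighting

__all__ = ["PipelineConfig", "run_pipeline", "demo_study", "DEMO_SYNTH"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything needed for one pipeline run.

    Exactly one of ``inputs`` (paths to the four CSVs) or ``synth``
    (a :class:`~habindex.synth.SynthConfig`) must be provided.
    """

    inputs: dict | None = None  # keys: floristics, correspondence, areas, occupancy
    synth: synth.SynthConfig | None = None
    methods: tuple = weighting.METHODS
    renormalize_wah: bool = True
    zero_pad_communities: bool = False
    short_start: int = 2005
    trend_end: int | None = 2015
    trend_metric: str = "annual"
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synth is None):
            raise ValueError("provide exactly one of input paths or a synth block")
        if self.inputs is not None:
            required = {"floristics", "correspondence", "areas", "occupancy"}
            missing = required - set(self.inputs)
            if missing:
                raise ValueError(f"input paths missing: {sorted(missing)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        syn = raw.pop("synth", None)
        if syn is not None:
            seed = raw.get("seed", 0)
            syn.setdefault("seed", seed)
            syn = synth.SynthConfig(**syn)
        known = {
            k: raw[k]
            for k in (
                "inputs",
                "methods",
                "renormalize_wah",
                "zero_pad_communities",
                "short_start",
                "trend_end",
                "trend_metric",
                "seed",
            )
            if k in raw
        }
        if "methods" in known:
            known["methods"] = tuple(known["methods"])
        return cls(synth=syn, **known)

    def echo(self) -> dict:
        d = {
            "methods": list(self.methods),
            "renormalize_wah": self.renormalize_wah,
            "zero_pad_communities": self.zero_pad_communities,
            "short_start": self.short_start,
            "trend_end": self.trend_end,
            "trend_metric": self.trend_metric,
            "seed": self.seed,
        }
        if self.inputs is not None:
            d["inputs"] = {k: str(v) for k, v in self.inputs.items()}
        if self.synth is not None:
            d["synth"] = self.synth.to_dict()
        return d


def _load_inputs(config: PipelineConfig) -> dict[str, pd.DataFrame]:
    if config.synth is not None:
        return synth.generate_study(config.synth)
    paths = config.inputs
    return {
        "floristics": io.read_floristic_table(paths["floristics"]),
        "correspondence": io.read_correspondence(paths["correspondence"]),
        "areas": io.read_areas(paths["areas"]),
        "occupancy": io.read_occupancy(paths["occupancy"]),
    }


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run every stage and write the output bundle to ``outdir``.

    Returns a dict of the in-memory tables keyed by output name; the
    same tables are written as CSV, together with ``manifest.json``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    data = _load_inputs(config)

    if config.synth is not None:
        io.write_table(data["floristics"], outdir / "floristics.csv")
        io.write_table(data["correspondence"], outdir / "correspondence.csv")
        io.write_table(data["areas"], outdir / "areas.csv")
        io.write_table(data["occupancy"], outdir / "occupancy.csv")
        io.write_table(data["ground_truth"], outdir / "ground_truth.csv")

    covers = floristics.aggregate_to_habitat(
        data["floristics"],
        data["correspondence"],
        zero_pad_communities=config.zero_pad_communities,
    )
    io.write_covers(covers, outdir / "covers.csv")

    weights = weighting.weight_table(
        covers,
        areas=data["areas"],
        methods=config.methods,
        renormalize_wah=config.renormalize_wah,
    )
    io.write_weights(weights, outdir / "weights.csv")

    occupancy = data["occupancy"]
    di = index.distribution_index(occupancy, weights)
    io.write_index_series(di, outdir / "index.csv")

    trend_tab = trends.trend_table(
        occupancy,
        short_start=config.short_start,
        end=config.trend_end,
        metric=config.trend_metric,
    )
    io.write_trends(trend_tab, outdir / "trends.csv")

    results: dict = {
        "covers": covers,
        "weights": weights,
        "index": di,
        "trends": trend_tab,
    }

    comparison_frames = []
    if len(config.methods) >= 2:
        di_cmp = compare.compare_di(di)
        comparison_frames.append(di_cmp["overall"])
        results["di_comparison"] = di_cmp
        per_hab = di_cmp["per_habitat"]
        if len(per_hab):
            io.write_table(per_hab, outdir / "di_per_habitat.csv")
        emmeans_frames = []
        for period in sorted(trend_tab["period"].unique()):
            tc = compare.compare_trends(trend_tab, weights, period=period)
            results[f"trend_comparison_{period}"] = tc
            comparison_frames.append(tc["anova"].assign(term=lambda d: period + ":" + d["term"]))
            emm = compare.significance_summary(tc["emmeans"]).assign(period=period)
            emmeans_frames.append(emm)
        emmeans = pd.concat(emmeans_frames, ignore_index=True)
        io.write_table(emmeans, outdir / "emmeans.csv")
        results["emmeans"] = emmeans
        comparison = pd.concat(comparison_frames, ignore_index=True)
        io.write_comparison(
            comparison.reindex(columns=io.COMPARISON_COLUMNS), outdir / "comparison.csv"
        )
        results["comparison"] = comparison

    manifest = {
        "package": "habindex",
        "version": __version__,
        "seed": config.seed,
        "config": config.echo(),
        "outputs": sorted(p.name for p in outdir.glob("*.csv")),
        "versions": _versions(),
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def _versions() -> dict:
    import numpy, scipy, statsmodels

    return {
        "numpy": numpy.__version__,
        "pandas": pd.__version__,
        "scipy": scipy.__version__,
        "statsmodels": statsmodels.__version__,
    }


#: The packaged demonstration scenario: rising, widespread, high-occupancy
#: generalists against declining habitat specialists, with habitat areas
#: spanning 2.5 decades — the configuration under which unweighted
#: aggregation overstates how well each habitat's flora is doing.
DEMO_SYNTH = dict(
    n_habitats=10,
    n_communities_per_habitat=4,
    n_specialists_per_habitat=3,
    n_generalists=40,
    generalist_breadth=3,
    first_year=1970,
    last_year=2016,
    specialist_trend=-0.01,
    generalist_trend=0.03,
    occupancy_baseline=0.15,
    generalist_baseline=0.35,
    trend_sd=0.005,
    noise_sd=0.1,
)


def demo_study(seed: int, outdir) -> dict:
    """Run the packaged demonstration study and render a short report.

    Generates the scenario in :data:`DEMO_SYNTH`, runs the full
    pipeline, and checks the headline qualitative pattern: every
    weighted scheme's Distribution Index sits below the unweighted one,
    and weighting strips at least one habitat's positive trend of its
    significance.  The findings (and whether each check held) are
    written to ``report.md`` in ``outdir``.
    """
    cfg = PipelineConfig(
        synth=synth.SynthConfig(seed=seed, **DEMO_SYNTH), seed=seed
    )
    results = run_pipeline(cfg, outdir)

    overall = results["di_comparison"]["overall"]
    contrasts = overall[overall["term"] != "Intercept (Unw)"]
    all_negative = bool((contrasts["estimate"] < 0).all())

    emm = results["emmeans"]
    flipped = []
    for (habitat, period), grp in emm.groupby(["habitat", "period"]):
        g = grp.set_index("method")["direction"]
        if (
            "Unw" in g.index
            and "W-AH" in g.index
            and g["Unw"] == "positive"
            and g["W-AH"] == "indistinguishable"
        ):
            flipped.append((habitat, period))

    report = [
        "# Demonstration study: specialist decline masked by generalists",
        "",
        f"Seed: {seed}. Scenario: {DEMO_SYNTH['n_habitats']} habitats, "
        f"{DEMO_SYNTH['n_specialists_per_habitat']} declining specialists per "
        f"habitat, {DEMO_SYNTH['n_generalists']} rising generalists spread over "
        f"{DEMO_SYNTH['generalist_breadth']} habitats each.",
        "",
        "## Method contrasts vs the unweighted index (mixed model)",
        "",
        overall.to_string(index=False),
        "",
        f"All weighted-method contrasts negative: **{all_negative}**",
        "",
        "## Habitat trends losing significance under W-AH",
        "",
        (
            "\n".join(f"- habitat {h} ({p}-term)" for h, p in flipped)
            if flipped
            else "- none in this draw"
        ),
        "",
    ]
    outdir = Path(outdir)
    (outdir / "report.md").write_text("\n".join(report))
    results["all_contrasts_negative"] = all_negative
    results["flipped_habitats"] = flipped
    return results
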