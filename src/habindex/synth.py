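"""Synthetic floristic tables, habitat areas and occupancy series.

The generator emulates the four inputs of the habitat-allocation
pipeline with known ground truth, so every downstream stage can be
tested without the survey data it normally consumes:

* a floristic table with controllable specialist/generalist structure —
  specialists occur only in communities of one home habitat, generalists
  in communities of several, with frequency class and Domin score drawn
  independently per community (so abundance-based weights are
  non-uniform by construction);
* a community -> habitat correspondence implied by that structure;
* habitat areas either given explicitly or log-spaced over a configured
  number of decades, mimicking real habitat extents that span orders of
  magnitude;
* annual occupancy following a per-species log-linear (logit-scale)
  trend plus Gaussian noise on the logit scale, which keeps every score
  inside (0, 1):

      occupancy(s, t) = expit( logit(b_s) + m_s (t - t0) + e_t ),
      e_t ~ N(0, noise_sd^2),

  with baseline b_s and slope m_s set by whether the species is a
  specialist or a generalist (plus optional per-species slope jitter).

Ground truth (species class, habitats, baseline, realised slope) is
always returned alongside the data, enabling parameter-recovery tests.
One global seed feeds a named sub-stream per operation, so changing one
stage's draw count cannot silently shift another's.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .io import (
    AREAS_COLUMNS,
    CORRESPONDENCE_COLUMNS,
    FLORISTICS_COLUMNS,
    FREQUENCY_CLASSES,
    OCCUPANCY_COLUMNS,
)

__all__ = [
    "SynthConfig",
    "generate_floristics",
    "generate_areas",
    "generate_occupancy",
    "generate_study",
    "true_occupancy",
    "true_annual_trend",
]

# Fixed index per named sub-stream; a stream's draws never depend on
# how many draws another stream made.
_STREAMS = {"floristics": 0, "areas": 1, "occupancy": 2}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STREAMS[stream]])


@dataclass
class SynthConfig:
    """Parameters of a synthetic study.

    Defaults describe a scaled-down terricolous-cryptogam-style study:
    ten coarse habitats, a handful of vegetation communities each,
    specialists confined to one habitat with modest declines, a pool of
    three-habitat generalists with higher baseline occupancy and rising
    trends, habitat areas log-spread over 2.5 decades, and annual
    occupancy from 1970 to 2016 with logit-scale noise.
    """

    n_habitats: int = 10
    n_communities_per_habitat: int = 4
    n_specialists_per_habitat: int = 3
    n_generalists: int = 20
    generalist_breadth: int = 3
    first_year: int = 1970
    last_year: int = 2016
    #: per-year log-odds slope of specialist / generalist occupancy
    specialist_trend: float = -0.02
    generalist_trend: float = 0.03
    #: baseline (first-year, noise-free) occupancy of specialists
    occupancy_baseline: float = 0.15
    #: baseline for generalists; None -> same as occupancy_baseline
    generalist_baseline: float | None = 0.35
    #: SD of per-species jitter added to the class slope (logit/yr)
    trend_sd: float = 0.01
    #: SD of year-to-year noise on the logit scale
    noise_sd: float = 0.1
    #: probability a species occurs in each community of an occupied habitat
    community_occupancy_p: float = 0.7
    #: categorical distribution of frequency classes I..V
    freq_probs: tuple = (0.30, 0.25, 0.20, 0.15, 0.10)
    #: categorical distribution of Domin scores 1..10
    domin_probs: tuple = (
        0.05, 0.10, 0.15, 0.15, 0.15, 0.12, 0.10, 0.08, 0.06, 0.04,
    )
    #: explicit areas per habitat (sequence, habitat order) or None
    areas: tuple | None = None
    #: decades between the largest and smallest habitat area
    area_log_spread: float = 2.5
    #: sum of all habitat areas (ha); default is of country scale
    total_area: float = 7.8e6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.last_year <= self.first_year:
            raise ValueError("last_year must exceed first_year")
        if self.generalist_breadth > self.n_habitats:
            raise ValueError("generalist_breadth cannot exceed n_habitats")
        if self.generalist_breadth < 2 and self.n_generalists > 0:
            raise ValueError("generalist_breadth must be >= 2")
        for name in ("occupancy_baseline", "generalist_baseline"):
            v = getattr(self, name)
            if v is not None and not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        if self.noise_sd < 0 or self.trend_sd < 0:
            raise ValueError("noise_sd and trend_sd must be nonnegative")
        if not np.isclose(sum(self.freq_probs), 1.0) or len(self.freq_probs) != 5:
            raise ValueError("freq_probs must be 5 probabilities summing to 1")
        if not np.isclose(sum(self.domin_probs), 1.0) or len(self.domin_probs) != 10:
            raise ValueError("domin_probs must be 10 probabilities summing to 1")

    @property
    def habitats(self) -> list[str]:
        """Habitat codes A, B, C, ... (coarse-typology style)."""
        if self.n_habitats > 26:
            return [f"H{i:02d}" for i in range(self.n_habitats)]
        return [chr(ord("A") + i) for i in range(self.n_habitats)]

    def communities(self, habitat: str) -> list[str]:
        return [
            f"NVC_{habitat}{j + 1}" for j in range(self.n_communities_per_habitat)
        ]

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.last_year + 1)

    def to_dict(self) -> dict:
        return asdict(self)


def generate_floristics(
    config: SynthConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Floristic table, correspondence table and ground-truth species map.

    Each specialist appears only in communities of its home habitat;
    each generalist in communities of exactly ``generalist_breadth``
    habitats.  Within each occupied habitat a species appears in each
    community with probability ``community_occupancy_p`` (forced into
    one random community if the coin flips all fail), with frequency
    class and Domin score drawn independently per community.

    Returns ``(floristics, correspondence, species_map)``; the species
    map has columns species, group (specialist/generalist), habitats
    (';'-joined), baseline, slope — baseline and slope being the
    ground-truth occupancy dynamics later consumed by
    :func:`generate_occupancy`.
    """
    rng = _rng(config.seed, "floristics")
    habitats = config.habitats

    correspondence = pd.DataFrame(
        [(c, h) for h in habitats for c in config.communities(h)],
        columns=CORRESPONDENCE_COLUMNS,
    )

    species: list[tuple[str, str, list[str]]] = []  # (name, group, habitats)
    for h in habitats:
        for i in range(config.n_specialists_per_habitat):
            species.append((f"spec_{h}{i + 1}", "specialist", [h]))
    for i in range(config.n_generalists):
        occupied = sorted(
            rng.choice(habitats, size=config.generalist_breadth, replace=False)
        )
        species.append((f"gen_{i + 1:02d}", "generalist", occupied))

    rows = []
    for name, _group, occ_habitats in species:
        for h in occ_habitats:
            comms = config.communities(h)
            present = rng.random(len(comms)) < config.community_occupancy_p
            if not present.any():
                present[rng.integers(len(comms))] = True
            for comm, here in zip(comms, present):
                if not here:
                    continue
                fc = FREQUENCY_CLASSES[rng.choice(5, p=config.freq_probs)]
                domin = int(rng.choice(10, p=config.domin_probs)) + 1
                rows.append((comm, name, fc, domin))
    floristics = pd.DataFrame(rows, columns=FLORISTICS_COLUMNS)

    base_spec = config.occupancy_baseline
    base_gen = (
        config.generalist_baseline
        if config.generalist_baseline is not None
        else config.occupancy_baseline
    )
    gt_rows = []
    for name, group, occ_habitats in species:
        mean_slope = (
            config.specialist_trend if group == "specialist" else config.generalist_trend
        )
        slope = mean_slope + (
            rng.normal(0.0, config.trend_sd) if config.trend_sd > 0 else 0.0
        )
        baseline = base_spec if group == "specialist" else base_gen
        gt_rows.append((name, group, ";".join(occ_habitats), baseline, slope))
    species_map = pd.DataFrame(
        gt_rows, columns=["species", "group", "habitats", "baseline", "slope"]
    )
    return floristics, correspondence, species_map


def generate_areas(config: SynthConfig) -> pd.DataFrame:
    """Habitat area table.

    Explicit ``config.areas`` are used verbatim (in habitat order);
    otherwise areas are log-spaced over ``area_log_spread`` decades from
    largest (first habitat) to smallest (last), rescaled to sum to
    ``total_area``.  With spread 0 all areas are equal.
    """
    habitats = config.habitats
    if config.areas is not None:
        if len(config.areas) != config.n_habitats:
            raise ValueError("explicit areas must list one value per habitat")
        values = np.asarray(config.areas, dtype=float)
    else:
        if config.n_habitats == 1:
            raw = np.ones(1)
        else:
            raw = np.logspace(0.0, -config.area_log_spread, config.n_habitats)
        values = raw / raw.sum() * config.total_area
    return pd.DataFrame({"habitat": habitats, "area": values})[AREAS_COLUMNS]


def true_occupancy(
    baseline: float, slope: float, years: np.ndarray, first_year: int
) -> np.ndarray:
    """Noise-free occupancy path: expit(logit(baseline) + slope * (t - t0))."""
    return expit(logit(baseline) + slope * (np.asarray(years) - first_year))


def generate_occupancy(
    config: SynthConfig, species_map: pd.DataFrame
) -> pd.DataFrame:
    """Annual occupancy series for every species in the ground-truth map.

    Values are clipped to [1e-6, 1 - 1e-6] so downstream geometric means
    are always defined.
    """
    rng = _rng(config.seed, "occupancy")
    years = config.years
    frames = []
    for row in species_map.itertuples(index=False):
        path = true_occupancy(row.baseline, row.slope, years, config.first_year)
        if config.noise_sd > 0:
            eps = rng.normal(0.0, config.noise_sd, size=len(years))
            path = expit(logit(path) + eps)
        else:
            # keep the stream aligned whether or not noise is drawn
            rng.normal(0.0, 1.0, size=len(years))
        path = np.clip(path, 1e-6, 1.0 - 1e-6)
        frames.append(
            pd.DataFrame(
                {"species": row.species, "year": years, "occupancy": path}
            )
        )
    out = pd.concat(frames, ignore_index=True)[OCCUPANCY_COLUMNS]
    return out.sort_values(["species", "year"], kind="stable").reset_index(drop=True)


def true_annual_trend(
    baseline: float,
    slope: float,
    start_year: int,
    penultimate_year: int,
    first_year: int,
    metric: str = "annual",
) -> float:
    """Ground-truth proportional trend between two years of the noise-free path.

    Matches the trend metric used downstream: the annualised (default)
    or total proportional change between occupancy at ``start_year`` and
    at ``penultimate_year``.
    """
    v0, v1 = true_occupancy(
        baseline, slope, np.array([start_year, penultimate_year]), first_year
    )
    span = penultimate_year - start_year
    if metric == "annual":
        return float((v1 / v0) ** (1.0 / span) - 1.0)
    if metric == "total":
        return float(v1 / v0 - 1.0)
    raise ValueError(f"unknown trend metric {metric!r}")


def generate_study(config: SynthConfig) -> dict[str, pd.DataFrame]:
    """Generate the full input bundle for one synthetic study.

    Returns a dict with keys ``floristics``, ``correspondence``,
    ``areas``, ``occupancy`` and ``ground_truth``.  Bit-identical for a
    given config (including its seed).
    """
    floristics, correspondence, species_map = generate_floristics(config)
    areas = generate_areas(config)
    occupancy = generate_occupancy(config, species_map)
    return {
        "floristics": floristics,
        "correspondence": correspondence,
        "areas": areas,
        "occupancy": occupancy,
        "ground_truth": species_map,
    }
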