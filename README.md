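# habindex

Habitat-level biodiversity trend metrics are often built by pooling the
trends of the species associated with each habitat. When a generalist
species is counted in full in every habitat it occupies, while a
specialist counts only once, the pooled metric is dominated by
generalist dynamics — and since generalists tend to fare better than
specialists, unweighted habitat indicators can paint a misleadingly rosy
picture of how each habitat's flora is doing.

`habindex` implements and compares four ways of allocating species
occupancy trends to habitats, for the kind of data available for
terricolous bryophytes and lichens: vegetation-survey floristic tables
(frequency class + Domin cover score per species per community), a
community→habitat correspondence, habitat areas, and modelled annual
occupancy scores per species.

## The model

For species *s* in habitat *h*, an approximate cover is built from the
floristic tables:

    cover(s, community) = frequency midpoint × Domin^2.6 / 400

(frequency classes I–V map to band midpoints 0.10 … 0.90; the Currall
relation converts the ten-point Domin cover-abundance score to percent
cover, Domin^2.6 / 4). Per-habitat cover is the mean over the habitat's
communities in which the species occurs. Four weight matrices follow:

| scheme | weight w(s, h) | species row sum |
|--------|----------------|-----------------|
| Unw    | 1 wherever cover > 0 | number of habitats |
| W-S    | 1 / (habitats occupied) | 1 |
| W-A    | cover(s,h) / Σ_h cover(s,h) | 1 |
| W-AH   | W-A × area(h)/Σ area, renormalised | 1 |

The habitat's **Distribution Index** in year *t* is the weighted
geometric mean of its species' occupancy scores x_s(t),

    DI_h(t) = exp( Σ_s w(s,h) ln x_s(t) / Σ_s w(s,h) ),

with a weighted geometric standard deviation as the multiplicative
spread. Per-species long- and short-term trends are annualised rates of
change of a GCV-penalised smoothing-spline fit of each series,
(v_pen / v_start)^(1/Δt) − 1, taken between the assessment window's
first year and the penultimate year of the series. Weighting methods
are then compared with a linear mixed model on the index
(DI ~ method, random intercepts for habitat and year-within-habitat)
and a weighted linear model on the trends
(trend ~ habitat × method, each scheme's own weights) with estimated
marginal means and 95% CIs per habitat × method.

A synthetic-data generator with known ground truth (specialist /
generalist composition, logit-linear occupancy dynamics, log-spread
habitat areas) stands in for the survey data and makes every stage
testable.

## Worked example

Run the packaged demonstration study — 30 declining habitat specialists
(baseline occupancy 0.15, −0.01 logit/yr) against 40 rising three-habitat
generalists (baseline 0.35, +0.03 logit/yr) across ten habitats whose
areas span 2.5 orders of magnitude:

```sh
habindex demo --seed 0 --out demo_out
```

The mixed model on the Distribution Index prints:

```
   model            term  estimate     se   df     stat   p
di_mixed Intercept (Unw)    0.3784 0.0085 1876  44.7337 0.0
di_mixed             W-S   -0.1065 0.0028 1876 -37.6566 0.0
di_mixed             W-A   -0.1073 0.0028 1876 -37.9564 0.0
di_mixed            W-AH   -0.1184 0.0028 1876 -41.8923 0.0
```

Every weighted scheme sits significantly below the unweighted index:
letting generalists count in full in each habitat inflates the index by
about 0.11 on an intercept of 0.38. The marginal mean trends show the
second effect — for the smallest habitat (J), the unweighted long-term
trend looks robustly positive, but under abundance-and-area weighting
the generalists' mass moves to the large habitats where their
populations actually sit, and the trend becomes indistinguishable from
zero:

```
habitat method    mean     se  ci_low  ci_high         direction
      J    Unw  0.0106 0.0020  0.0066   0.0146          positive
      J   W-AH -0.0052 0.0046 -0.0142   0.0038 indistinguishable
```

The same pipeline runs on real inputs via
`habindex run --config config.yaml --out OUT` with paths to the four
CSVs (see `habindex --help` for the stage-wise subcommands
`simulate`, `covers`, `weights`, `index`, `trends`, `compare`, `plot`).

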