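# pyrotraits

Wildfire reshapes soil bacterial communities, but taxonomy alone cannot say
*which* bacteria survive the heat of a fire, *which* bloom in its aftermath,
and *which* simply prefer the altered post-fire soil.  `pyrotraits`
implements an experimentally anchored pipeline that assigns these three
life-history strategies to individual 16S rRNA amplicon variants (ASVs)
from paired burned/unburned soil-core experiments, quantifies how prevalent
each strategy is across a field burn-severity gradient, and fits two-pool
kinetics to soil CO₂ efflux to ask whether the post-fire community
constrains carbon mineralization.  It is aimed at soil microbial ecologists
and fire/biogeochemistry researchers working with amplicon count tables and
incubation flux data.

## The methods at its core

**Trait assignment.**  For each ASV, the change in relative abundance
between two experimental arms is modelled as a beta-binomial regression
with a logit mean link and a single overdispersion parameter φ ∈ (0, 1),

&nbsp;&nbsp;&nbsp;&nbsp;Wᵢ ~ BetaBinomial(nᵢ, μᵢ, φ),&nbsp;&nbsp;
logit(μᵢ) = β₀ + β_g·groupᵢ + β_pH·pHᵢ,

fit by maximum likelihood and summarized as the log₂ fold change
log₂[μ(group 1)/μ(group 0)] at mean covariates.  Three contrasts define the
traits — **fire survivors** (burned vs unburned, 24 h post-burn, restricted
to taxa whose 16S rRNA:rRNA-gene ratio is ≥ 1, i.e. demonstrably alive),
**fast growers** (burned cores at 5 weeks vs 24 h), and **post-fire
environment affinity** (burned vs unburned after autoclaving, re-inoculation
and a 6-month incubation).  Only cores whose thermocouples exceeded 50 °C
(and their site controls) enter any contrast; calls require
Benjamini–Hochberg q < 0.05 and a positive fold change, and an effect-size
filter drops responses more than one standard deviation below the mean of
the significant responders.  Organic and mineral horizons are analysed
separately and unioned.

**Carbon kinetics.**  Cumulative mineralization per gram initial C follows
the two-pool exponential decay model

&nbsp;&nbsp;&nbsp;&nbsp;M(t) = M₁·e^(−k₁t) + M₂·e^(−k₂t),&nbsp;&nbsp;
M₁ + M₂ = 1, k₁ ≥ k₂,

fit per sample by nonlinear least squares on the cumulative curve, with
coefficients compared across burn treatments by site-paired Wilcoxon
signed-rank tests.

**Field projection.**  Lab and field ASVs are merged by exact sequence
identity; per field sample the pipeline reports total, rRNA-copy-number-
normalized and qPCR-scaled absolute abundances of each trait group,
regresses them on the burn severity index with a years-post-fire
interaction (dropped when p ≥ 0.05), and computes each burned sample's mean
Bray–Curtis dissimilarity to unburned sites matched by vegetation, horizon
and year.

A fully seeded synthetic-data generator (`pyrotraits.simulate`) reproduces
the statistical structure of the study — Dirichlet-multinomial communities
with known spiked trait taxa, paired DNA/RNA libraries, relic-DNA decoys,
treatment-dependent flux curves and a severity gradient with year-specific
slopes — so the whole pipeline is testable against ground truth without any
sequence download.

## Worked example

```bash
python examples/02_trait_calling.py
```

prints, for the default synthetic conditions (19 sites, seed 1):

```
survivor           organic  tested=196 significant=12 kept= 7
survivor           mineral  tested=194 significant=10 kept= 7
fast_grower        organic  tested=194 significant= 9 kept= 9
fast_grower        mineral  tested=192 significant=10 kept= 8
postfire_affinity  organic  tested=197 significant= 7 kept= 6
postfire_affinity  mineral  tested=198 significant= 3 kept= 3

catalogue: 26 taxa
survivor: called 8, truly spiked 8, recovered 8 (sensitivity 1.00, precision 1.00)
fast_grower: called 11, truly spiked 12, recovered 11 (sensitivity 0.92, precision 1.00)
postfire_affinity: called 7, truly spiked 8, recovered 7 (sensitivity 0.88, precision 1.00)
```

Each line of the first block is one contrast × horizon: how many taxa were
testable, how many passed the q < 0.05 ∧ log₂FC > 0 gate, and how many
survived the viability and effect-size filters.  The catalogue recovers the
spiked ground truth with high sensitivity and no false positives; the four
relic-DNA decoys (burn-enriched DNA from dead cells) are all removed by the
RNA:DNA filter.  `examples/03_decay_fitting.py` and
`examples/04_field_severity.py` continue the walk-through: a dry-burn flux
series fits to M₁ = 0.0173, k₁ = 0.180, k₂ = 0.00072 (generating truth
0.0166, 0.186, 0.00073; R² = 1.000), and the fast-grower trait total climbs
with burn severity at +0.032 per severity unit one year post-fire but only
+0.011 five years on, with the interaction retained (p = 0.009).

There is also a thin CLI over the same functions:

```bash
pyrotraits simulate --seed 1        # write synthetic tables + ground truth
pyrotraits traits                   # trait catalogue from tables on disk
pyrotraits decay                    # two-pool fits + treatment comparisons
pyrotraits field                    # severity regressions, Bray-Curtis
```

## Layout

```
src/pyrotraits/    io, simulate, diffabund, traits, decay, field, pipeline, cli
examples/          one narrative script per capability
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    model assumptions, defaults, numerical choices, limitations
```
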