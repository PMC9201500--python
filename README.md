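# rootplast

Root-system-architecture (RSA) plasticity analysis for pot-grown plants
under contrasting irrigation, built for plant-phenomics and
stress-physiology work: screening genotypes for drought tolerance from
gravimetric water use, root morphology by depth and diameter, and the
relative distance plasticity index.

The package implements, as a tested and scriptable pipeline, the full
analysis of a randomized-complete-block genotype × water-regime factorial
(default: 8 bottle-gourd genotypes × {well-watered WW, water-deficit WD}
× 3 blocks, 35 days), together with a seeded synthetic-data generator
that emulates the design so every stage is testable without raw data.

## What it computes

**Water accounting.** From pot-weight series corrected by unplanted
control pots:

    PBG = (final fresh weight − initial fresh weight) / days          [g/day]
    WU  = Σᵢ (PWᵢ₋₁ − PWᵢ) − (CPWᵢ₋₁ − CPWᵢ) − PBG·Δtᵢ               [L]
    WP  = (RDW + SDW) / WU                                            [kg m⁻³]
    root:shoot = RDW / SDW

where PW/CPW are planted/control pot weights (kg), RDW/SDW root and
shoot dry weights (g). Irrigation refills are recorded as separate
pre/post entries so only transpiration enters the sum.

**Root traits.** Each root segment is a cylinder (SA = π·d·L,
RV = π·(d/2)²·L); segments are binned into four 10-cm depth layers and
nine 0.5-mm diameter classes (half-open bins, last bin closed), and
RL (cm), SA (cm²), RV (cm³) and length-weighted MRD (mm) are aggregated
per plant, layer and class with exact partition conservation.

**Plasticity.** The relative distance plasticity index per genotype ×
trait over all cross-environment individual pairs:

    rd = |x_WD − x_WW| / (x_WD + x_WW),     RDPI = Σ rd / n ∈ [0, 1]

If WD responses are exactly proportional (x_WD = k·x_WW), RDPI =
(1 − k)/(1 + k); a 50 % reduction gives 1/3.

**Inference.** Shapiro–Wilk and Bartlett checks; RCBD two-way ANOVA
(`value ~ block + G + W + G×W`, Type-II SS); one-way ANOVA for RDPI;
Fisher's LSD with compact letter display (insert-and-absorb); per-genotype
WW − WD contrasts on the pooled error; Pearson correlation panels; PCA of
the trait correlation matrix with biplot data export.

## Worked example

```python
from rootplast.config import PipelineConfig
from rootplast.pipeline import run_pipeline

result = run_pipeline(PipelineConfig(seed=1))
print(result.analysis.groupby("regime")[
    ["wu_l", "wp_kg_m3", "root_shoot", "rl_cm", "mrd_mm"]
].mean().round(2))
```

prints

```
         wu_l  wp_kg_m3  root_shoot   rl_cm  mrd_mm
regime
WD       5.81      3.60        0.12  278.48    0.68
WW      21.09      4.75        0.04  696.07    0.80
```

WD plants used 5.8 L of water against 21.1 L for WW, their root:shoot
ratio tripled (shoot growth collapses faster than root growth), and
total root length dropped by more than half. `result.rdpi` holds the
64-cell genotype × trait plasticity grid (all values in [0, 1]);
`result.letters` the LSD letter displays, e.g. for root length:

```
      group  mean letters
         GC 617.2       a
      BG-58 600.7       a
      BG-78 532.6       b
...
Philippines 352.5       e
```

Groups sharing a letter do not differ at the 5 % LSD.

The same pipeline runs from the shell:

```
rootplast simulate --seed 1 --out data/
rootplast run-all  --seed 1 --out results/     # or --in data/
```

writing tidy CSVs (`plants.csv`, `pot_weights.csv`, `root_segments.csv`,
`water_results.csv`, `rdpi.csv`, `anova.csv`, `letters.csv`,
`contrasts.csv`, PCA loadings/scores, `biplot_data.json`) plus a
`manifest.json` with the config hash and seed: same seed, same bytes.

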