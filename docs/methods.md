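# Methods

## Scope and data model

The package analyses a glasshouse drydown trial: genotypes (default
eight bottle-gourd accessions of South African, Asian and Chilean
origin) grown in 20 L pots under two irrigation regimes — well-watered
(WW, refilled to field capacity at every weighing) and water-deficit
(WD, irrigation suspended) — in a randomized complete block design
(RCBD), default 3 blocks, 35 days, pots weighed three times a week.
Three tidy tables describe one experiment: per-plant biomass records,
pot-weight time series (planted and unplanted control pots), and
per-segment root tables (depth, length, diameter). All downstream
results are functions of these tables only.

## Gravimetric water accounting

Water use is the telescoped sum of successive pot-weight differences,
corrected by the control-pot differences over the same intervals
(drainage and residual surface evaporation) and by the plant's own
fresh-biomass gain PBG (g/day, converted to kg):

WU = Σᵢ (PWᵢ₋₁ − PWᵢ) − (CPWᵢ₋₁ − CPWᵢ) − PBG·Δtᵢ  [L, 1 kg water ≡ 1 L]

Two conventions matter and are fixed here:

* **Refills.** A WW refill raises the pot weight; taking raw successive
  differences would count the added water as negative consumption. The
  series therefore stores the pre- and post-irrigation weight as two
  entries on the same day, and only intervals with Δt > 0 enter the sum.
  The water transpired between weighings is kept; the refill jump is not.
* **PBG inside the sum.** The biomass correction is applied per interval
  as PBG·Δt, so the total subtraction over the run equals the total
  fresh-biomass gain — dimensionally consistent and additive over
  arbitrary interval splits.

These choices give three exact identities (tested to 1e−12): the
telescoping collapse (constant control, PBG = 0, no refills ⇒
WU = first − last weight), control neutrality (identical plant and
control series ⇒ WU = −PBG·T), and additivity over interior splits.

Water productivity is WP = (RDW + SDW)/WU in g/L ≡ kg m⁻³, undefined
(NaN with a warning) for nonpositive WU; root:shoot = RDW/SDW.

## Root traits

Segments are cylinders: SA = π·d·L, RV = π·(d/2)²·L. Depth layers
(default 0–10–20–30–40 cm) and diameter classes (default nine 0.5 mm
classes, 0–4.5 mm) are half-open [a, b) with the last bin closed, so the
bins partition the segments: per-layer and per-class RL/SA/RV sums equal
whole-plant totals exactly. Oversized diameters go to a flagged overflow
class rather than being dropped. A segment belongs to the layer of its
midpoint depth; segments are not split across layers (the generator
emits segments much shorter than the 10 cm layer thickness). MRD is the
length-weighted mean diameter by default — the mean diameter *of the
root system*, where long segments count more; an unweighted per-segment
mean is available (`mrd_weighting="unweighted"`) since scanner-software
definitions vary. Units: inputs mm (length, diameter) and cm (depth);
outputs RL cm, SA cm², RV cm³, MRD mm.

## RDPI

For each genotype and trait, every cross-environment pair of individuals
(j in WW, j′ in WD) contributes rd = |x − x′| / (x + x′), and RDPI is
the mean over the n defined pairs (default design: 3 × 3 = 9). Within-
environment pairs are never used. The index is scale-invariant,
symmetric in the environment labels, and confined to [0, 1] for
nonnegative traits. Pairs with both values zero are excluded (n
decremented), since 0/0 is undefined; treating them as 0 would fabricate
evidence of no plasticity. Under an exactly proportional response
x_WD = k·x_WW every pair gives rd = (1 − k)/(1 + k), which is the
closed form used throughout the tests (k = 0.5 ⇒ 1/3).

The replication unit for the one-way ANOVA on RDPI is genuinely
ambiguous: the n = 9 relative distances per genotype derive from only 6
plants and are not independent. The default passes the per-pair rd
values as observations and flags the output `pseudo_replicated`; a
conservative `rdpi_mode="blocks"` computes one RDPI per block (3
independent observations per genotype). Neither mode is claimed to be
what any particular historical analysis used.

## Inference

* **Model.** `value ~ block + genotype + water + genotype:water`, all
  factors fixed, fitted by OLS (statsmodels) with Type-II sums of
  squares — identical to the classical decomposition on balanced data
  and robust to mild imbalance (unbalanced layouts are accepted with a
  warning). Blocks are fixed effects; no mixed model is attempted.
* **Assumptions.** Shapiro–Wilk on residuals, Bartlett across groups;
  reported alongside each ANOVA, not used to gate it.
* **LSD letters.** LSD(a,b) = t₁₋α/2,df·√(MSE·(1/nₐ + 1/n_b)). The
  compact letter display uses insert-and-absorb: start with all groups
  in one letter column; for each significant pair split every column
  containing both; drop columns absorbed by supersets; letter the
  surviving columns from "a" at the highest mean. The construction
  guarantees two groups share a letter iff their difference is within
  the LSD (verified against an all-pairs oracle).
* **Contrasts.** Per-genotype estimate = mean(WW) − mean(WD) with SE
  from the pooled two-way MSE, so a positive estimate means the trait
  declined under deficit and the root:shoot contrast comes out negative.
* **Correlations.** Pairwise-complete Pearson r with two-sided t-based
  p-values; zero-variance pairs are NaN with a warning.
* **PCA.** Eigendecomposition of the trait correlation matrix
  (observations standardized per variable). Loadings are unit-norm
  eigenvectors, so loadings·diag(λ)·loadingsᵀ reconstructs the
  correlation matrix and Σλ equals the number of variables; biplot
  arrows are loadings·√λ. Each component is sign-fixed so its
  largest-magnitude loading is positive, making biplots reproducible.
  Default observations are the per-condition genotype means of
  {WP, RL, SA, MRD, RV} (8 rows per condition), configurable to
  plant-level rows. Note that with 5 standardized variables the top two
  eigenvalues bound PC1+PC2 variance at (λ₁+λ₂)/5, so high two-axis
  percentages reported in small-n screening studies should be read
  against that denominator.
* **Multiplicity.** No correction beyond the LSD's ANOVA protection is
  applied, matching common practice in variety-trial reporting; with 9
  traits × 28 genotype pairs this inflates family-wise error, a known
  limitation of the display rather than a bug.

## Synthetic-data generator

The generator's job is to produce datasets with the statistical
structure the analysis assumes, at the scale of the emulated trial.

* **Schedule.** Weighing days are day 0, the final day, and k evenly
  spaced days per week (offsets ⌊7j/k⌋); the default 3/week over 35 days
  is the Mon/Wed/Fri pattern {0, 2, 4, 7, …, 32, 35}.
* **Pot weights.** Daily water loss for WW pots is a constant base rate
  (default 0.65 kg/day, scaled by a per-plant transpiration multiplier,
  giving ≈ 21 L over the run); for WD pots the loss decays exponentially
  (time constant 10 days, total ≈ 6 L) so the drydown flattens as plants
  die late in the run. Noise (lognormal, CV 0.10, mean-corrected) is
  applied to the *loss*, never to the weight, so WD series are monotone
  by construction. Control pots lose only a drainage/evaporation trickle
  (0.02 kg/day).
* **Biomass.** Multiplicative model: panel base (SDW 95 g, RDW 3.3 g)
  × genotype multiplier × regime reduction (SDW ×0.2, RDW ×0.64 under
  WD, so root:shoot rises ~3× under deficit) × block effect (lognormal,
  CV 0.05) × residual (CV 0.10). Final fresh weight is 10× total dry
  weight (a fixed fresh:dry ratio linking PBG to dry biomass; real
  plants vary around such a ratio, and nothing downstream is sensitive
  to its exact value).
* **Root segments.** Per-plant segment count is Poisson (base 280 ×
  genotype × regime reduction × block); lengths are uniform on
  [0.2, 1.8]×25 mm (mean exactly 25 mm, always shorter than a layer);
  diameters are lognormal (median 0.70 mm × genotype × 0.85 under WD,
  σ = 0.5), which puts the largest share of root length in the
  0.5–1.0 mm class — the fine-root signature of this kind of data.
  Depth layers are drawn from regime-specific allocations
  (WW 0.32/0.28/0.22/0.18; WD 0.28/0.32/0.23/0.17, peaking in the
  second layer), and deep-rooting genotypes (Illapel, Chepica) shift
  toward a deeper profile under WD.
* **WD reduction of root traits.** The overall WD/WW expectation ratio
  for root totals defaults to 0.4. With any depth reallocation the
  per-layer ratios straddle the overall one (allocations sum to 1), so
  an overall 0.4 keeps the expected WD mean of each additive trait at or
  below half the WW mean in every layer — the "at least 50 % decline in
  all layers" pattern — with a margin (max expected layer ratio ≈ 0.46)
  that MC noise does not erase. Osorno instead carries an exact
  proportional reduction k = 0.5 (`root_reduction=0.5`), making it the
  reference genotype whose RL RDPI recovers the closed form 1/3. MRD is
  intensive and shrinks only via the diameter median (×0.85), mirroring
  the much weaker diameter response real trials report.
* **Noise-free limit.** Setting all noise SDs to 0 makes counts, lengths
  and diameters deterministic, so WD expectations equal reduction ×
  WW exactly; the closed-form plasticity tests run in this limit (with
  a segment base divisible by the reduction factors so rounding cannot
  break exactness).
* **QC.** An optional guard warns when mean dry biomass per pot volume
  exceeds a configurable bound (≈ 2 g/L is the usual pot-binding
  guidance); the generator can be configured into the 1–2.6 g/L band by
  lowering the biomass bases.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: no soil physics or evapotranspiration
response to weather; no growth dynamics (biomass appears only as
endpoint values); no root topology, branching or image artefacts;
trait families are conditionally independent given genotype/regime/block
(real RL–RDW correlations arise only through shared multipliers);
measurement error on weighings is folded into the loss process.
End-to-end checks therefore validate the *accounting and inference
machinery* under a faithful design, not biological realism.

## Numerical choices

* Half-open bins with a closed top edge; boundary diameters (e.g.
  exactly 0.5 mm) belong to the upper class.
* Problem sizes: the acceptance checks use 1000 random RDPI instances,
  100 random segment tables, 200 LSD instances and 2000 null ANOVA
  replicates of the 8×2×3 design — large enough for the 0.05 ± 0.02
  type-I band (MC SE ≈ 0.005) while keeping a full run around a minute.
* All randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning; identical config + seed ⇒
  byte-identical outputs (hashed config in the run manifest).
* Exactness tolerances: water identities and RDPI oracle 1e−12
  (pure floating-point accumulation), partition conservation 1e−9
  relative, PCA reconstruction 1e−9.

## Known limitations

* The WU formula attributes any un-modelled evaporation difference
  between planted and control pots to the plant.
* Fisher's LSD without further multiplicity control is liberal across
  many traits.
* Pseudo-replication in the default RDPI ANOVA (see above).
* The generator's effect sizes are calibrated to reproduce qualitative
  regime/genotype patterns, not any specific published means; no numeric
  agreement with historical tables is claimed or tested.
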