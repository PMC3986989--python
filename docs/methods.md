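# Methods

## Scope and data model

The package assesses six metals — Cd, Cr, Cu, Ni, Pb, Zn — in topsoil
sampled on transects crossing a pipeline right-of-way (RoW). A sample
table carries one row per (site, transect, zone) with dry-weight
concentrations in mg/kg; the seven zones are the trench (0 m), working
zone and piling area (10 m, opposite sides), and paired plots at 20 m
and 50 m. Compass-direction labels (E20/W20, N20/S20, …) are normalized
to side-agnostic names (`d20_side1`, `d20_side2`, …) because every
analysis groups by distance, never by direction; the original label is
kept as metadata. Concentrations are totals on air-dried soil; no
moisture or bioavailability correction is applied.

Three parameter families ship as fixtures and can be overridden from a
TOML config (`[backgrounds.<site>]`, `[toxicity_factors]`,
`[exposure.child|adult|shared]`, `[tox.<metal>]`); absent keys fall back
to the fixtures, and the serializer emits `repr(float)` so a round trip
reproduces every value exactly.

## Geo-accumulation index

`Igeo = log2(C / 1.5B)`; the 1.5 buffers natural background fluctuation.
The index convention takes B from average shale, but no shale values are
bundled: the packaged backgrounds are the two sites' local soil values,
and the profile uses them by default with a logged notice. Users
following the shale convention supply an `average_shale` background set
via config. Zone values average the per-sample indices over transect
replicates (log-domain mean, the variance-stabilizing choice for
lognormal concentrations); `aggregation="mean_conc"` instead applies the
index to the zone-mean concentration, since either convention is
defensible for replicate designs. A zero concentration yields a −∞
sentinel that is excluded from zone means with a warning rather than
propagated — below-detection handling is site-specific and left to the
user. Class boundaries are closed above (class k covers (k−1, k]), so
Igeo = 0 is class 0 and Igeo = 1 is class 1 exactly.

## Potential ecological risk index

`RI = Σ T_i · C_i/B_i` with T = {Cd 30, Cu/Ni/Pb 5, Cr 2, Zn 1}; soil at
background scores RI = 48. The category thresholds (50/100/200) are the
adjusted criteria appropriate for this six-metal set rather than the
original sediment formulation. RI reads its backgrounds independently of
Igeo and defaults to the site-local sets, which is what "background
value for metals" denotes here. Because RI is linear in concentration,
the zone value computed from zone-mean concentrations equals the mean of
per-sample RI; per-sample values are available (`per_sample=True`) for
the between-zone ANOVA.

## Health risk model

Doses follow the canonical USDOE-RAIS / USEPA-RAGS factor chains given
in the README. Choices that were genuinely open:

- **Units.** The single 10⁻⁶ kg/mg factor converts ingested/adhered soil
  mass once per soil-mass-based dose. Non-cancer inhalation compares an
  air concentration in mg/m³ against RfC; cancer inhalation converts to
  µg/m³ (×10³) to match the inhalation unit risk.
- **Missing toxicity values.** A metal × route without a reference dose,
  reference concentration, slope factor or unit risk contributes zero
  and is recorded in `skipped_routes` with a log notice (RfC exists only
  for Cd and Ni; an oral slope factor only for Pb). A table with nothing
  evaluable at all raises.
- **Age adjustment.** IR_adj and DFS_adj weight childhood (ED_child
  years) by child parameters and the remaining ED_adult − ED_child years
  by adult parameters; with the default table they evaluate to 112.9 and
  362.36 (printed as 113 and 362.4). DFS_adj excludes the dermal
  absorption fraction; for dermal cancer risk the age-specific ABS_d is
  applied inside the age sum (giving 6.377 by default), with
  `dermal_cancer_abs="child"|"adult"` available since compilations
  differ on this placement.
- **Inhalation exposure duration** for cancer defaults to the adult ED
  (30 y), configurable via `ed_inh`.
- **Lead** is treated like the other carcinogens through its tabulated
  CSF/IUR; blood-lead modelling is out of scope.
- **Reporting.** HI is summed over metals per receptor and zone (one
  value per bar), with per-metal HQ columns retained; cancer risk is
  age-adjusted and therefore identical across receptor rows. The adult
  dermal absorption factor of 0.001 is used verbatim from the compiled
  exposure table.

## Zone statistics and clustering

The one-way ANOVA is the classical between/within decomposition
(scipy's implementation) with two sentinel cases: zero within-group
variance with distinct means reports an infinite F with p = 0; fully
constant data is flagged degenerate. No Welch correction is applied,
matching the plain ANOVA convention of desktop statistics packages. The
default contrast is the all-zones omnibus; `contrast="row_vs_far"` pools
the RoW zones against the 50 m plots.

Metals are clustered on correlation distance (1 − Pearson r between
metal columns) with average linkage; z-scored Euclidean distance and
complete or Ward linkage are available, and columns are processed in
canonical metal order so ties break deterministically. Low merge heights
mean strong co-variation, the signature of a shared source.

## Synthetic data generator

`log C = log B_m + λ_m s(z) + γ_m Z_t + ε`, with zone schedule s =
(trench 1.0, working 0.8, piling 0.6, 20 m 0.2, 50 m 0.0), per-metal
log-enrichment λ = (Cd 1.0, Pb 0.9, Cu 0.5, Ni 0.5, Cr 0.1, Zn 0.0), a
standard-normal factor Z drawn once per transect and loaded with
γ = 0.6 on the anthropogenic metals {Cd, Cu, Ni, Pb} (zero otherwise),
and i.i.d. noise ε ~ N(0, 0.15²). Enrichment is multiplicative because
every downstream quantity is ratio-based; the per-transect (not
per-sample) factor mimics construction-activity heterogeneity between
transects and induces the Cu–Ni–Pb–Cd correlation block. The defaults
put the median trench Cd near e ≈ 2.7× background, keeping zone RI in
the moderate–considerable band with a decline to low by 50 m. Default
design size is 2 sites × 3 transects × 7 zones = 42 samples, the scale
of a real transect survey; the parameter-recovery analysis uses a
single-site design with 200 transects.

`estimate_enrichment` returns the zone mean of log(C/B) per metal, an
unbiased estimator of λ_m s(z) whose sampling sd over n transects is
√(γ_m² + σ²)/√n.

**What the generator does and does not emulate.** It reproduces the
survey geometry, lognormal marginals, the distance-decaying enrichment
and the anthropogenic correlation block. It deliberately omits spatial
autocorrelation, measurement error structure, below-detection censoring
— and any *shared natural (geogenic) factor* between Cr and Zn. That
last omission has a visible consequence: in real soils Cr and Zn co-vary
through parent material, which is what makes them cluster together in a
source dendrogram; in the generator their mutual correlation is exactly
zero while Cr retains a weak correlation (~0.12) with the anthropogenic
metals through the shared spatial trend. A two-cluster cut therefore
tends to attach Cr to the anthropogenic group (or isolate whichever of
Cr/Zn merges last) rather than form a {Cr, Zn} cluster — at the default
design size the {Cd,Cu,Ni,Pb} | {Cr,Zn} partition emerges in roughly 40%
of runs under the default settings and ~85% under Ward linkage, and the
correlation-distance rate *decreases* with sample size. Passing cluster
tests on this generator consequently shows that the clustering machinery
is correct, not that the two-source structure of real data is
recoverable at any rate; the other pipeline-level patterns (RI and
health-risk decline with distance, child > adult hazard) are faithfully
reproduced.

## Numerical conventions

CSV output is written at 6 significant digits; classification labels use
Müller's and the RI scheme's standard English wording. All randomness
flows from a single integer seed through `numpy.random.default_rng`.
Validation errors carry the offending row number and the allowed
vocabulary. Profile tables are ordered by site, nominal distance, then
canonical metal order.
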