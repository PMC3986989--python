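# soilrisk

Ecological and human health risk assessment of heavy-metal contamination
in agricultural topsoil around linear construction corridors (e.g., a
buried gas pipeline right-of-way).

Construction of a pipeline disturbs a ~30 m corridor: a trench where the
pipe is welded and buried, a working zone used by vehicles, and a piling
area where stripped soil is stockpiled. These activities can deposit Cd,
Cr, Cu, Ni, Pb and Zn in the surrounding cropland. `soilrisk` takes
transect surveys of soil metal concentrations at graded distances from
the trench (0 m, 10 m, 20 m, 50 m) and answers three questions: *is the
soil contaminated*, *what ecological risk does it pose*, and *what does
it mean for the people working or living there* — plus which metals
likely share a source.

## Models

**Geo-accumulation index** (per metal, concentration C against
geochemical background B, both mg/kg dry soil):

```
Igeo = log2( C / (1.5 B) )
```

graded into Müller's seven classes: Igeo ≤ 0 class 0 (uncontaminated),
k−1 < Igeo ≤ k class k for k = 1…5, Igeo > 5 class 6 (extremely
contaminated).

**Hakanson potential ecological risk index** over the six metals, with
toxicity factors T (Cd 30, Cu/Ni/Pb 5, Cr 2, Zn 1):

```
f_i = C_i / B_i        E_i = T_i f_i        RI = Σ_i E_i
```

Background soil scores RI = 48. Grades: RI ≤ 50 low, ≤ 100 moderate,
≤ 200 considerable, > 200 high pollution.

**Three-pathway human health risk** (USDOE-RAIS / USEPA-RAGS form):
chronic daily intakes for soil ingestion, particulate inhalation and
dermal contact, for child and adult receptors,

```
CDI_ing    = C · IngR · EF · ED / (BW · AT_nc) · 10⁻⁶
EC_inh     = C · ET · EF · ED / (PEF · 24 · AT_nc)
CDI_dermal = C · SA · AF · ABS_d · EF · ED / (BW · AT_nc) · 10⁻⁶
```

hazard quotients HQ = dose / reference value per route, hazard index
HI = Σ HQ; carcinogenic risk for Cd, Cr, Ni, Pb uses lifetime-averaged,
age-adjusted factors (IR_adj = 113, DFS_adj = 362.4 mg·year/kg/d with the
default exposure table) and Risk = CDI_ca × CSF summed into a Total Risk.

Zone-comparison one-way ANOVA and hierarchical clustering of metals
(correlation distance, average linkage) support source attribution, and
a seeded lognormal generator reproduces the 2-site × 3-transect × 7-plot
survey design for testing and power analysis.

## Worked example

```python
import soilrisk as sr

table = sr.generate_transects(sr.GeneratorConfig(seed=42))
backgrounds = {s: sr.default_parameters(s)[0] for s in ("Site1", "Site2")}
_, T, exposure, tox = sr.default_parameters(None)

ri = sr.ri_profile(table, backgrounds, T)
print(ri[ri.site == "Site1"][["zone", "RI", "category"]])
```

prints the zone ranking for the first site:

```
        zone          RI      category
      trench  113.584196  considerable
     working   96.473639      moderate
      piling   83.408920      moderate
   d20_side1   58.821781      moderate
   d20_side2   59.303596      moderate
   d50_side1   49.586768           low
   d50_side2   50.841439      moderate
```

The trench (RI 113.6) is in the *considerable* pollution band and risk
declines with distance, reaching the *low* band (RI < 50) by 50 m — the
spatial footprint expected of construction-sourced contamination.
Health risk follows the same gradient and children carry more of it: at
this seed the child hazard index averages 2.15 in the right-of-way vs
1.90 at 50 m, against 0.0655 vs 0.0527 for adults, and the trench total
cancer risk is 8.0×10⁻⁷ vs 4.5×10⁻⁷ at 50 m.

The same stages are packaged as numbered drivers — run
`python analysis/01_simulate.py` through `05_source_attribution.py` to
produce `results/*.csv` and `results/dendrogram.json` — and as a CLI:

```
soilrisk simulate --seed 42 --out samples.csv
soilrisk report --samples samples.csv --outdir report/
```

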