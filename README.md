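# celloc

Per-cell fluorescence colocalization analysis for protein-mislocalization
studies, plus rare-variant case/control cohort arithmetic.

## The problem

Missense mutations in membrane transporters such as ABCA7 (an
Alzheimer's-disease risk gene) can leave protein abundance intact while
abolishing trafficking: the mutant protein never reaches the plasma
membrane and is retained in the endoplasmic reticulum. The standard
readout is confocal imaging of cells expressing a GFP-tagged construct,
co-stained with a plasma-membrane marker (wheat-germ agglutinin, WGA) and
an ER marker (calreticulin), followed by *per-cell* colocalization
analysis: for each segmented cell, the Pearson correlation

r = Σᵢ (aᵢ − ā)(bᵢ − b̄) / √( Σᵢ (aᵢ − ā)² · Σᵢ (bᵢ − b̄)² )

between the tagged-protein channel *a* and a co-marker channel *b* over the
cell's pixels. Membrane-localized protein gives high r against WGA;
ER-retained protein gives high r against calreticulin. Genotype groups of
per-cell r values have unequal variances, so group inference uses Welch's
heteroscedastic one-way ANOVA with Games-Howell post-hoc comparisons
against the wild type (studentized-range reference distribution,
Welch–Satterthwaite degrees of freedom).

`celloc` implements that workflow end to end:

- **`celloc.synthgen`** — seeded, ground-truthed synthetic scenes: elliptical
  cells whose tagged-protein channel is a mixture
  `alpha · membrane-ring + (1 − alpha) · reticular-ER-texture`, Gaussian
  PSF, Poisson + Gaussian detector noise. `alpha` is the membrane fraction
  (wild-type-like ≈ 0.8, ER-retained mutant ≈ 0.1).
- **`celloc.segment`** — cell delineation on the protein channel: circular
  median filter, Huang fuzzy-entropy auto-threshold, 8-connected
  components, particle-size filter, optional curated mask override.
- **`celloc.coloc`** — per-cell Pearson r, batch measurement tables, and an
  optional block-shuffle randomization significance test.
- **`celloc.stats`** — `WelchOneWay` model / `WelchOneWayResults` with
  Welch ANOVA, Games-Howell post-hoc table and `summary()`.
- **`celloc.cohort`** — MAF rarity filter (≤ 1%), HGVS-driven variant
  classification, carrier frequencies, Fisher exact contingency tests,
  compound-carrier counts; `celloc.datasets` bundles the Belgian
  Alzheimer case/control tallies (1376 patients / 976 controls) and the
  annotation table of the 14 variants used in the localization study.
- **`celloc.pipeline` / CLI `celloc`** — batch orchestration:
  `simulate`, `segment`, `measure`, `stats`, `cohort`, `run-all`.

## Worked example

```python
import pandas as pd
from celloc import pipeline, datasets

cfg = pipeline.RunConfig(
    genotype_alphas={"WT": 0.8, "p.L620P": 0.1, "p.G1820S": 0.1},
    images_per_genotype=10,      # 4 cells per 512x512 image
    comarkers=("PM",),
    base_seed=17,
    out_dir="demo_out",
)
report = pipeline.run_imaging_pipeline(cfg)
df = pd.read_csv("demo_out/measurements.tsv", sep="\t")
print(df.groupby("genotype_label")["pearson_r"].agg(["count", "mean"]).round(3))
print({c["group_j"]: (round(c["p_adj"], 6), c["significance_stars"])
       for c in report.posthoc})
```

prints

```
                count   mean
genotype_label
WT                 40  0.908
p.G1820S           40 -0.713
p.L620P            40 -0.703

{'p.G1820S': (0.0, '***'), 'p.L620P': (0.0, '***')}
```

i.e. each genotype contributed 40 segmented cells; wild-type cells
correlate strongly with the plasma-membrane marker (mean r ≈ 0.91) while
both ER-retained mutants lose that colocalization entirely (mean r ≈
−0.71), and both Games-Howell comparisons against WT are significant far
below the 0.001 star threshold.

The cohort side:

```sh
celloc cohort --out-dir cohort_out
```

prints, among others, `patients any_rare 115/1376 8.36%` — the rare-variant
(MAF ≤ 1%) carriage frequency in the patient cohort — and the Fisher exact
p for the excess of compound carriers (11/1376 vs 5/976).

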