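# ecosens

Regional-scale analysis of how plant biodiversity relates to the
**sensitivity of vegetation productivity to climate variability**, built as
a tested, fully synthetic-data-driven pipeline.

## The problem

At plot scale, more diverse plant communities tend to keep their
productivity more stable under environmental fluctuation. Whether that
pattern holds at the scale of biogeographic regions — where diversity means
thousands of species mapped onto half-degree grid cells — is much harder to
test. The ingredients are: satellite vegetation-index time series (EVI, a
reflectance ratio in [0, 1] proxying productivity), gridded monthly climate,
species range maps, a dated phylogeny, and functional traits.

This package implements that analysis end to end:

1. **Ecosystem sensitivity** (`ecosens.sensitivity`). For each grid cell,
   EVI is regressed on temperature and precipitation with all series
   z-transformed, so the slopes `β_T`, `β_P` are standardized sensitivity
   coefficients — values near zero indicate stability. Two temporal scales
   are fitted: *seasonal* (monthly series, centred 12-month moving-average
   detrend) and *interannual* (annual mean EVI and temperature, cumulative
   annual precipitation, not detrended). Cells with mean EVI < 0.1 are
   masked; cells are classified temperature- vs water-limited by comparing
   |β_T| and |β_P|.
2. **Biodiversity dimensions** (`ecosens.biodiversity`). Species richness
   from the presence matrix; Faith's phylogenetic diversity (PD, summed
   branch length to the root) on the maximum-clade-credibility tree of a
   tree set; functional richness (FRic, convex-hull volume) in a
   correlation-PCA trait space retaining ≥ 80 % of variance. PD and FRic
   are standardized against a richness-constant null model,
   `SES = (obs − mean(null)) / sd(null)`.
3. **Trait gap-filling** (`ecosens.trait_imputation`). Missing trait values
   are imputed by deterministic iterative ridge regression on the other
   traits plus *phylogenetic eigenvectors* (principal coordinates of the
   patristic distance matrix, axes ≥ 3 % variance), with imputed values
   clamped to the observed per-trait range.
4. **Spatial error models** (`ecosens.spatial_model`). Each |sensitivity|
   response is modelled as `y = Xβ + u`, `u = λWu + ε`, with W an
   inverse-distance (1/d) weights matrix on the band where Moran's I is
   strongest, observation weights 1/(CI range), and predictors = richness,
   SES-PD, SES-FRic, biome, limiting factor and their interactions.
   Estimation is exact maximum likelihood (eigenvalue log-determinant).
5. **Synthetic study system** (`ecosens.synthetic`). Every input is
   generated with known ground truth — climate with seasonal cycle, trend
   and year effects; EVI built from known per-cell β fields; disc-shaped
   species ranges; a Yule phylogeny (root height 100 Myr) plus an
   NNI-perturbed tree set; Brownian-motion traits with controllable
   phylogenetic signal and missingness — so every stage is testable offline.

`ecosens.pipeline` / the `ecosens` CLI orchestrate the stages with
manifests, checksum-guarded reruns and full determinism under one seed.

## Worked example

```python
from ecosens import pipeline
from ecosens.config import PipelineConfig, SyntheticConfig

cfg = PipelineConfig(
    synthetic=SyntheticConfig(n_rows=12, n_cols=12, n_years=10,
                              n_species=30, seed=42),
    n_null_reps=99, seed=42)
manifest = pipeline.run_pipeline(cfg, "demo")
```

The run writes per-stage CSVs into `demo/`. The sensitivity table starts

```
 cell_id       scale  beta_T  beta_P  ci_T_low  ci_T_high  ci_P_low  ci_P_high    r2  n_obs
       0    seasonal   0.673   0.469     0.658      0.688     0.453      0.484 0.995    108
       0 interannual   0.415   1.041     0.283      0.546     0.909      1.173 0.980     10
```

— cell 0's monthly EVI moves 0.67 standard deviations per standard
deviation of temperature at the seasonal scale (108 months left after the
moving-average window loss), with a tight t-based 95 % CI. The four spatial
error models (T/P × seasonal/interannual) report their spatial parameter in
`demo/sar_fits.json`:

```
{'P_interannual': 0.666, 'P_seasonal': 0.998, 'T_interannual': 0.724, 'T_seasonal': 0.997}
```

and `demo/sar_T_seasonal.csv` holds the coefficient table; with the default
generator (β fields independent of richness) the biodiversity terms hover
near zero, e.g.

```
    term  estimate    se      z     p
richness     0.006 0.006  0.936 0.350
```

When the generator couples true sensitivity to richness
(`ecosens.synthetic.couple_beta_to_richness`), the richness coefficient
turns strongly negative and significant — the diversity–stability signal
recovered under a known generative model.

The same pipeline runs from the shell:

```bash
ecosens run-all --seed 42 --outdir demo
ecosens validate --presence demo/presence.csv --trees demo/trees.nwk
```

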