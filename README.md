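# beediv

Dimensions of bee-community diversity under land use: species, functional
and phylogenetic diversity from site-level abundance data, Gaussian mixed
models of their response to land-use class, cropland intensity and human
population density, and gridded projection of each facet relative to an
uninhabited semi-natural baseline — with a synthetic-data generator that
makes the whole pipeline testable end to end against known ground truth.

The package is aimed at community ecologists and biodiversity-informatics
researchers who work with multi-study site networks (sites nested in
blocks nested in studies, unequal sampling effort, heterogeneous
methodology) and want conceptually matched diversity facets rather than a
single index.

## The model

Every facet is Rao's quadratic entropy with a facet-specific species
dissimilarity d ∈ [0, 1],

&nbsp;&nbsp;&nbsp;&nbsp;Q = Σᵢⱼ dᵢⱼ pᵢ pⱼ,&nbsp;&nbsp;&nbsp;&nbsp;E = 1 / (1 − Q),

expressed as an effective number of species E so facets share units:

| facet | dᵢⱼ |
|---|---|
| species (SD) | 1 for all i ≠ j (Q = Gini–Simpson, E = inverse Simpson) |
| functional (FD) | square-root-corrected Gower dissimilarity over mixed traits |
| phylogenetic (PD) | half-cophenetic tree distance, rescaled to [0, 1], averaged over a tree sample |

Around that core: sampling-effort correction (abundance assumed linear in
effort, within study), missForest-style random-forest imputation of
missing traits with phylogenetic eigenvectors as predictors, taxonomic
grafting of species missing from the phylogeny, mixed models with
AIC-chosen random structures and backward likelihood-ratio
simplification, parametric-bootstrap intervals, marginal R², GVIF and
Moran's I diagnostics, baseline-relative projection over raster
covariates, per-country aggregation, and OLS residual maps quantifying
the spatial mismatch between facets. `docs/methods.md` documents each
choice.

## Worked example

Per-site diversity from a long community table and a trait table:

```python
import pandas as pd
from beediv import site_diversity

comm = pd.DataFrame({
    "site_id": ["s1"]*3 + ["s2"]*2,
    "species_id": ["Andrena_a", "Bombus_b", "Lasioglossum_c", "Andrena_a", "Bombus_b"],
    "abundance": [6.0, 3.0, 1.0, 5.0, 5.0],
})
traits = pd.DataFrame(
    {"body_size_mm": [8.0, 16.0, 6.0],
     "nesting": pd.array(["ground", "cavity", "ground"], dtype=object)},
    index=["Andrena_a", "Bombus_b", "Lasioglossum_c"],
)
print(site_diversity(comm, traits=traits).round(3).to_string(index=False))
```

```
site_id  Q_sd  E_sd  Q_fd  E_fd
     s1  0.54 2.174 0.439 1.784
     s2  0.50 2.000 0.474 1.902
```

Site s1 holds three species but behaves like ~2.2 equally common ones
(E_sd), and like ~1.8 fully distinct ones once trait redundancy is
accounted for (E_fd ≤ E_sd always, because trait distances are ≤ 1).

The full pipeline — simulate a known study system, impute traits,
compute diversity, fit the models, project and map the mismatch — runs
from the CLI:

```sh
beediv run --seed 1 --outdir run1
```

`run1/model_sd.json` then holds the recovered land-use effects on
ln-scale species diversity (truth injected by the generator: pasture
−0.39, medium cropland −0.50, high cropland −0.48):

```
"Intercept": 2.126, "land_use[T.pasture]": -0.436,
"land_use[T.cropland_low]": -0.149, "land_use[T.cropland_medium]": -0.499,
"land_use[T.cropland_high]": -0.536, "land_use[T.urban]": -0.117
```

together with diversity tables, relative-diversity and mismatch-residual
maps (plain-text ESRI ASCII grids), country summaries and a manifest with
per-stage seeds and SHA-256 hashes — rerunning with the same seed
reproduces every file byte-for-byte. The packaged EU27 country table can
be summarized directly:

```sh
$ beediv report
SD: 25/27 countries below 95% of baseline
FD: 24/27 countries below 95% of baseline
PD: 25/27 countries below 95% of baseline
```

i.e. in all but two or three countries the average grid cell retains
less than 95% of the diversity expected for uninhabited semi-natural
vegetation.

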