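# cacaopheno

Statistical toolkit for the agromorphological and phytochemical
characterization of cacao (*Theobroma cacao* L.) germplasm collections.
It is written for genebank curators and breeders who run replicated clonal
trials — many accessions, a handful of grafts each, a couple of seasons —
and need to turn trait tables into decisions: which descriptors are
heritable enough to select on, how the collection is structured, and which
accessions are worth propagating.

The pipeline covers:

* **Descriptive screening** — per-descriptor summaries (mean, SD, range,
  CV%), iterative Grubbs outlier screening on accession means, and
  qualitative-trait frequency tables (overall or per cluster).
* **Quantitative genetics** — seed index SI (mean dry single-seed mass, g)
  and pod index PI = 1000 / (seeds per pod × dry seed mass), variance
  components from the genotype × replication decomposition
  (GV = (MSG − MSE)/r), and the derived parameters
  GCV = 100·√GV/x̄, PCV = 100·√PV/x̄, H² = 100·GV/PV,
  GA = k·√PV·(GV/PV) with k = 2.06, GAM = 100·GA/x̄, each with the
  conventional low/moderate/high bands, plus across-season repeatability
  (intraclass correlation).
* **Multivariate structure** — Pearson correlation screening,
  correlation-matrix PCA with the eigenvalue > 1 / 75%-cumulative-variance
  retention rule, Ward.D2 hierarchical clustering on Euclidean distances
  with silhouette + gap-statistic K selection, multiscale-bootstrap AU
  node support, and an inter/intra cluster-distance summary.
* **Per-cluster inference** — Lilliefors-corrected KS and Bartlett
  assumption checks, unbalanced one-way ANOVA, and Tukey–Kramer compact
  letter displays.
* **Bayesian selection** — a bivariate mixed model on (SI, PI) fitted by a
  Gibbs sampler; the Bayesian Yield Stability Index (BYSI) is the genotypic
  value exceeded (SI) or not exceeded (PI) with 90% posterior probability,
  and accessions with BYSI_SI > 0.8 g and BYSI_PI < 23.5 are flagged as
  promising.
* **Phytochemistry** — calibration-curve inversion (DPPH, total phenolics),
  theobromine/caffeine ratio classification (Criollo < 2, Trinitario 2–9,
  Forastero > 9), and Pearson correlation networks over assay panels.
* **Synthetic trials** — a generator that plants known cluster structure,
  variance components and trait correlations, so every stage is testable
  end-to-end without any external data.

The clustering, PCA and Gibbs components are scikit-learn-style estimators
(`fit`, fitted `_` attributes, `get_params`); everything else is plain
functions over pandas tables.

## Worked example

```python
import cacaopheno as cp

# simulate a 113-accession trial with 8 planted phenotypic clusters
cfg = cp.SimConfig(separation=5.0, seed=42, qual_traits=[])
trial, truth = cp.generate_trial(cfg)

# genetic parameters for fruit mass
vc = cp.variance_components(trial, "FM")
gp = cp.genetic_parameters(vc.GV, vc.EV, vc.grand_mean)
print(f"FM: GCV={gp.GCV:.1f}% H2={gp.H2:.1f}% GAM={gp.GAM:.1f}% "
      f"({gp.H2_band} heritability)")

# cluster the collection and summarize distances
model = cp.WardClusterer(n_clusters=8).fit(trial.trait_matrix())
print("mean inter-cluster distances:")
print(model.distance_summary_.mean_distance.round(2).to_dict())

# Bayesian bivariate selection on (SI, PI)
si_pi = cp.selection.si_pi_table(trial)
post = cp.fit_bivariate(si_pi, iterations=5000, burnin=1000, seed=1)
res = cp.select_promising(cp.bysi(post))
print(f"promising accessions: {res.n_selected}/{res.n_total} "
      f"({res.selected_pct:.2f}%)")
```

Output:

```
FM: GCV=30.4% H2=79.0% GAM=55.7% (high heritability)
mean inter-cluster distances:
{1: 8.95, 2: 8.41, 3: 7.81, 4: 8.62, 5: 8.74, 6: 9.14, 7: 8.63, 8: 8.52}
promising accessions: 113/113 (100.00%)
```

Fruit mass comes out highly heritable (the estimate recovers the planted
GV/PV split), the distance summary shows the eight planted clusters are
roughly equidistant, and every simulated accession clears the (0.8 g, 23.5)
thresholds because the generator centers SI and PI on a favourable
collection mean with modest genotypic spread — tighten the thresholds or
raise the planted variances to exercise partial selection.

A command-line entry point mirrors the library
(`cacaopheno all --seed 1 --outdir out/` runs the full pipeline and writes
the genetic-parameter, cluster-distance, cluster-means, selection and
network tables plus a Newick dendrogram).

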