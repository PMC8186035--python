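# microtraits

Functional analysis of host-associated microbial communities from a curated
trait database.

Taxonomic composition of the human microbiome varies wildly between people,
yet the *functions* present at a body site are remarkably stable. This
package analyzes that functional layer directly: it combines a curated table
of microbial traits (growth conditions, morphology, enzyme activities, gas
production, carbon-substrate use) with relative-abundance profiles of
human-associated communities and per-phylum phylogenies, and asks which
traits characterize which body sites, which traits let a species live across
many body areas, and what drives the metabolic breadth of a community.

It is intended for microbial ecologists who have (i) a trait database (one
row per species or genus, mixed continuous / categorical / binary traits),
(ii) an HMP-style abundance matrix with sample metadata (subject, body site,
body area), and (iii) Newick phylogenies per phylum, and who want the full
phylogenetically corrected analysis stack rather than ad-hoc scripts.

## Methods at a glance

* **Trait profiles.** For trait $t$ and sample $s$ the profile is the
  abundance-weighted mean
  $\bar{x}_{t,s} = \sum_i w_{i,s}\,x_{i,t}$, where the relative abundances
  $w_{i,s}$ are renormalized over the taxa whose value of $t$ is known.
* **Site contrasts.** For every trait and pair of body sites, a permutation
  test on the difference of per-site profile means (default $B=10{,}000$
  permutations, add-one estimator), Benjamini–Hochberg FDR control within
  each phylum, and a replication filter keeping contrasts significant in
  $\ge 2$ phyla.
* **Blocked prediction.** Random forests evaluated by *phylogenetically
  blocked* cross-validation: folds are monophyletic clades (phyla, classes,
  or families), never random splits, so shared evolutionary history cannot
  leak between training and test. Classification is scored by Cohen's
  $\kappa = (p_o - p_e)/(1 - p_e)$ and the area under the precision–recall
  curve; regression by RMSE, $\rho(\hat y, y)$ and adjusted $R^2$.
* **Trait network.** Graphical lasso over standardized profiles with the
  extended BIC, $\mathrm{EBIC} = -2\ell + |E|\log n + 4|E|\gamma\log p$,
  selecting the penalty; signed spin-glass (Potts) community detection by
  simulated annealing; and a bipartite cluster–site graph from per-site
  $L_1$-penalized logistic regressions.
* **Phylogenetic logistic regression.** For a binary tip trait
  (generalist vs specialist), $\mathrm{logit}\,P(y_i{=}1) = \beta_0 +
  \beta_1 x_i$ with residual correlation $\exp(-\alpha\,d_{ij})$ in
  patristic distance $d_{ij}$, fit by iterated estimating equations, with a
  parametric-bootstrap two-sided $p$-value for $\beta_1$.
* **Metabolic breadth.** The number of carbon substrates a taxon uses;
  per-sample Shannon decomposition of carbon-source versus taxonomic
  diversity; blocked random-forest regression of breadth on all
  non-substrate traits.

A first-class synthetic-data generator (`microtraits.synthetic_data`) emits
all three inputs with planted ground truth — site–trait effects,
block-structured trait covariance, tree-evolved binary traits, a
generalism rule, and a metabolic-breadth driver — so every stage of the
pipeline is testable end to end without downloads.

## Worked example

Simulate a world in which the number of carbon substrates a species uses is
driven by one continuous trait, then predict metabolic breadth with
phylum-blocked random-forest regression:

```python
from microtraits import synthetic_data as sd
from microtraits.orchestration import PipelineData, RunConfig, run_metabolism_analysis

world = sd.simulate_world(sd.WorldConfig(seed=0, breadth_driver="cont trait 05",
                                         n_subjects=12, taxa_per_phylum=40))
paths = sd.write_world(world, "demo_world")
data = PipelineData.load(paths["traits"], paths["schema"],
                         paths["abundance"], paths["metadata"])
cfg = RunConfig(seed=1, n_trees=300, min_focal_taxa=20, importance_repeats=1)
res = run_metabolism_analysis(data, cfg)
print(res["regression_metrics"].per_fold.round(3))
print("mean rho:", round(res["regression_metrics"].mean_rho, 3))
print(res["importances"]["mean"].nlargest(3).round(3))
```

prints

```
           rmse    rho  rho_spearman  adj_r2   n
phylum 1  4.423  0.924         0.935   0.850  46
phylum 2  4.556  0.909         0.925   0.823  46
phylum 3  3.447  0.939         0.942   0.878  46
phylum 4  3.493  0.941         0.940   0.884  46
mean rho: 0.928
cont trait 05    151.090
cont trait 06      6.637
cont trait 04      5.326
```

Each row is one held-out phylum: a forest trained on the other three phyla
predicts breadth for species it has never seen any relative of, and the
predicted–observed correlation $\rho \approx 0.93$ shows the planted driver
generalizes across clades. The importance column recovers `cont trait 05`
— the planted driver — as by far the strongest predictor (the score is the
permutation increase in mean squared error).

The same pattern runs from the shell:

```bash
microtraits simulate --seed 0 --out demo_world
microtraits all --data demo_world --out results --seed 1 --fast
```

Subcommands `sites`, `generalism` and `metabolism` run the three study
pipelines separately; `--fast` switches to the reduced profile
(1000 permutations, 500 trees, 500 bootstraps).

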