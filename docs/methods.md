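# Methods

This note documents the models and procedures implemented in `microtraits`,
the choices made where the design was genuinely open, and what the synthetic
worlds do and do not emulate.

## Trait database model

A database row is one taxon (species- or genus-rank) with a taxonomic
lineage and a value per trait. Traits are typed by a schema:

* **continuous** (e.g. optimal growth temperature) — real-valued, missing
  allowed (`NA`, `NaN`, empty cell, any case);
* **categorical** (e.g. oxygen requirement) — one of the schema's declared
  levels, missing allowed;
* **binary** (e.g. growth on glucose, catalase activity) — 0/1 and *never*
  missing: curation records an activity only when it is reported, so an
  absent report is coded 0. This asymmetry propagates through the whole
  pipeline (binary profile cells always have full abundance support).

**Genus consensus.** A genus record takes a trait value only when all of its
species agree. Missing species values do not break consensus by default:
agreement is evaluated over the non-missing values (requiring non-missing
unanimity would empty most genera, since typical databases are sparse).
The strict rule is available via `genus_consensus(..., ignore_missing=False)`.
For binary traits, which cannot be missing, disagreement falls back to 0 —
the genus has no consistent report of the activity, and not-reported is 0 by
the coding convention above.

**Encoding.** Categorical traits expand to one-hot dummy columns
(`trait=level`); all dummies of a missing value are masked jointly.
Continuous traits are used untransformed; standardization happens only
inside network inference, where comparable penalization across scales
requires it.

**Metabolic breadth** is the count of carbon-substrate binary traits equal
to 1 — a direct database summary, not an inference.

## Trait profiles

The profile of trait $t$ in sample $s$ is the abundance-weighted mean of $t$
over the matched, trait-annotated taxa, with weights renormalized over taxa
whose value of $t$ is known. A cell's *support* is the summed
(unrenormalized) relative abundance of the contributing taxa; a cell with no
contributor is missing, not zero. Species-level database matches are
preferred; a genus-consensus record is used when the species is absent;
taxon names are normalized (underscores to spaces, case-folded) before
matching because abundance files and databases differ in exactly these
cosmetic ways. "Phyla-sample" profiles restrict the contributors to one
phylum and are the units of leave-one-phylum-out prediction.

## Site contrasts

The test statistic for a trait and a site pair is the difference of per-site
means of the per-sample profile values; site labels are permuted over the
de-duplicated sample set (one sample per subject and site, chosen uniformly
under the run seed) and the two-sided p-value uses the add-one estimator
$p = (1 + \#\{|\Delta^\ast| \ge |\Delta|\})/(B+1)$, so $p \ge 1/(B+1)$.
Benjamini–Hochberg step-up control is applied to all trait × site-pair tests
within one phylum as a single family, and a contrast is reported as
ecologically informative when it is BH-significant in at least two phyla.
Sign conflicts between phyla are kept but flagged, never silently merged.
Permutations do not preserve subject pairing across sites; after
de-duplication, at most one sample per subject enters each site's group.

## Blocked cross-validation and forests

Random splits overstate performance whenever related taxa share both
features and labels. All model assessment here therefore holds out whole
monophyletic clades: phyla for cross-phylum questions, classes within a
phylum, falling back to families when a phylum's sampled members all share
one class. A fold whose training partition is single-class is skipped and
flagged.

The classifier is an in-repo balanced random forest: each of `n_trees`
(default 5000; 500 in the reduced profile) CART trees is grown on a
bootstrap drawn per class with counts equalized to the minority class. This
stratification keeps predicted probabilities calibrated around the balanced
prior, which matters because the site tasks are one-vs-rest with small
positive classes; an implementation that merely reweights classes leaves
the 0.5 vote threshold majority-biased and collapses kappa while leaving
rank-based scores high. Variable importance is the per-tree out-of-bag mean
decrease in accuracy: each tree is scored on its own out-of-bag rows with
one feature permuted at a time. Importance is evaluated per tree rather
than on the ensemble because correlated features mask each other at the
ensemble level. Regression uses scikit-learn's `RandomForestRegressor` with
training-set permutation importance (mean increase in MSE).

Metrics: Cohen's $\kappa$ (0 returned in the degenerate all-one-class case,
where the prevalence-only null is already perfect), step-interpolated
AUPRC, RMSE, Pearson $\rho$ (Spearman reported alongside), and the adjusted
$R^2$ of the observed-on-predicted simple regression with $n$ = fold test
size and one predictor. Both the mean of per-fold $\kappa$ and the pooled
predictions $\kappa$ are reported, since they answer slightly different
questions. One master seed fans out deterministically to per-fold seeds.

## Trait network

Profiles are transposed to samples × expanded traits, mean-imputed,
standardized, and pruned of exactly collinear columns by pivoted QR (the
dummies of one categorical trait share their support and sum to 1 per
sample, which would make the Gaussian model unidentifiable).

The penalty path is `n_lambda` log-spaced values (default 100) from
$\lambda_{\max}$ (the smallest penalty giving an empty graph) down to
$0.01\,\lambda_{\max}$. Model selection follows the extended BIC,
$\mathrm{EBIC}(\lambda) = -2\ell + |E|\log n + 4|E|\gamma\log p$ with
$\gamma = 0.5$ (the conventional default; exposed in config). The graphical
lasso proposes the candidate support at each $\lambda$; the likelihood
$\ell$ entering EBIC is that of the support-constrained *unshrunk* Gaussian
MLE (solved by L-BFGS on the free precision entries, with a Cholesky-based
positive-definiteness barrier). Scoring the shrunk penalized estimate
instead systematically favors denser graphs, because de-shrinkage of true
edges along the path masquerades as evidence for extra edges; the refit
variant recovers planted block supports exactly. Edges carry partial
correlations $-\Theta_{ij}/\sqrt{\Theta_{ii}\Theta_{jj}}$ from the refit
precision.

Communities minimize a signed Potts energy: the pairwise gain matrix is
$(w^+_{ij} - \gamma e^+_{ij}) - (w^-_{ij} - \gamma e^-_{ij})$, with
configuration-model expectations computed separately on the positive and
negative subgraphs, summed over within-cluster pairs. Positive weight
inside clusters and negative weight between clusters lower the energy. The
optimizer is simulated annealing (single-node moves, geometric cooling,
several restarts, incremental energy updates), deterministic given its
seed; on small graphs its optima match exhaustive search over all
partitions, and on planted signed graphs they match igraph's spin-glass
reference implementation.

The bipartite cluster–site graph comes from one $L_1$-penalized logistic
regression per site (site membership on all standardized profiles), with
the penalty chosen by minimum cross-validated misclassification (10-fold by
default, reduced with a warning when a site has too few positives; the
minimum rule rather than 1-SE). The cluster–site weight is the mean of the
cluster's retained coefficients; no retained coefficient, no edge.

## Phylogenetic logistic regression

For binary tip data $y$ and a single predictor $x$,
$\mathrm{logit}\,P(y_i{=}1) = \beta_0 + \beta_1 x_i$ with working residual
correlation $R_{ij}(\alpha) = \exp(-\alpha d_{ij})$ in patristic distance.
$\beta$ solves the GEE-type estimating equation
$X^\top A^{1/2} R^{-1} A^{-1/2}(y - \mu) = 0$ ($A = \mathrm{diag}\,
\mu(1-\mu)$) by Fisher scoring with a step-norm cap of 30 guarding against
quasi-separation; $\alpha$ is profiled over a fixed grid spanning roughly
two orders of magnitude around the inverse mean tip distance (plus an
effectively-independent endpoint), maximizing the scale-profiled Gaussian
working likelihood of the standardized residuals. On a star phylogeny the
fit reduces exactly to ordinary logistic regression.

Inference on $\beta_1$ uses a parametric bootstrap, chosen over asymptotic
standard errors because per-phylum sample sizes are small: tip data are
re-simulated from the *fitted* model through a Gaussian copula whose latent
correlation is $R(\hat\alpha)$ (marginals preserved exactly), each
replicate is refit with $\alpha$ held at $\hat\alpha$ (re-profiling per
replicate multiplies cost roughly tenfold for no measurable change in
calibration at these sizes), and the two-sided p-value is twice the smaller
tail of the replicate slopes beyond zero, floored at $1/(n_{boot}+1)$.
Percentile intervals come from the same replicates. Measured on 48-tip
balanced trees, the test's type-I error at $\alpha=0.05$ sits within
Monte-Carlo error of 0.05, and 95% intervals cover a true slope of 1.0 at
roughly their nominal rate on 64-tip trees.

The generalism workflow fits one trait at a time: the top five traits per
phylum by blocked-forest importance, then one phylogenetic logistic fit per
(phylum, trait), with BH correction over all tests as a single family.

## Synthetic worlds

`simulate_world` generates the three pipeline inputs with a ground-truth
ledger. Default conditions: 4 phyla × 75 taxa in a nested
class/family/genus taxonomy with clade-monophyletic random trees; 40
subjects sampled at 7 body sites (stool, posterior fornix, three oral
sites, anterior nares, retroauricular crease) across 5 areas, with
occasional repeat visits to exercise subject de-duplication; 12 continuous
traits from a 4-block precision matrix (partial correlation 0.35 within
blocks), 5 categorical traits from per-phylum multinomials, 45 binary
traits (30 carbon substrates) evolved on the trees through the same
distance-decaying copula the regression uses, so they carry genuine
phylogenetic signal; 10% missingness on continuous and categorical traits,
never on binary. Abundances are site-specific Dirichlet draws over the taxa
present in a sample; presence follows each taxon's home areas (a planted
~30% of taxa are generalists ranging over two or more areas) plus a small
out-of-range leak that creates the single-sample noise the generalism
filter exists to remove.

Planted site–trait effects multiply a taxon's Dirichlet concentration by
$\exp(\beta z_i)$ in the affected site, where $z_i$ is the taxon's
standardized trait value and $\beta$ defaults to 2 (an effect of +2 SD).
Default planting targets continuous traits, one per precision block: binary
traits differ in baseline prevalence across phyla (they evolved on
different trees), which confounds cross-phylum transfer of a planted
effect, and block-correlated traits leak a planted signature into sibling
traits' sites. One effect per block on phylogeny-free traits keeps each
planted signature identifiable, so recovery tests measure recovery rather
than robustness to confounding. `site_neutral=True` removes all
compositional site signal (every taxon ranges everywhere, no leak); with
`auto_effects=False` this gives an exchangeable global null under which the
permutation test's rejection rate is the nominal $\alpha$, and with one
explicit effect it isolates that effect as the only site signal.

What the generator does *not* emulate: real HMP taxon names, realistic
phylogenetic depth calibration, strain-level trait variability, sequencing
noise or compositional detection limits, and correlations between trait
blocks and the taxonomy. Passing recovery tests therefore demonstrates that
the estimators find the structure they target when it is present at
realistic strength — not that real data contain such structure.

## Numerical and procedural choices

* Permutation p-values use the add-one estimator; permuted statistics are
  computed vectorized from group-sum identities.
* EBIC candidate supports are deduplicated along the path; a penalty whose
  glasso fit fails is dropped with a warning.
* Annealing defaults: start temperature 1.0, geometric cooling ×0.95 to
  5·10⁻³, 15 sweeps per node per temperature, 3 restarts. Deterministic
  given seed.
* Generalism labels: presence is strictly positive abundance (no detection
  cutoff, since relative-abundance inputs carry none); a taxon present in
  only one sample overall is excluded, as is a taxon with ≥2 appearances
  but no single area reaching 2 (flagged `excluded` with its area count).
* The carbon-source distribution of a sample splits each taxon's abundance
  equally among its substrates (maximum-entropy default; the alternative
  "full weight then renormalize" rule is exposed). Entropies are in nats;
  any base rescales all sites identically.
* Site tasks use sites with ≥10 subjects; the pooled "mouth (all)" task
  merges the three oral sites. The classifier score for AUPRC is the
  forest's positive-class vote fraction.
* Mean imputation uses database-wide column means (not per training fold),
  matching the use of the full curated database as the reference.
* Tips present in a tree but absent from trait data are pruned before
  regression; tie-breaks in top-k trait selection are lexicographic.

## Problem sizes

The shipped test-suite and acceptance-script sizes are chosen to exercise
every code path at desk scale: worlds of 120–300 taxa and 100–250 samples,
1000-permutation contrasts, 60–500-tree forests, 200-replicate bootstrap
and calibration loops, 64-tip regression trees. The full-size defaults
(10,000 permutations, 5000 trees, 10,000 bootstraps) are what the config
objects ship with and are intended for real analyses.

## Known limitations

* EBIC selection at $\gamma=0.5$ is consistent but not error-free at
  moderate $n$: across many simulated block worlds an occasional weak
  cross-block partial correlation (~0.1) is admitted; tightening $\gamma$
  trades these false edges against missed weak true edges.
* The spin-glass optimizer is stochastic; on large dense graphs the
  annealing schedule may need more restarts to reach the global optimum.
* The GEE slope estimate carries the usual small-sample logistic bias
  (upward, order 0.1 at 64 tips with a true slope of 1), which the
  bootstrap intervals absorb but the point estimate does not.
* Phylogenetic signal is modeled as a single exponential decay rate per
  fit; heterogeneous signal across clades is not represented.
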