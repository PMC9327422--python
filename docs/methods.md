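# Methods

This note documents the models, numerical choices, and design decisions
behind `amlsig`, and what the synthetic-data tests do and do not
establish about real cohorts.

## Synthetic cohorts

The generator emulates a small proteogenomic drug-response cohort: 38
samples by default, four molecular layers, a drug panel whose pooled AUC
distribution spans exactly 14.7–186.3 (an affine map of the generative
responses), and weak cross-layer coupling.

Coupling is induced through a shared latent Gaussian factor per gene.
For a Gaussian copula, Spearman ρ_s and Pearson ρ_p of the latents obey
ρ_p = 2·sin(π·ρ_s/6), so the mixing weight that yields a target Spearman
is available in closed form. Defaults: mRNA–protein ρ_s = 0.25,
site–protein ρ_s = 0.15 — the weak correlations characteristic of
proteogenomic cohorts. Transcripts are exp(Normal) abundances scaled to
10⁶ per sample (CPM semantics without read simulation); proteins and
phosphosites are reported as per-feature-centered log₂-ratio-like
values; mutations are Bernoulli(0.03) per gene × sample, a typical
per-gene somatic rate for a small panel. Sites per gene are Poisson with
mean 3.

Each drug's response is a sparse linear combination of planted features
(default: 5 protein features, coefficients ±1) plus Gaussian noise.
When `noise_sd` is left unset it is solved from a target generative
R² = 0.7: with unit coefficients on unit-variance features,
sd = sqrt(s·(1−R²)/R²) for signature size s. Missingness in the drug
table is injected completely at random (default 15%) — no mechanism
beyond MCAR is modeled. Phosphosite ids are "GENE-pS123"-style strings
so the site→protein map is a pure string operation.

What the generator does **not** emulate: batch effects, missingness in
the molecular matrices, heavy-tailed abundance distributions,
correlated gene modules, or mutation co-occurrence structure. Passing
recovery tests on these cohorts therefore demonstrates correctness of
the machinery under the stated statistical structure, not performance on
real data.

### Cell lines

Cell-line datasets carry protein/phosphosite features only (transcript
signature members map to the protein of the same gene). The late /
resistant group shifts every signature feature by `shift_late`; the
early group models ligand-mediated resistance, which engages only part
of the intrinsic resistance program, so it shifts a fraction
`early_fraction` (default 0.6) of the signature features by
`shift_early`. This makes early cultures genuinely closer to parental
cells than late cultures — with a fully colinear shift model
(`early_fraction = 1`) and `shift_early = shift_late/2` the early group
would sit exactly midway and its merge side in the dendrogram would be
decided by noise. Set `early_fraction = 1.0` to recover the colinear
model (used in the equal-shift symmetry test).

## Drug filtering and response coding

A drug is retained when at least max(⌈0.10·n⌉, 2) of its n non-missing
samples have AUC < 100. The ceiling implements "at least 10%", and n
counts non-missing measurements because panel coverage varies per drug.
AUC exactly 100 codes as resistant (1): sensitivity is defined strictly
below the threshold. Both choices are configurable.

## Penalized regression

The gaussian objective is (1/2n)·RSS + λ[(1−a)‖β‖₂²/2 + a‖β‖₁] with
unpenalized intercept; logistic replaces the loss with the average
binomial deviance. Solvers: scikit-learn coordinate descent
(`ElasticNet`, tol 1e-12) for gaussian fits and SAGA
(`LogisticRegression`, tol 1e-10, fixed `random_state`) for logistic
fits; returned solutions satisfy the KKT conditions to ≤ 1e-6 (checked
in tests against an independent split-variable L-BFGS-B minimizer).
λ = 0 falls back to least squares.

The penalty path has 50 log-spaced points from λ_max (the null-model
KKT threshold) down to 1e-3·λ_max for gaussian families. For logistic
the floor is raised to 1e-2·λ_max: at ≲ 40 samples the binarized
response is near-separable below that and fits degenerate (the same
reason glmnet raises its own `lambda.min.ratio` when n < p). The mixing
parameter is fixed per family (lasso 1, elastic net 0.5, logistic 1) and
the penalty level is what leave-one-out CV tunes; LOO ties break toward
the larger penalty (sparser model).

Leave-one-out selection is exact, not approximate. For gaussian
families each left-out problem is solved by a warm-started
coordinate-descent path at selection-grade tolerance (1e-5; the winning
penalty is refit tightly). For logistic, all n leave-one-out problems
are solved jointly by FISTA on the average-deviance objective — the
problems share the design matrix up to one excluded row, so their
gradients differ by a rank-one correction and vectorize; this matches
tightly-converged per-problem SAGA fits to ~1e-3 in mean deviance and
reproduces their selected penalties.

### Nested cross-validation and the exclusion rule

Outer folds are a seeded balanced partition (stratified by class for
logistic, since unstratified splits of ~38 samples frequently produce
single-class training sets). Per fold: select λ by LOO on the training
portion, refit, record the Spearman correlation between held-out
predictions and observations (for logistic, between the linear predictor
— rank-equivalent to the predicted probability — and the label). A model
is excluded when any fold refit selects zero features or any fold score
is undefined; every fold is still evaluated so the defined fold scores
are retained on excluded models.

A caveat worth knowing: conditioning on *inclusion* (all five folds
selecting features) is optimistic under the null. On pure-noise cohorts
the mean score of included models is ≈ +0.2, while the per-fold held-out
correlation — conditioned only on its own training set — is calibrated
(mean ≈ 0 over repetitions). Calibration checks in this package
therefore aggregate fold-level scores; summary tables still report the
per-model mean for included models, as the comparison figure convention
requires.

All features, including binary mutations, are standardized (population
variance) before penalization, for scale comparability across layers in
combined models; constant columns are dropped with a warning.

## Network integration

Base PPI edge cost is 1 − confidence, clipped to [0.01, 1]. The mean
base cost m is computed **before** augmentation (otherwise the m/4 and
3m/2 site-edge rules would be self-referential). Each phosphosite of
interest becomes a node: substrate→site at m/4, site→kinase at 3m/2 per
annotated kinase. Prizes are |coefficient| max-normalized to 1 —
the standard magnitude convention of prize-collecting tools. The graph
is undirected for solving; edge kinds are retained as metadata.

The PCSF objective is β·Σ_{v∉F} p(v) + Σ_{e∈F} c(e) + ω·#trees with
ω defaulting to m. Two solvers:

* **exact** — subset enumeration scoring each node subset by the minimum
  spanning forest of its induced subgraph (a true oracle, feasible to
  ~15 nodes), restricted to subsets where every site brings its parent
  protein (its substrate edge then always enters the MSF, since m/4 is
  the cheapest edge incident to a site).
* **heuristic** — dummy-root transformation (virtual root joined to each
  positive-prize node at cost ω), Goemans–Williamson moat growth, strong
  pruning, then a first-improvement single-node-flip local search from
  three starts (GW solution, all prize nodes, empty set) with edges
  re-derived as the induced MSF. On random ≤ 8-node instances this is
  optimal ~95% of the time and never exceeds twice the optimum
  (GW's approximation guarantee). A repair pass enforces the
  site-anchoring rule in heuristic solutions (leaf swaps are strict
  improvements; orphaned sites are dropped); the reported objective is
  recomputed after repair.

Randomization multiplies every edge cost by an independent
Uniform(1−δ, 1+δ) draw (δ = 0.05 by default), runs the solver (100
times by default), and reports per-node selection frequencies; the
consensus subgraph is induced on nodes at frequency ≥ 0.5. The
aggregation and noise model follow the documented behavior of
prize-collecting network tools; all of β, ω, δ, the run count and the
consensus threshold are configurable.

## Enrichment

Over-representation is the upper-tail hypergeometric test P(X ≥ k) with
Benjamini–Hochberg correction across tested sets ("corrected p" is read
as BH FDR); significance defaults to q < 0.01. The universe is the
measured feature set of the relevant modality, not the genome. Kinase
over-representation treats each kinase's annotated substrate sites as a
set within the site universe and reports the fraction of selected sites
with no kinase annotation — with realistic annotation sparsity (~20%)
this fraction is large and the test is underpowered, which the package
reports rather than hides.

Discrete p-values are super-uniform under the null (P(p ≤ x) ≤ x), so
their distribution cannot be compared to Uniform(0,1) directly; the
calibration diagnostic `randomized_null_pvalue` (P(X>k) + U·P(X=k),
exactly uniform under the null) is provided for that purpose.

## Cell-line validation

Signature features are z-scored across samples; samples are clustered by
average-linkage agglomerative clustering on Euclidean distance (flat
labels by cutting at k clusters; sample order fixed by sorted id so the
result is input-order invariant). Distance, linkage and scaling are
package choices — heatmap figures in the literature rarely state them —
and are configurable. Separation is quantified by the adjusted Rand
index between cluster labels and known groups (1 = identical, ~0 at
chance; the degenerate single-cluster-vs-single-group case is defined
as 1). Resistance-stage ordering compares mean cophenetic distances
parental↔early vs parental↔late on the same tree. Signature features
missing from the cell-line data (e.g. transcripts when only proteins
were measured) are dropped and the protein-level sub-signature used.

## Pipeline

One YAML config drives all seven stages; a single global seed derives
per-stage seeds by CRC-hashing the stage name, so stages are
independently reproducible and a rerun with the same config and seed is
byte-identical in all summary tables. Stage artifacts are TSV/GMT/JSON
with a JSON manifest. The `amlsig` CLI wraps the library thinly;
exit codes distinguish config (2), data (3) and numerical (4) errors.

### Problem sizes in tests and the acceptance script

Test and default-pipeline problem sizes are chosen to exercise the full
machinery at desk scale: the default pipeline study uses 38 samples,
30 genes (plus ~90 phosphosites), 3 drugs, lasso/elastic-net over all
seven layer combinations plus logistic on two, and 25 PCSF
randomizations. Signature-recovery checks use the cohort geometry the
method targets (n = 38, p = 200 per layer, 5 planted features,
generative R² = 0.7); null calibration uses p = 40 cohorts where fold
scores are plentiful. The acceptance script mirrors these sizes.

## Known limitations

* The inclusion-conditioned mean score is optimistic under the null
  (see above); compare models by this convention only among models of
  similar inclusion behavior.
* Under the recovery conditions (n = 38, p = 200, R² = 0.7) lasso
  support recall averages near 0.8 with substantial seed-to-seed spread
  — occasional cohorts yield an empty signature, exactly as the
  reference coordinate-descent implementation does on identical data.
* The GW heuristic's 2× bound is inherited from the rooted
  prize-collecting construction; the local-search polish is first-order
  only (single-node flips).
* Logistic models on small cohorts are frequently excluded (single-class
  folds, empty refits); this is expected behavior of the method, not an
  error.
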