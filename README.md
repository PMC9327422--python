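# amlsig

Multi-omic sparse-regression signatures of ex vivo AML drug response,
with phosphosite-aware interaction-network integration.

## The problem

Ex vivo drug screens expose freshly isolated AML patient cells to a panel
of small-molecule inhibitors and summarize each dose–response curve as an
AUC (low = sensitive, high = resistant). Given matched molecular profiles
of the same samples — somatic mutations (binary), transcript abundance
(CPM), global protein abundance and phosphosite abundance (log₂ ratios to
a common reference) — which molecular layer, or combination of layers,
best predicts response, and which features form an interpretable
signature? This package implements that analysis end to end for
bioinformaticians working with proteogenomic drug-response cohorts, and
ships a synthetic-cohort generator with planted ground truth so every
stage can be tested against known answers.

## The model

For each drug, response is regressed on standardized features X with the
elastic-net penalty (intercept unpenalized):

    min over (β₀, β):  L(y, β₀ + Xβ) + λ [ (1−a) ‖β‖₂²/2 + a ‖β‖₁ ]

where L is (1/2n)·RSS for the gaussian families (lasso a = 1, elastic net
a = 0.5) and the average binomial deviance for logistic regression on the
binarized response (resistant ⇔ AUC ≥ 100). Assessment is nested:
5-fold outer CV measures Spearman correlation between held-out
predictions and observed response, and within each outer training set λ
is selected by leave-one-out CV over a 50-point log-spaced path from
λ_max (the null-model threshold) downward, ties broken toward the sparser
model. Models whose refits select no features are excluded, not scored.
The signature for a drug is the nonzero support of a final refit on all
samples.

Signatures are then contextualized in a protein–protein interaction graph
augmented with one node per phosphosite: substrate→site edges cost m/4
and site→kinase edges 3m/2, where m is the mean base-edge cost
(cost = 1 − confidence). Signature members receive prizes
|coef|/max|coef| and a Prize-Collecting Steiner Forest

    min  β·Σ_{v∉F} p(v) + Σ_{e∈F} c(e) + ω·(#trees)

is solved over 100 edge-cost randomizations; nodes recurring in ≥ 50% of
runs form the consensus network. Signature genes are tested for gene-set
over-representation (hypergeometric, BH-corrected) and selected
phosphosites for kinase over-representation. Finally, signatures are
validated in cell-line data by average-linkage hierarchical clustering:
a good signature separates resistant from parental cultures (adjusted
Rand index) and places early (ligand-mediated) resistance closer to
parental cells than late (mutation-driven) resistance on the cophenetic
tree.

## Worked example

```python
from amlsig.synthdata import CohortConfig, generate_cohort
from amlsig.cohort import FilterConfig, filter_drugs, modality_correlation
from amlsig.models import ModelSpec, CVConfig, assemble_features, \
    evaluate_nested_cv, extract_signature

cohort, response, truth = generate_cohort(CohortConfig(seed=3, n_genes=200,
                                                       n_drugs=2,
                                                       missing_rate=0.0))
print(round(modality_correlation(cohort["transcript"],
                                 cohort["protein"]).pooled, 3))
print(filter_drugs(response, FilterConfig()))

X = assemble_features(cohort, ("protein",))
y = response.auc.loc["D01"].to_numpy(float)
spec = ModelSpec("lasso", ("protein",))
fit = evaluate_nested_cv(X, y, spec, CVConfig(seed=5))
print(round(fit.mean_score, 3))

sig = extract_signature(X, y, spec, drug="D01")
recovered = {f for f, _m, _c in sig.features} & truth.support("D01")
print(len(recovered), "of", len(truth.support("D01")))
```

prints

```
0.257
['D01', 'D02']
0.512
5 of 5
```

The pooled mRNA–protein Spearman correlation of the generated cohort is
0.257 (the generator targets the weak coupling, ≈ 0.25, typical of
proteogenomic cohorts); both synthetic drugs pass the sensitivity filter
(≥ max(⌈10%·n⌉, 2) samples with AUC < 100); the nested-CV held-out
Spearman for the lasso protein model is 0.51 under ~70% generative
signal; and the extracted signature recovers all 5 planted features.

The full pipeline (simulate → filter → compare → signature → network →
enrich → validate) runs from one config:

```bash
amlsig run --outdir results/demo --seed 7
```

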