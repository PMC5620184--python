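# bloodmark

Blood-biomarker discovery and validation for dendritic-cell (DC)
vaccination cohorts.

In DC vaccination of metastatic melanoma, only a subset of patients
mounts an effective anti-tumor response, and no pre-treatment marker
reliably identifies them. A practical alternative is a blood readout
measured after the first vaccination cycle: find genes whose PBMC
expression tracks overall survival on a discovery microarray cohort,
validate them by qPCR against array-mined reference genes, and turn the
best candidate into a clinically usable rule (an expression cutoff that
flags probable short survivors, who need a different treatment).
`bloodmark` implements that entire workflow as a tested, reusable Python
package, together with a synthetic-cohort generator that reproduces the
statistical structure of such a study (paired PBMC/vaccine-DC samples,
multi-center batches, censored survival, planted survival genes, stable
reference genes, longitudinal sampling), so every stage runs and is
verifiable without any patient data.

## The methods at its core

* **Survival SAM** — per probe, d = r/(s + s0) where r is the Cox
  partial-likelihood score at β = 0, U(0) = Σ_deaths (x_i − x̄_risk set),
  s the square root of the accumulated risk-set variance and s0 the SAM
  fudge factor; significance by the permutation rule "90th-percentile
  FDR = 0" (in ≥90% of permutations, no permuted statistic beyond the
  calling thresholds).
* **Two-class and paired SAM** for the vaccination signature (PBMC vs
  matured DC) gating a long-vs-short survivor pass.
* **PLS-DA** (NIPALS PLS2 on survival-class indicators) with VIP ≥ 1
  variable selection.
* All arms finish with a linear fold-change filter (long/short mean
  ratio ≥ 2 or ≤ ½); candidates are the gene-level intersection.
* **geNorm** reference-gene stability, M_j = mean_k SD(log2 x_j − log2
  x_k), with stepwise elimination, after invariance (log2 CV < 5%) and
  trend-absence screens.
* **ΔCt quantification**: log2 relative expression = mean(Ct_refs) −
  Ct_target, i.e. 2^−ΔCt against the geometric mean of two references.
* **Evaluation**: center-median normalization, ROC of "low expression
  predicts death before a survival window" (AUC = Mann–Whitney
  U/(n₊n₋), Hanley–McNeil SE) with a 10–18-month window sweep, Youden or
  specificity-floor cutoffs, Kaplan–Meier + log-rank stratification,
  longitudinal Δ-from-baseline analysis, and a Fisher exact test that
  expression changes oppose myeloid/lymphoid-balance changes.
* **Preranked GSEA** of anchor-gene co-expression (weighted running-sum
  ES, gene-permutation NES/FDR) against blood-transcriptional-module
  style gene sets (GMT).

See `docs/methods.md` for models, defaults and numerical conventions.

## Worked example

Discover the planted survival genes in a synthetic 74-patient cohort:

```python
from bloodmark import SimulationConfig, simulate_cohort
from bloodmark.preprocess import preprocess
from bloodmark.cli import run_discovery

cohort = simulate_cohort(SimulationConfig(seed=7))
pbmc, _ = preprocess(cohort.pbmc)          # background offset + log2
dc, _ = preprocess(cohort.dc)
result = run_discovery(pbmc, dc, cohort.samples, n_perm=1000, seed=7)
panel = result["panel"]
print("panel genes:", panel.genes)
```

prints

```
panel genes: ['SURV02', 'SURV03', 'SURV05', 'SURV07', 'SURV08', 'SURV09', 'SURV10']
```

— seven of the ten planted survival genes and zero false positives out
of 1000 probes survive all three arms. Then validate one candidate at
qPCR scale and evaluate it as a clinical rule:

```python
from bloodmark import simulate_qpcr
from bloodmark.discovery import survival_class
from bloodmark.refgenes import select_reference_pair
from bloodmark.qpcr import relative_expression
from bloodmark.evaluate import evaluate_biomarker

months, event = cohort.samples.survival(cohort.samples.pbmc_ids())
classes = survival_class(months)
refs = select_reference_pair(pbmc,
                             list(classes.index[classes == "short"]),
                             list(classes.index[classes == "long"]),
                             relax_p_min=True)
ct = simulate_qpcr(pbmc, ["SURV02"], list(refs.pair), seed=7)
rel = relative_expression(ct, "SURV02", refs.pair)
df = cohort.samples.df.loc[rel.index]
report = evaluate_biomarker(rel, df["center"],
                            df["survival_months"], df["event"])
```

which reports (same seed):

```
reference pair: ('REF04', 'REF07')
pooled Spearman rho = 0.53 (one-tailed p = 5.5e-07)
best survival window = 11 months, AUC = 0.81 +/- 0.061
cutoff -0.44: sensitivity 68%, specificity 83%
log-rank chi2 = 17.1, p = 3.5e-05
```

Read: the geNorm pipeline picked two of the planted stable genes as
references; the candidate's center-normalized qPCR expression correlates
with survival across both centers; an 11-month window maximizes the AUC
on this cohort; and patients below the −0.44 log2 cutoff have
significantly shorter survival by log-rank.

A shell interface wraps the same stages
(`bloodmark simulate|preprocess|discover|refgenes|qpcr|evaluate|gsea|run`);
`bloodmark run --config cfg.yaml --outdir out` executes them end to end
with one seed fanned out per stage.

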